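"""Positive rules of the screening panel and the triage policy.

Each rule row screens for one disorder or for a set of disorders that share a
biochemical signature (differential diagnosis belongs to confirmatory testing,
so such rows carry every member's OMIM codes and flag a single combined
screening label).  A row is a disjunction of groups; a group is a conjunction
of threshold conditions with the exact printed comparator, evaluated strictly:
a value exactly at a ``gt`` threshold does not satisfy the condition, and a
condition on an absent marker evaluates false.

Triage of a flagged record is three-way: ``negative`` (no flags),
``clear_aberrant`` (some satisfied condition lies beyond ``k``-fold of its
threshold — such newborns are referred for confirmatory testing immediately),
else ``mild_positive`` (recalled for a second dried-blood-spot test).  The
``k``-fold boundary is this package's quantitative interpretation of a
"clearly aberrant" first screen; it is configurable and defaults to 2.
"""

from __future__ import annotations

import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .panel import MarkerDefinition, PanelRecord, normalize_marker_name

COMPARATORS = {
    "gt": operator.gt,
    "ge": operator.ge,
    "lt": operator.lt,
    "le": operator.le,
}

CATEGORIES = ("AAMD", "OAMD", "FAOD")


@dataclass(frozen=True)
class RuleCondition:
    marker: str
    comparator: str  # gt | ge | lt | le
    threshold: float

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ConfigError(f"unknown comparator {self.comparator!r}")
        if not np.isfinite(self.threshold):
            raise ConfigError(f"condition on {self.marker!r}: non-finite threshold")

    def holds(self, value: float | None) -> bool:
        if value is None:
            return False
        return COMPARATORS[self.comparator](value, self.threshold)

    @property
    def upper_tailed(self) -> bool:
        """True when the condition fires on elevated values (gt/ge)."""
        return self.comparator in ("gt", "ge")


@dataclass(frozen=True)
class RuleGroup:
    """A conjunction of conditions (one "positive rule" column entry)."""

    conditions: tuple[RuleCondition, ...]

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ConfigError("empty rule group")


@dataclass(frozen=True)
class Disorder:
    name: str
    abbrev: str
    omim: tuple[str, ...] = ()


@dataclass(frozen=True)
class DisorderRule:
    """One row of the positive-rule table (possibly covering several disorders)."""

    label: str
    category: str
    disorders: tuple[Disorder, ...]
    groups: tuple[RuleGroup, ...]
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigError(f"rule {self.label!r}: unknown category {self.category!r}")
        if not self.groups:
            raise ConfigError(f"rule {self.label!r}: no positive-rule groups")

    @property
    def omim_codes(self) -> tuple[str, ...]:
        return tuple(code for d in self.disorders for code in d.omim)

    def covers(self, diagnosis: str) -> bool:
        """Whether this screening label contains ``diagnosis`` (name or abbrev)."""
        names = {d.name for d in self.disorders} | {d.abbrev for d in self.disorders}
        return diagnosis in names or diagnosis in self.aliases


@dataclass(frozen=True)
class SatisfiedCondition:
    marker: str
    comparator: str
    threshold: float
    value: float


@dataclass(frozen=True)
class ScreenFlag:
    """A disorder flagged for one record.

    ``margin`` is the largest relative distance from threshold among the
    satisfied group's conditions, ``max |value - threshold| / threshold``.
    """

    disorder_name: str
    satisfied_group_index: int
    margin: float
    conditions: tuple[SatisfiedCondition, ...] = field(default=(), compare=False)


def load_rules(path=None, defs: list[MarkerDefinition] | None = None) -> list[DisorderRule]:
    """Load the positive-rule table from YAML (shipped table when ``path`` is None).

    When ``defs`` is given, every referenced marker must be defined in the
    panel; an unknown marker raises :class:`ConfigError` naming the rule row
    and the marker.
    """
    if path is None:
        from .datasets import _data_path

        path = _data_path("rules.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'rules' list")

    known = {d.name for d in defs} if defs is not None else None
    rules: list[DisorderRule] = []
    for row in doc["rules"]:
        try:
            label = row["label"]
            groups = []
            for grp in row["groups"]:
                conds = tuple(
                    RuleCondition(
                        normalize_marker_name(c["marker"]), c["op"], float(c["threshold"])
                    )
                    for c in grp
                )
                groups.append(RuleGroup(conds))
            disorders = tuple(
                Disorder(
                    d["name"],
                    d.get("abbrev", d["name"]),
                    tuple(str(x) for x in d.get("omim", ())),
                )
                for d in row["disorders"]
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"rule row {row.get('label', '?')!r}: malformed ({exc})") from exc
        rule = DisorderRule(
            label=label,
            category=row["category"],
            disorders=disorders,
            groups=tuple(groups),
            aliases=tuple(row.get("aliases", ())),
        )
        if known is not None:
            for grp in rule.groups:
                for cond in grp.conditions:
                    if cond.marker not in known:
                        raise ConfigError(
                            f"rule {label!r}: unknown marker {cond.marker!r}"
                        )
        rules.append(rule)
    return rules


def evaluate_record(record: PanelRecord, rules: list[DisorderRule]) -> list[ScreenFlag]:
    """Classify one record: a disorder is flagged iff some group is fully satisfied.

    The satisfied group reported for a flagged rule is the first (lowest
    index); flags are sorted by disorder label.
    """
    flags: list[ScreenFlag] = []
    for rule in rules:
        for gi, grp in enumerate(rule.groups):
            values = [record.values.get(c.marker) for c in grp.conditions]
            if all(c.holds(v) for c, v in zip(grp.conditions, values)):
                margin = max(
                    abs(v - c.threshold) / c.threshold if c.threshold != 0 else float(v)
                    for c, v in zip(grp.conditions, values)
                )
                flags.append(
                    ScreenFlag(
                        disorder_name=rule.label,
                        satisfied_group_index=gi,
                        margin=margin,
                        conditions=tuple(
                            SatisfiedCondition(c.marker, c.comparator, c.threshold, v)
                            for c, v in zip(grp.conditions, values)
                        ),
                    )
                )
                break
    return sorted(flags, key=lambda f: f.disorder_name)


@dataclass(frozen=True)
class TriagePolicy:
    """Urgency multiplier for the clear-aberrant boundary; must exceed 1."""

    k: float = 2.0

    def __post_init__(self) -> None:
        if not self.k > 1:
            raise ConfigError(f"triage urgency multiplier k must be > 1, got {self.k}")


def _condition_is_clear(cond: SatisfiedCondition, k: float) -> bool:
    if cond.comparator in ("gt", "ge"):
        return cond.value > k * cond.threshold
    return cond.value < cond.threshold / k


def triage(flags: list[ScreenFlag], policy: TriagePolicy = TriagePolicy()) -> str:
    """Triage a screened record: ``negative``, ``mild_positive`` or ``clear_aberrant``."""
    if not flags:
        return "negative"
    for flag in flags:
        for cond in flag.conditions:
            if _condition_is_clear(cond, policy.k):
                return "clear_aberrant"
    return "mild_positive"


def evaluate_frame(
    frame: pd.DataFrame,
    rules: list[DisorderRule],
    policy: TriagePolicy = TriagePolicy(),
) -> pd.DataFrame:
    """Vectorized screening of a cohort frame with derived ratio columns.

    Returns a DataFrame indexed like ``frame`` with one boolean column per rule
    label plus ``flagged`` (any rule) and ``clear_aberrant`` (some satisfied
    condition beyond the k-fold triage boundary).  Missing marker columns and
    NaN values evaluate false, matching the per-record semantics.
    """
    n = len(frame)
    out = pd.DataFrame(index=frame.index)
    any_clear = np.zeros(n, dtype=bool)
    for rule in rules:
        rule_hit = np.zeros(n, dtype=bool)
        for grp in rule.groups:
            grp_hit = np.ones(n, dtype=bool)
            clear_in_grp = np.zeros(n, dtype=bool)
            for cond in grp.conditions:
                if cond.marker not in frame.columns:
                    grp_hit[:] = False
                    break
                col = frame[cond.marker].to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    ok = COMPARATORS[cond.comparator](col, cond.threshold)
                ok &= ~np.isnan(col)
                grp_hit &= ok
                if cond.upper_tailed:
                    clear_in_grp |= ok & (col > policy.k * cond.threshold)
                else:
                    clear_in_grp |= ok & (col < cond.threshold / policy.k)
            rule_hit |= grp_hit
            any_clear |= grp_hit & clear_in_grp
        out[rule.label] = rule_hit
    out["flagged"] = out[[r.label for r in rules]].any(axis=1) if rules else False
    out["clear_aberrant"] = any_clear & out["flagged"].to_numpy()
    return out
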