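"""Synthetic newborn cohorts with the statistical structure the screen assumes.

Unaffected newborns get lognormal concentrations per measured marker,
calibrated in closed form so that the laboratory reference interval
``[low, high]`` sits at configurable quantiles (default 0.5% / 99.5%) of the
marker's distribution.  Lognormal is the standard family for metabolite
panels: non-negative and right-skewed.  Ratio indicators are always derived
from the sampled operands, never sampled directly.

Markers share a specimen-level factor: all log-concentrations of a newborn
load on one common standard normal with exchangeable correlation ``rho``
(dried-blood-spot punch volume, hematocrit and extraction efficiency scale
every analyte of a specimen together).  The shared factor partially cancels
in ratios, which is what makes the laboratory's ratio reference intervals far
narrower than independent per-marker variation would produce; ``rho`` is
fitted in closed form from the printed ratio reference ranges (see
:func:`fit_marker_correlation`) and marker marginals remain the exactly
calibrated lognormals regardless of ``rho``.  ``rho = 0`` gives fully
independent markers.

Affected newborns are drawn at configured per-disorder incidences.  A disease
profile targets one positive-rule group of the disorder's rule row and samples
the rule markers uniformly between the threshold and the most extreme value
printed for a confirmed case of that disorder (falling back to three-fold the
threshold), so a profiled panel satisfies the group; ``sensitivity`` is the
probability a case expresses the profile at all (otherwise its panel is drawn
from the unaffected population — a biochemical false negative).

A false-positive layer perturbs one randomly chosen rule marker of an
unaffected newborn just past its threshold with probability ``fp_rate``,
emulating pre-analytical and transient elevations beyond pure reference-range
tail exceedances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from . import datasets
from .errors import CalibrationError, ConfigError, ProfileError
from .panel import CutoffRange, MarkerDefinition, derive_frame
from .rules import COMPARATORS, DisorderRule, RuleGroup

#: Male fraction of the screened population (178,265 of 300,849 newborns).
MALE_FRACTION = 178_265 / 300_849


@dataclass(frozen=True)
class AnalyteDistribution:
    """Calibrated lognormal for one measured marker (log-scale mu, sigma)."""

    marker: str
    mu: float
    sigma: float
    family: str = "lognormal"

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise CalibrationError(f"{self.marker}: sigma must be positive")

    def quantile(self, q: float) -> float:
        return float(np.exp(self.mu + self.sigma * norm.ppf(q)))

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))


def calibrate_normal_distributions(
    cutoffs: list[CutoffRange],
    defs: list[MarkerDefinition] | None = None,
    q_low: float = 0.005,
    q_high: float = 0.995,
) -> list[AnalyteDistribution]:
    """Solve (mu, sigma) per measured marker so the cut-off bounds sit at the anchors.

    ``quantile(q_low) = low`` and ``quantile(q_high) = high`` have the closed
    form ``sigma = (ln high - ln low) / (z_high - z_low)``,
    ``mu = ln low - sigma * z_low``.  A non-positive lower bound is replaced by
    ``min(high/1000, 0.001)``.  Ratio markers are never calibrated or sampled.
    """
    if not 0 < q_low < q_high < 1:
        raise CalibrationError(f"invalid quantile anchors ({q_low}, {q_high})")
    measured = (
        {d.name for d in defs if d.kind != "ratio"} if defs is not None else None
    )
    z_low, z_high = norm.ppf(q_low), norm.ppf(q_high)
    out: list[AnalyteDistribution] = []
    for rng in cutoffs:
        if measured is not None and rng.marker not in measured:
            continue
        low, high = rng.low, rng.high
        if low is None or high is None:
            raise CalibrationError(f"{rng.marker}: both bounds required for calibration")
        if low <= 0:
            low = min(high / 1000.0, 0.001)
        if low >= high:
            raise CalibrationError(f"{rng.marker}: low {low} >= high {high}")
        sigma = (np.log(high) - np.log(low)) / (z_high - z_low)
        mu = np.log(low) - sigma * z_low
        out.append(AnalyteDistribution(rng.marker, float(mu), float(sigma)))
    return out


def fit_marker_correlation(
    cutoffs: list[CutoffRange],
    defs: list[MarkerDefinition],
    q_low: float = 0.005,
    q_high: float = 0.995,
) -> float:
    """Exchangeable log-scale marker correlation implied by the ratio cut-offs.

    For a two-marker ratio A/B under the shared-factor model,
    ``Var(ln A/B) = sigma_A^2 + sigma_B^2 - 2 rho sigma_A sigma_B``.  Each
    ratio's reference range, anchored at the same quantiles as the markers,
    implies a target log-sd; rho is fitted by least squares of modeled minus
    target log-sd over all single-marker/single-marker ratios with positive
    lower bounds, constrained to [0, 0.95].
    """
    dists = {d.marker: d for d in calibrate_normal_distributions(cutoffs, defs, q_low, q_high)}
    z_span = norm.ppf(q_high) - norm.ppf(q_low)
    by_marker = {r.marker: r for r in cutoffs}
    triples = []
    for d in defs:
        if d.kind != "ratio" or len(d.numerator) != 1 or len(d.denominator) != 1:
            continue
        rng = by_marker.get(d.name)
        if rng is None or rng.low is None or rng.low <= 0 or rng.high is None:
            continue
        s_t = (np.log(rng.high) - np.log(rng.low)) / z_span
        triples.append((dists[d.numerator[0]].sigma, dists[d.denominator[0]].sigma, s_t))
    if not triples:
        return 0.0

    def sse(rho: float) -> float:
        return sum(
            (np.sqrt(max(sa**2 + sb**2 - 2 * rho * sa * sb, 1e-12)) - st) ** 2
            for sa, sb, st in triples
        )

    res = minimize_scalar(sse, bounds=(0.0, 0.95), method="bounded")
    return float(res.x)


@dataclass(frozen=True)
class DiseaseProfile:
    """Sampling recipe for panels of newborns affected by one disorder."""

    disorder_name: str
    rule: DisorderRule
    target_group_index: int
    sensitivity: float
    #: per-marker (low, high) sampling anchors for the target group's markers
    marker_shifts: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.sensitivity <= 1:
            raise ProfileError(f"{self.disorder_name}: sensitivity must be in (0, 1]")

    @property
    def target_group(self) -> RuleGroup:
        return self.rule.groups[self.target_group_index]


def make_disease_profile(
    disorder: str,
    rule: DisorderRule,
    group_index: int,
    sensitivity: float = 1.0,
    anchors: dict[str, tuple[float, float]] | None = None,
    defs: list[MarkerDefinition] | None = None,
) -> DiseaseProfile:
    """Build a profile targeting ``rule.groups[group_index]``.

    ``anchors`` maps marker name -> (min, max) abnormal values observed for
    this disorder; the sampling interval per condition runs from the threshold
    to the anchor on the condition's abnormal side, or to threshold*3
    (threshold/3 for low-sided conditions) when no anchor is informative.
    """
    if not 0 <= group_index < len(rule.groups):
        raise ProfileError(f"{disorder}: rule {rule.label!r} has no group {group_index}")
    group = rule.groups[group_index]
    if defs is not None:
        known = {d.name for d in defs}
        if all(c.marker not in known for c in group.conditions):
            raise ProfileError(
                f"{disorder}: target group references only absent markers"
            )
    anchors = anchors or {}
    shifts: dict[str, tuple[float, float]] = {}
    for cond in group.conditions:
        lo_a, hi_a = anchors.get(cond.marker, (None, None))
        if cond.upper_tailed:
            hi = hi_a if hi_a is not None and hi_a > cond.threshold else 3 * cond.threshold
            shifts[cond.marker] = (cond.threshold, float(hi))
        else:
            lo = lo_a if lo_a is not None and lo_a < cond.threshold else cond.threshold / 3
            shifts[cond.marker] = (float(lo), cond.threshold)
    return DiseaseProfile(disorder, rule, group_index, sensitivity, shifts)


def abnormal_anchors(cases: pd.DataFrame | None = None) -> dict[str, dict[str, tuple[float, float]]]:
    """Per-diagnosis (min, max) printed abnormal value for each marker.

    Derived from the shipped confirmed-case fixture by default; keys are the
    diagnosis abbreviations of the fixture.
    """
    if cases is None:
        cases = datasets.load_confirmed_cases()
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for _, row in cases.iterrows():
        d = out.setdefault(row["diagnosis"], {})
        for marker, value in row["marker_values"].items():
            lo, hi = d.get(marker, (value, value))
            d[marker] = (min(lo, value), max(hi, value))
    return out


def _group_rank(group: RuleGroup, measured: set[str]) -> tuple[int, int]:
    n_ratio = sum(1 for c in group.conditions if c.marker not in measured)
    return (n_ratio, len(group.conditions))


def default_profiles(
    rules: list[DisorderRule],
    defs: list[MarkerDefinition],
    disorders: list[str] | None = None,
    sensitivity: float = 1.0,
    cases: pd.DataFrame | None = None,
) -> dict[str, DiseaseProfile]:
    """Profiles for the given disorder abbreviations (default: all confirmed disorders).

    For each disorder the covering rule row is located and the target group is
    the one needing the fewest derived-ratio conditions (these require operand
    adjustment rather than direct sampling), ties broken by group size then
    group order.
    """
    if disorders is None:
        disorders = list(datasets.load_confirmed_counts()["abbrev"])
    measured = {d.name for d in defs if d.kind != "ratio"}
    anchors = abnormal_anchors(cases)
    profiles: dict[str, DiseaseProfile] = {}
    for abbrev in disorders:
        rule = next((r for r in rules if r.covers(abbrev)), None)
        if rule is None:
            raise ConfigError(f"no screening rule covers disorder {abbrev!r}")
        gi = min(
            range(len(rule.groups)),
            key=lambda i: (_group_rank(rule.groups[i], measured), i),
        )
        profiles[abbrev] = make_disease_profile(
            abbrev, rule, gi, sensitivity, anchors.get(abbrev, {}), defs
        )
    return profiles


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_newborns: int
    incidence: dict[str, float]
    year_weights: dict[int, float]
    fp_rate: float = 0.0
    seed: int = 0
    #: exchangeable log-scale marker correlation; None fits it from the ratio
    #: cut-off ranges at sampling time, 0 gives independent markers
    marker_correlation: float | None = None

    def __post_init__(self) -> None:
        if sum(self.incidence.values()) >= 1:
            raise ConfigError("total incidence must be < 1")
        total_w = sum(self.year_weights.values())
        if not np.isclose(total_w, 1.0):
            raise ConfigError(f"year weights must sum to 1, got {total_w}")
        if not 0 <= self.fp_rate < 1:
            raise ConfigError("fp_rate must be in [0, 1)")


def default_cohort_config(
    seed: int = 0, n_newborns: int | None = None, fp_rate: float = 0.0
) -> CohortConfig:
    """The five-year program conditions: observed incidences and yearly volumes."""
    counts = datasets.load_confirmed_counts()
    annual = datasets.load_annual_screening()
    total = datasets.TOTAL_SCREENED
    incidence = {r.abbrev: r.cases / total for r in counts.itertuples()}
    weights = {int(r.year): r.screened / total for r in annual.itertuples()}
    return CohortConfig(
        n_newborns=total if n_newborns is None else n_newborns,
        incidence=incidence,
        year_weights=weights,
        fp_rate=fp_rate,
        seed=seed,
    )


@dataclass(frozen=True)
class NewbornCase:
    """One synthetic individual (``truth`` is None for unaffected newborns)."""

    specimen_id: str
    truth: str | None
    year: int
    sex: str
    values: dict[str, float]


def _apply_profile(
    values: dict[str, float],
    profile: DiseaseProfile,
    defs_by_name: dict[str, MarkerDefinition],
    rng: np.random.Generator,
    max_tries: int = 10,
) -> dict[str, float]:
    """Mutate a raw-marker map so the profile's target group is satisfied.

    Measured-marker conditions are sampled directly in their shift interval;
    ratio conditions are met by rescaling the ratio's numerator operands to a
    target ratio sampled in the shift interval.  The group is re-verified on
    the derived values and sampling is retried on the rare interaction failure.
    """
    group = profile.target_group
    for _ in range(max_tries):
        vals = dict(values)
        for cond in group.conditions:
            d = defs_by_name.get(cond.marker)
            lo, hi = profile.marker_shifts[cond.marker]
            target = rng.uniform(lo, hi)
            if d is None or d.kind != "ratio":
                vals[cond.marker] = target
        for cond in group.conditions:
            d = defs_by_name.get(cond.marker)
            if d is None or d.kind != "ratio":
                continue
            lo, hi = profile.marker_shifts[cond.marker]
            target = rng.uniform(lo, hi)
            num = sum(vals[m] for m in d.numerator)
            den = sum(vals[m] for m in d.denominator)
            if num <= 0 or den <= 0:
                continue
            factor = target * den / num
            for m in d.numerator:
                vals[m] *= factor
        # verify on derived values
        ok = True
        for cond in group.conditions:
            d = defs_by_name.get(cond.marker)
            if d is not None and d.kind == "ratio":
                num = sum(vals[m] for m in d.numerator)
                den = sum(vals[m] for m in d.denominator)
                value = num / den if den > 0 else None
            else:
                value = vals.get(cond.marker)
            if value is None or not COMPARATORS[cond.comparator](value, cond.threshold):
                ok = False
                break
        if ok:
            return vals
    raise ProfileError(
        f"{profile.disorder_name}: could not satisfy group "
        f"{profile.target_group_index} after {max_tries} attempts"
    )


def _fp_conditions(rules: list[DisorderRule], measured: set[str]):
    """Measured-marker rule conditions eligible for the false-positive layer."""
    out = []
    for rule in rules:
        for grp in rule.groups:
            for cond in grp.conditions:
                if cond.marker in measured:
                    out.append(cond)
    return out


def sample_cohort(
    config: CohortConfig,
    dists: list[AnalyteDistribution],
    profiles: dict[str, DiseaseProfile],
    rules: list[DisorderRule],
    defs: list[MarkerDefinition],
    cutoffs: list[CutoffRange] | None = None,
) -> pd.DataFrame:
    """Draw a cohort as a DataFrame: marker columns plus ``truth``, ``year``, ``sex``.

    Reproducible under a fixed ``config.seed``.  Affected counts are
    multinomial at the configured incidences; ``truth`` holds the disorder
    abbreviation or the empty string.  Use :func:`cases_from_frame` for a
    per-individual object view.
    """
    for name, rate in config.incidence.items():
        if rate > 0 and name not in profiles:
            raise ConfigError(f"no disease profile for disorder {name!r}")
    rng = np.random.default_rng(config.seed)
    n = config.n_newborns
    disorders = [d for d in config.incidence if config.incidence[d] > 0]
    probs = np.array([config.incidence[d] for d in disorders] + [0.0])
    probs[-1] = 1.0 - probs[:-1].sum()
    labels = rng.choice(len(disorders) + 1, size=n, p=probs)

    rho = config.marker_correlation
    if rho is None:
        if cutoffs is None:
            raise ConfigError(
                "marker_correlation is unset: pass cutoffs to fit it, or set it explicitly"
            )
        rho = fit_marker_correlation(cutoffs, defs)
    if not 0 <= rho < 1:
        raise ConfigError(f"marker correlation must be in [0, 1), got {rho}")
    shared = rng.standard_normal(n)
    frame = pd.DataFrame(
        {
            dist.marker: np.exp(
                dist.mu
                + dist.sigma
                * (
                    np.sqrt(rho) * shared
                    + np.sqrt(1.0 - rho) * rng.standard_normal(n)
                )
            )
            for dist in dists
        }
    )
    defs_by_name = {d.name: d for d in defs}
    measured = {d.name for d in defs if d.kind != "ratio"}

    for di, disorder in enumerate(disorders):
        profile = profiles[disorder]
        for i in np.flatnonzero(labels == di):
            if rng.random() >= profile.sensitivity:
                continue  # biochemical false negative: unaffected-looking panel
            row = frame.iloc[i].to_dict()
            frame.iloc[i] = pd.Series(
                _apply_profile(row, profile, defs_by_name, rng)
            )[frame.columns]

    if config.fp_rate > 0:
        eligible = _fp_conditions(rules, measured)
        unaffected = labels == len(disorders)
        hit = unaffected & (rng.random(n) < config.fp_rate)
        idx = np.flatnonzero(hit)
        picks = rng.integers(0, len(eligible), size=idx.size)
        for i, pi in zip(idx, picks):
            cond = eligible[pi]
            if cond.upper_tailed:
                frame.iat[i, frame.columns.get_loc(cond.marker)] = rng.uniform(
                    cond.threshold, 1.2 * cond.threshold
                )
            else:
                frame.iat[i, frame.columns.get_loc(cond.marker)] = rng.uniform(
                    cond.threshold / 1.2, cond.threshold
                )

    frame = derive_frame(frame, defs)
    truth = np.array(disorders + [""], dtype=object)[labels]
    years = sorted(config.year_weights)
    frame["truth"] = truth
    frame["year"] = rng.choice(
        np.array(years), size=n, p=[config.year_weights[y] for y in years]
    )
    frame["sex"] = np.where(rng.random(n) < MALE_FRACTION, "M", "F")
    frame.index = pd.Index(
        [f"NB{i + 1:07d}" for i in range(n)], name="specimen_id"
    )
    return frame


def cases_from_frame(frame: pd.DataFrame, defs: list[MarkerDefinition]):
    """Yield :class:`NewbornCase` objects from a sampled cohort frame."""
    marker_cols = [d.name for d in defs if d.name in frame.columns]
    for specimen_id, row in frame.iterrows():
        yield NewbornCase(
            specimen_id=str(specimen_id),
            truth=row["truth"] or None,
            year=int(row["year"]),
            sex=str(row["sex"]),
            values={m: float(row[m]) for m in marker_cols},
        )
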