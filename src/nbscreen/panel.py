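"""Marker panel of the expanded newborn screen.

The panel has 74 indicators: 43 measured channels (amino acids, succinylacetone
and acylcarnitine species, some of which the non-derivatized MS/MS kit reports
as a single combined channel, e.g. ``C3DC + C4OH``) and 31 ratios derived from
them.  Concentrations are in μmol/L; ratios are dimensionless.  Each indicator
carries a laboratory reference interval; a value inside the closed interval
``[low, high]`` is normal.

Combined channels are single measured quantities and are never synthesized by
adding their nominal components.  Ratio markers are always derived, never
measured: ``compute_derived_markers`` evaluates each ratio as
``sum(numerator values) / sum(denominator values)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd
import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)

MARKER_KINDS = ("raw_analyte", "combined_channel", "ratio")

_WS = re.compile(r"\s+")


def normalize_marker_name(name: str) -> str:
    """Canonicalize a marker name: single spaces around ``+``, none around ``/``.

    Combined channels and sums print with spaces around ``+`` (``C4DC + C5OH``)
    while ratios print without spaces around ``/``.
    """
    s = _WS.sub(" ", str(name).strip())
    s = re.sub(r"\s*\+\s*", " + ", s)
    s = re.sub(r"\s*/\s*", "/", s)
    s = re.sub(r"\(\s*", "(", s)
    s = re.sub(r"\s*\)", ")", s)
    return s


@dataclass(frozen=True)
class MarkerDefinition:
    """One of the 74 screening indicators.

    For ``kind == "ratio"``, ``numerator`` and ``denominator`` list the measured
    marker names whose sums form the ratio; both are empty for measured markers.
    """

    name: str
    kind: str
    numerator: tuple[str, ...] = ()
    denominator: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in MARKER_KINDS:
            raise ConfigError(f"marker {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "ratio" and not (self.numerator and self.denominator):
            raise ConfigError(f"ratio marker {self.name!r} needs numerator and denominator")
        if self.kind != "ratio" and (self.numerator or self.denominator):
            raise ConfigError(f"measured marker {self.name!r} must not carry a formula")


@dataclass(frozen=True)
class CutoffRange:
    """Laboratory reference interval for a marker; either bound may be open."""

    marker: str
    low: float | None
    high: float | None

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ConfigError(f"marker {self.marker!r}: low {self.low} > high {self.high}")


@dataclass
class PanelRecord:
    """One newborn's marker → concentration map (raw plus derived values)."""

    specimen_id: str
    values: dict[str, float] = field(default_factory=dict)
    derived_complete: bool = False

    def __post_init__(self) -> None:
        self.values = {normalize_marker_name(k): float(v) for k, v in self.values.items()}
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"{self.specimen_id}: negative value for {name!r}")


def load_cutoff_table(path=None) -> tuple[list[MarkerDefinition], list[CutoffRange]]:
    """Load marker definitions and cut-off ranges from a YAML panel config.

    With no argument the shipped 74-indicator panel is loaded.  Returns
    ``(definitions, ranges)`` in panel order.  Raises :class:`ConfigError` for
    schema violations, duplicate marker names, or ratios referencing unknown or
    non-measured markers.
    """
    if path is None:
        from .datasets import _data_path

        path = _data_path("cutoffs.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "markers" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'markers' list")

    defs: list[MarkerDefinition] = []
    ranges: list[CutoffRange] = []
    seen: set[str] = set()
    for i, row in enumerate(doc["markers"]):
        try:
            name = normalize_marker_name(row["name"])
            kind = row["kind"]
            num = tuple(normalize_marker_name(m) for m in row.get("numerator", ()))
            den = tuple(normalize_marker_name(m) for m in row.get("denominator", ()))
            low = row.get("low")
            high = row.get("high")
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"panel row {i}: missing or malformed field ({exc})") from exc
        if name in seen:
            raise ConfigError(f"panel row {i}: duplicate marker name {name!r}")
        seen.add(name)
        defs.append(MarkerDefinition(name, kind, num, den))
        ranges.append(
            CutoffRange(
                name,
                None if low is None else float(low),
                None if high is None else float(high),
            )
        )

    measured = {d.name for d in defs if d.kind != "ratio"}
    for d in defs:
        if d.kind == "ratio":
            for op in (*d.numerator, *d.denominator):
                if op not in measured:
                    raise ConfigError(
                        f"ratio {d.name!r} references {op!r}, which is not a measured marker"
                    )
    return defs, ranges


def compute_derived_markers(
    record: PanelRecord, defs: list[MarkerDefinition]
) -> PanelRecord:
    """Populate every computable ratio marker of ``record``.

    Raw values are never modified, so the operation is idempotent.  A ratio
    with a missing operand or a zero denominator is left absent and logged at
    WARN level; it is never stored as inf/NaN.
    """
    values = dict(record.values)
    for d in defs:
        if d.kind != "ratio" or d.name in values:
            continue
        try:
            num = sum(values[m] for m in d.numerator)
            den = sum(values[m] for m in d.denominator)
        except KeyError as exc:
            logger.warning(
                "%s: ratio %s not computed, operand %s missing",
                record.specimen_id, d.name, exc.args[0],
            )
            continue
        if den == 0:
            logger.warning(
                "%s: ratio %s not computed, zero denominator", record.specimen_id, d.name
            )
            continue
        values[d.name] = num / den
    return replace(record, values=values, derived_complete=True)


def flag_out_of_range(
    record: PanelRecord, ranges: list[CutoffRange]
) -> list[tuple[str, str]]:
    """Markers strictly outside their reference interval, in panel order.

    The closed interval ``[low, high]`` is normal; a value equal to a bound is
    not flagged.  Returns ``(marker, "low"|"high")`` pairs.  Markers present in
    the record but absent from ``ranges`` are ignored with a log entry.
    """
    by_marker = {r.marker: r for r in ranges}
    for name in record.values:
        if name not in by_marker:
            logger.info("%s: marker %r has no cut-off range, ignored", record.specimen_id, name)
    out: list[tuple[str, str]] = []
    for r in ranges:
        v = record.values.get(r.marker)
        if v is None:
            continue
        if r.low is not None and v < r.low:
            out.append((r.marker, "low"))
        elif r.high is not None and v > r.high:
            out.append((r.marker, "high"))
    return out


def derive_frame(frame: pd.DataFrame, defs: list[MarkerDefinition]) -> pd.DataFrame:
    """Vectorized ratio derivation over a cohort DataFrame (one row per newborn).

    Columns are measured marker names; derived ratio columns are added (rows
    with a zero denominator get NaN, the frame analogue of "absent").  Existing
    ratio columns are left untouched.
    """
    out = frame.copy()
    for d in defs:
        if d.kind != "ratio" or d.name in out.columns:
            continue
        if any(m not in out.columns for m in (*d.numerator, *d.denominator)):
            logger.warning("ratio %s not derived: operand column missing", d.name)
            continue
        num = sum(out[m] for m in d.numerator)
        den = sum(out[m] for m in d.denominator)
        out[d.name] = num.where(den != 0) / den.where(den != 0)
    return out
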