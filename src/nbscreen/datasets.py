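"""Loaders for the data shipped with nbscreen.

Shipped documents: the 74-indicator cut-off panel, the positive-rule table,
the per-case biochemical values and genotypes of the confirmed cases, the
canonical allele-count table of the mutation spectrum (118 alleles), and the
yearly screening volumes and confirmed-case counts of the five-year program
(300,849 newborns, 2016–2020).
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd

from .panel import (
    CutoffRange,
    MarkerDefinition,
    PanelRecord,
    compute_derived_markers,
    normalize_marker_name,
)

#: Genes pooled into one disease for spectrum denominators: hyperphenylalaninemia
#: comprises phenylalanine-hydroxylase and tetrahydrobiopterin-synthesis defects.
HPA_GROUP_MAP = {"PAH": "Hyperphenylalaninemia", "PTS": "Hyperphenylalaninemia"}

#: Total newborns screened over the five program years.
TOTAL_SCREENED = 300_849


def _data_path(name: str):
    return resources.files("nbscreen.data").joinpath(name)


def load_annual_screening() -> pd.DataFrame:
    """Yearly screened / suspected / recalled / confirmed counts (5 rows)."""
    return pd.read_csv(_data_path("annual_screening.tsv"), sep="\t")


def load_confirmed_counts() -> pd.DataFrame:
    """Confirmed-case counts by disorder with AAMD/OAMD/FAOD category (15 rows)."""
    return pd.read_csv(_data_path("confirmed_counts.tsv"), sep="\t")


def load_confirmed_cases() -> pd.DataFrame:
    """Per-case biochemical fixture: diagnosis, gene and printed abnormal markers.

    ``markers`` is parsed into a dict column ``marker_values``.  ``workup`` is
    "laboratory" for the 63 cases with full laboratory work-ups and "clinical"
    for the eight cases diagnosed clinically elsewhere.
    """
    df = pd.read_csv(_data_path("confirmed_cases.tsv"), sep="\t")

    def parse(cell: str) -> dict[str, float]:
        out = {}
        for part in str(cell).split(";"):
            name, _, val = part.rpartition("=")
            out[normalize_marker_name(name)] = float(val)
        return out

    df["marker_values"] = df["markers"].map(parse)
    return df


def load_genotypes() -> pd.DataFrame:
    """Genotypes of the sequenced confirmed cases (up to three detected alleles)."""
    return pd.read_csv(_data_path("genotypes.tsv"), sep="\t", dtype=str, keep_default_na=False)


def load_spectrum_counts() -> pd.DataFrame:
    """Canonical per-variant allele counts of the mutation spectrum (118 alleles)."""
    df = pd.read_csv(_data_path("spectrum_counts.tsv"), sep="\t", keep_default_na=False)
    df["count"] = df["count"].astype(int)
    return df


def reference_median(rng: CutoffRange, eps_floor: float = 0.001) -> float:
    """Typical (median) value of the reference population for one marker.

    The reference analytes are right-skewed, so the representative central
    value is the median of the lognormal calibrated to the reference bounds:
    the geometric mean ``sqrt(low * high)``.  A zero lower bound is replaced by
    ``min(high/1000, eps_floor)``, mirroring the cohort calibration.
    """
    low, high = rng.low, rng.high
    if high is None:
        raise ValueError(f"marker {rng.marker!r}: no upper bound")
    if low is None or low <= 0:
        low = min(high / 1000.0, eps_floor)
    return math.sqrt(low * high)


def reference_panel(
    defs: list[MarkerDefinition],
    ranges: list[CutoffRange],
    specimen_id: str = "reference",
) -> PanelRecord:
    """A fully normal panel with every measured marker at its reference median."""
    by_marker = {r.marker: r for r in ranges}
    values = {
        d.name: reference_median(by_marker[d.name]) for d in defs if d.kind != "ratio"
    }
    return compute_derived_markers(PanelRecord(specimen_id, values), defs)


def case_panel(
    marker_values: dict[str, float],
    defs: list[MarkerDefinition],
    ranges: list[CutoffRange],
    specimen_id: str = "case",
) -> PanelRecord:
    """Complete a confirmed case's printed abnormal values into a full panel.

    Unprinted measured markers are set to the reference median; ratios are then
    derived, except that a printed ratio value overrides the derived one (the
    printed ratio is the measurement of record even though its operands are
    unprinted).
    """
    by_marker = {r.marker: r for r in ranges}
    values: dict[str, float] = {}
    printed = {normalize_marker_name(k): float(v) for k, v in marker_values.items()}
    for d in defs:
        if d.kind == "ratio":
            continue
        values[d.name] = printed.get(d.name, reference_median(by_marker[d.name]))
    record = compute_derived_markers(PanelRecord(specimen_id, values), defs)
    for name, v in printed.items():
        record.values[name] = v
    return record
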