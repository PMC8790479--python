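"""Mutation-spectrum tabulation: allele counts and relative frequencies.

Each detected variant allele of a sequenced case contributes one count to its
``(gene, nucleotide variant)`` cell; missing allele slots contribute nothing
and apparent homozygotes count twice only when listed twice.  HGVS strings are
carried verbatim — grouping folds only case and whitespace (``C.51C > G`` and
``c.51C>G`` are the same allele), never normalizes nomenclature.  The
pathogenicity column (P / LP / VUS) is annotation carried through, never
computed.

Relative frequencies can pool genes into one disease denominator via a
gene → disease map; the shipped default pools *PAH* and *PTS* into
hyperphenylalaninemia, whose biochemical phenotype they share.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .errors import ReportError
from .report import _round_half_up


@dataclass(frozen=True)
class VariantAllele:
    nucleotide: str
    protein: str | None = None


@dataclass(frozen=True)
class GenotypeRecord:
    """Sequencing result of one case: up to three detected variant alleles."""

    case_id: str
    gene: str
    transcript: str | None
    alleles: tuple[VariantAllele, ...]

    def __post_init__(self) -> None:
        if not self.gene:
            raise ReportError(f"{self.case_id}: empty gene symbol")


def fold_variant(hgvs: str) -> str:
    """Grouping key for an HGVS string: lowercase, all whitespace removed."""
    return re.sub(r"\s+", "", hgvs).lower()


def records_from_frame(frame: pd.DataFrame) -> list[GenotypeRecord]:
    """Build genotype records from a table with allele{1,2,3}_{c,p} columns."""
    records = []
    for row in frame.itertuples(index=False):
        alleles = []
        for slot in (1, 2, 3):
            c = getattr(row, f"allele{slot}_c", "") or ""
            if not str(c).strip():
                continue
            p = getattr(row, f"allele{slot}_p", "") or ""
            alleles.append(VariantAllele(str(c).strip(), str(p).strip() or None))
        records.append(
            GenotypeRecord(
                case_id=str(row.case_id),
                gene=str(row.gene),
                transcript=str(getattr(row, "transcript", "") or "") or None,
                alleles=tuple(alleles),
            )
        )
    return records


def count_alleles(records: list[GenotypeRecord]) -> pd.DataFrame:
    """Detected-allele counts grouped by (gene, nucleotide variant).

    Returns columns ``gene, variant_c, variant_p, count`` sorted by gene, then
    count descending, then folded variant string.  The displayed HGVS string
    is the first-seen spelling of each folded group.
    """
    cells: dict[tuple[str, str], dict] = {}
    for rec in records:
        for allele in rec.alleles:
            key = (rec.gene, fold_variant(allele.nucleotide))
            cell = cells.setdefault(
                key,
                {
                    "gene": rec.gene,
                    "variant_c": allele.nucleotide,
                    "variant_p": allele.protein or "",
                    "count": 0,
                },
            )
            cell["count"] += 1
            if not cell["variant_p"] and allele.protein:
                cell["variant_p"] = allele.protein
    rows = sorted(
        cells.items(), key=lambda kv: (kv[0][0], -kv[1]["count"], kv[0][1])
    )
    return pd.DataFrame([v for _, v in rows], columns=["gene", "variant_c", "variant_p", "count"])


@dataclass
class SpectrumReport:
    """Per-variant, per-gene and per-disease allele accounting.

    ``within_percent`` columns use the disease denominator (the gene's own
    total unless the gene is pooled by the group map); ``total_percent``
    columns use the grand total of detected alleles.
    """

    variants: pd.DataFrame  # gene, group, variant_c, variant_p, count, within_percent, total_percent
    genes: pd.DataFrame     # gene, group, count, within_group_percent, total_percent
    groups: pd.DataFrame    # group, count, total_percent
    grand_total: int


def relative_frequencies(
    counts: pd.DataFrame, group_map: dict[str, str] | None = None
) -> SpectrumReport:
    """Compute the spectrum report from a (gene, variant, count) table.

    ``group_map`` maps gene symbols to a pooled disease label; unmapped genes
    form their own group.  All percentages are rounded half-up to 2 dp.
    """
    if len(counts) == 0 or counts["count"].sum() < 1:
        raise ReportError("empty allele-count table")
    group_map = group_map or {}
    df = counts.copy()
    df["group"] = df["gene"].map(lambda g: group_map.get(g, g))
    grand_total = int(df["count"].sum())
    group_totals = df.groupby("group")["count"].sum()
    df["within_percent"] = [
        _round_half_up(100.0 * c / group_totals[g], 2)
        for c, g in zip(df["count"], df["group"])
    ]
    df["total_percent"] = [
        _round_half_up(100.0 * c / grand_total, 2) for c in df["count"]
    ]
    genes = (
        df.groupby(["gene", "group"], as_index=False)["count"].sum()
        .sort_values("count", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    genes["within_group_percent"] = [
        _round_half_up(100.0 * c / group_totals[g], 2)
        for c, g in zip(genes["count"], genes["group"])
    ]
    genes["total_percent"] = [
        _round_half_up(100.0 * c / grand_total, 2) for c in genes["count"]
    ]
    groups = group_totals.sort_values(ascending=False, kind="stable").reset_index()
    groups["total_percent"] = [
        _round_half_up(100.0 * c / grand_total, 2) for c in groups["count"]
    ]
    cols = ["gene", "group", "variant_c"]
    if "variant_p" in df.columns:
        cols.append("variant_p")
    cols += ["count", "within_percent", "total_percent"]
    return SpectrumReport(
        variants=df[cols].reset_index(drop=True),
        genes=genes,
        groups=groups,
        grand_total=grand_total,
    )


def hotspot_summary(report: SpectrumReport, gene: str, top_k: int) -> pd.DataFrame:
    """Top-``k`` variants of a gene (or pooled disease) with cumulative percent.

    Variants are ranked by count descending, ties broken by the folded HGVS
    string; cumulative percent uses the gene's disease denominator, so pooled
    genes (e.g. *PAH* within hyperphenylalaninemia) are ranked against the
    pooled allele total.
    """
    v = report.variants
    sel = v[(v["gene"] == gene) | (v["group"] == gene)]
    if len(sel) == 0:
        raise ReportError(f"unknown gene or disease group {gene!r}")
    denominator = int(
        report.groups.set_index("group").loc[sel["group"].iloc[0], "count"]
    )
    sel = sel.assign(_key=sel["variant_c"].map(fold_variant)).sort_values(
        ["count", "_key"], ascending=[False, True], kind="stable"
    )
    out = sel.head(top_k).drop(columns="_key").reset_index(drop=True)
    cum = out["count"].cumsum()
    out["cumulative_percent"] = [
        _round_half_up(100.0 * c / denominator, 2) for c in cum
    ]
    return out
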