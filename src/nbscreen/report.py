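"""Incidence and proportion arithmetic of the screening program's summary tables.

An incidence is reported as ``"1:N"`` — one case per N newborns screened.  The
program's disorder-level table rounds N half away from zero (300,849 screened
with 2 cases prints ``1:150,425``), while its yearly report truncates
(59,439 screened with 20 confirmed prints ``1:2,971``); both modes are
supported, with half-up the default.  Percentages are rounded half-up to 2 dp.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .errors import ReportError

ROUNDINGS = ("half_up", "floor")


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def incidence_ratio(screened: int, cases: int, rounding: str = "half_up") -> str:
    """``"1:N"`` incidence string with thousands separators.

    ``N = screened / cases`` rounded per ``rounding`` ("half_up" or "floor").
    """
    if cases < 1:
        raise ReportError("incidence undefined for zero cases")
    if screened < cases:
        raise ReportError(f"screened ({screened}) < cases ({cases})")
    if rounding not in ROUNDINGS:
        raise ReportError(f"unknown rounding mode {rounding!r}")
    ratio = screened / cases
    n = int(ratio) if rounding == "floor" else int(_round_half_up(ratio))
    return f"1:{n:,}"


def parse_incidence_ratio(text: str) -> int:
    """Inverse of :func:`incidence_ratio`: ``"1:4,237"`` -> 4237."""
    head, _, tail = text.replace(" ", "").partition(":")
    if head != "1" or not tail:
        raise ReportError(f"not an incidence string: {text!r}")
    return int(tail.replace(",", ""))


def proportion(cases: int, total: int) -> float:
    """``100 * cases / total`` rounded half-up to 2 dp."""
    if total <= 0:
        raise ReportError("proportion undefined for zero total")
    if not 0 <= cases <= total:
        raise ReportError(f"cases ({cases}) outside [0, total={total}]")
    return _round_half_up(100.0 * cases / total, 2)


@dataclass(frozen=True)
class IncidenceEntry:
    """One row of the screening-results summary (disorder, category or total)."""

    label: str
    kind: str  # "disorder" | "category" | "total"
    cases: int
    screened: int
    ratio_n: int
    ratio_text: str
    percent_of_imds: float


def _entry(label: str, kind: str, cases: int, screened: int, total_confirmed: int) -> IncidenceEntry:
    text = incidence_ratio(screened, cases)
    return IncidenceEntry(
        label=label,
        kind=kind,
        cases=cases,
        screened=screened,
        ratio_n=parse_incidence_ratio(text),
        ratio_text=text,
        percent_of_imds=proportion(cases, total_confirmed),
    )


def build_summary(
    confirmed: list[tuple[str, str]], screened: int
) -> list[IncidenceEntry]:
    """Disorder, category and grand-total incidence entries.

    ``confirmed`` is one ``(disorder, category)`` pair per confirmed case.
    Output order: for each category in first-seen order, its disorder entries
    (first-seen order) then the category rollup; finally the grand total.
    Percentages use the total confirmed count as denominator.
    """
    if any(not cat for _, cat in confirmed):
        raise ReportError("every disorder must be mapped to a category")
    total_confirmed = len(confirmed)
    if total_confirmed == 0:
        raise ReportError("no confirmed cases")
    by_cat: dict[str, dict[str, int]] = {}
    for disorder, category in confirmed:
        by_cat.setdefault(category, {})
        by_cat[category][disorder] = by_cat[category].get(disorder, 0) + 1
    entries: list[IncidenceEntry] = []
    for category, disorders in by_cat.items():
        for disorder, cases in disorders.items():
            entries.append(_entry(disorder, "disorder", cases, screened, total_confirmed))
        entries.append(
            _entry(category, "category", sum(disorders.values()), screened, total_confirmed)
        )
    entries.append(_entry("Total", "total", total_confirmed, screened, total_confirmed))
    return entries


def summary_frame(entries: list[IncidenceEntry]) -> pd.DataFrame:
    """Tabular view of :func:`build_summary` output."""
    return pd.DataFrame(
        [
            {
                "label": e.label,
                "kind": e.kind,
                "cases": e.cases,
                "frequency": e.ratio_text,
                "percent_of_imds": e.percent_of_imds,
            }
            for e in entries
        ]
    )
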