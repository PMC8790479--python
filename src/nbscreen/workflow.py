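"""Two-tier screening workflow: screen → recall → retest → referral → confirmation.

First-screen positives split by triage: clear-aberrant newborns are referred
for confirmatory testing immediately; mild positives are recalled for a second
dried-blood-spot test with probability ``recall_prob`` (non-recalled newborns
are lost to follow-up and never diagnosed).  At retest a truly affected case
re-flags with probability ``tp_persist`` and an unaffected one with
``fp_persist``.  Referred cases undergo confirmatory testing, collapsed into a
single Bernoulli step: a truly affected case is diagnosed with probability
``confirm_sens``; confirmation is treated as perfectly specific, so unaffected
referred cases are always refuted.

Reported recall rates count directly-referred clear-aberrant newborns as
successfully recalled (they return for confirmatory sampling), matching the
program bookkeeping in which the recall denominator is all suspected
positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .report import incidence_ratio, proportion
from .rules import DisorderRule, TriagePolicy, evaluate_frame

logger = logging.getLogger(__name__)

_STAGES = ["screened", "suspected", "recalled", "retest_positive", "referred", "confirmed"]


@dataclass(frozen=True)
class WorkflowParams:
    """Stage probabilities of the two-tier flow (all in [0, 1])."""

    recall_prob: float = 1.0
    tp_persist: float = 1.0
    fp_persist: float = 1.0
    confirm_sens: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recall_prob", "tp_persist", "fp_persist", "confirm_sens"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class WorkflowOutcome:
    """Per-year funnel counts plus per-disorder confirmed counts."""

    by_year: pd.DataFrame  # one row per year, columns _STAGES
    confirmed_by_disorder: dict[str, int] = field(default_factory=dict)

    @property
    def totals(self) -> dict[str, int]:
        return {c: int(self.by_year[c].sum()) for c in _STAGES}

    def _check_funnel(self) -> None:
        t = self.totals
        assert t["screened"] >= t["suspected"] >= t["recalled"] >= t["retest_positive"]
        assert t["confirmed"] <= t["referred"] <= t["recalled"]


def run_two_tier(
    cohort: pd.DataFrame,
    rules: list[DisorderRule],
    params: WorkflowParams,
    policy: TriagePolicy = TriagePolicy(),
) -> WorkflowOutcome:
    """Push a screened cohort through the two-tier flow and tabulate per-year counts.

    ``cohort`` is a sampled cohort frame (derived ratio columns plus ``truth``
    and ``year``).  Reproducible under ``params.seed``.
    """
    if len(cohort) == 0:
        logger.warning("empty cohort: returning empty outcome")
        return WorkflowOutcome(
            by_year=pd.DataFrame(columns=["year", *_STAGES]).astype(int)
        )
    rng = np.random.default_rng(params.seed)
    screen = evaluate_frame(cohort, rules, policy)
    flagged = screen["flagged"].to_numpy()
    clear = screen["clear_aberrant"].to_numpy()
    affected = (cohort["truth"].to_numpy() != "") & ~pd.isna(cohort["truth"]).to_numpy()

    n = len(cohort)
    mild = flagged & ~clear
    recalled_mild = mild & (rng.random(n) < params.recall_prob)
    persist_p = np.where(affected, params.tp_persist, params.fp_persist)
    retest_positive = recalled_mild & (rng.random(n) < persist_p)
    referred = retest_positive | clear
    confirmed = referred & affected & (rng.random(n) < params.confirm_sens)
    recalled = recalled_mild | clear  # directly-referred cases count as recalled

    tab = pd.DataFrame(
        {
            "year": cohort["year"].to_numpy(),
            "screened": 1,
            "suspected": flagged.astype(int),
            "recalled": recalled.astype(int),
            "retest_positive": retest_positive.astype(int),
            "referred": referred.astype(int),
            "confirmed": confirmed.astype(int),
        }
    )
    by_year = tab.groupby("year", as_index=False).sum().sort_values("year")
    by_disorder = (
        pd.Series(cohort.loc[confirmed, "truth"]).value_counts().to_dict()
    )
    outcome = WorkflowOutcome(
        by_year=by_year.reset_index(drop=True),
        confirmed_by_disorder={str(k): int(v) for k, v in by_disorder.items()},
    )
    outcome._check_funnel()
    # perfect confirmatory specificity: diagnoses are a subset of the affected
    assert int(confirmed.sum()) == sum(outcome.confirmed_by_disorder.values())
    return outcome


def summarize_by_year(outcome: WorkflowOutcome) -> pd.DataFrame:
    """Program-style yearly report: recall rate (%) and confirmed frequency "1:N".

    Recall rate is ``100 * recalled / suspected`` to 2 dp (absent when nothing
    was suspected); frequency is ``1:floor(screened/confirmed)`` (absent when
    nothing was confirmed) — yearly reports truncate the ratio.  A totals row
    is appended.
    """
    rows = []
    years = outcome.by_year
    total = {c: int(years[c].sum()) for c in _STAGES}
    for rec in [*years.to_dict("records"), {"year": "Total", **total}]:
        suspected, screened = int(rec["suspected"]), int(rec["screened"])
        recalled, confirmed = int(rec["recalled"]), int(rec["confirmed"])
        rows.append(
            {
                "year": rec["year"],
                "screened": screened,
                "suspected": suspected,
                "recalled": recalled,
                "recall_rate": proportion(recalled, suspected) if suspected else None,
                "confirmed": confirmed,
                "frequency": (
                    incidence_ratio(screened, confirmed, rounding="floor")
                    if confirmed
                    else None
                ),
            }
        )
    return pd.DataFrame(rows)
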