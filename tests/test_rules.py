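"""Rule engine: loading, classification, triage, brute-force equivalence."""

import numpy as np
import pandas as pd
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

import nbscreen as nbs
from nbscreen.datasets import case_panel, reference_panel
from nbscreen.errors import ConfigError
from nbscreen.rules import COMPARATORS

from conftest import random_panels


class TestLoadRules:
    def test_pcd_row_groups(self, rules):
        pcd = next(r for r in rules if r.covers("PCD"))
        g1, g2 = pcd.groups
        assert [(c.marker, c.comparator, c.threshold) for c in g1.conditions] == [
            ("C0", "lt", 8.5)
        ]
        assert [(c.marker, c.comparator, c.threshold) for c in g2.conditions] == [
            ("C0", "lt", 9.0),
            ("(C0 + C2 + C3 + C16 + C18:1 + C18)/CIT", "le", 1.3),
        ]

    def test_hpa_row_has_three_groups(self, rules):
        hpa = next(r for r in rules if r.covers("HPA"))
        assert len(hpa.groups) == 3
        assert hpa.groups[1].conditions[0].threshold == 120

    def test_41_disorders_with_categories(self, rules):
        assert sum(len(r.disorders) for r in rules) == 41
        assert {r.category for r in rules} == {"AAMD", "OAMD", "FAOD"}

    def test_combined_row_carries_all_omim_codes(self, rules):
        mma = next(r for r in rules if r.covers("PA"))
        assert mma.covers("MMA") and len(mma.omim_codes) == 11

    def test_unknown_marker_rejected(self, defs, tmp_path):
        doc = {"rules": [{
            "label": "bogus", "category": "FAOD",
            "disorders": [{"name": "bogus", "abbrev": "B"}],
            "groups": [[{"marker": "C99", "op": "gt", "threshold": 1}]],
        }]}
        path = tmp_path / "bad.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigError, match="C99"):
            nbs.load_rules(path, defs)


class TestEvaluateRecord:
    def test_low_c0_flags_pcd(self, defs, ranges, rules):
        rec = case_panel({"C0": 5.15}, defs, ranges)
        flags = nbs.evaluate_record(rec, rules)
        pcd = [f for f in flags if "carnitine" in f.disorder_name.lower()]
        assert len(pcd) == 1 and pcd[0].satisfied_group_index == 0

    def test_high_phe_flags_hpa_via_single_marker_group(self, defs, ranges, rules):
        rec = case_panel({"PHE": 745.62}, defs, ranges)
        flags = nbs.evaluate_record(rec, rules)
        hpa = [f for f in flags if f.disorder_name == "Hyperphenylalaninemia"]
        assert len(hpa) == 1
        sat = {c.marker for c in hpa[0].conditions}
        assert "PHE" in sat

    def test_high_c4_flags_scadd(self, defs, ranges, rules):
        rec = case_panel({"C4": 1.46}, defs, ranges)
        flags = nbs.evaluate_record(rec, rules)
        assert any("Short-chain" in f.disorder_name for f in flags)

    def test_reference_panel_yields_no_flags(self, defs, ranges, rules):
        assert nbs.evaluate_record(reference_panel(defs, ranges), rules) == []

    def test_exact_threshold_not_satisfied_for_strict_comparator(self, defs, ranges, rules):
        # PHE exactly 100 with "PHE > 100": not positive
        rec = case_panel({"PHE": 100.0}, defs, ranges)
        assert not any(
            f.disorder_name == "Hyperphenylalaninemia"
            for f in nbs.evaluate_record(rec, rules)
        )

    def test_flags_sorted_and_margin_nonnegative(self, defs, ranges, rules):
        for rec in random_panels(defs, ranges, 20, seed=3):
            flags = nbs.evaluate_record(nbs.compute_derived_markers(rec, defs), rules)
            names = [f.disorder_name for f in flags]
            assert names == sorted(names)
            assert all(f.margin >= 0 for f in flags)


def _bruteforce_flags(record, rules):
    """Direct enumeration of every (disorder, group, condition)."""
    hits = {}
    for rule in rules:
        for gi, grp in enumerate(rule.groups):
            ok = True
            for cond in grp.conditions:
                v = record.values.get(cond.marker)
                if v is None or not COMPARATORS[cond.comparator](v, cond.threshold):
                    ok = False
                    break
            if ok:
                hits.setdefault(rule.label, gi)
                break
    return hits


def test_rule_engine_matches_bruteforce_enumeration(defs, ranges, rules):
    for rec in random_panels(defs, ranges, 100, seed=17, p_missing=0.05):
        rec = nbs.compute_derived_markers(rec, defs)
        expected = _bruteforce_flags(rec, rules)
        got = {f.disorder_name: f.satisfied_group_index for f in nbs.evaluate_record(rec, rules)}
        assert got == expected


def test_frame_evaluation_matches_record_evaluation(defs, ranges, rules):
    """The vectorized cohort path and the per-record path agree flag-for-flag."""
    recs = [
        nbs.compute_derived_markers(r, defs)
        for r in random_panels(defs, ranges, 50, seed=23)
    ]
    frame = pd.DataFrame([r.values for r in recs])
    res = nbs.evaluate_frame(frame, rules)
    for i, rec in enumerate(recs):
        expected = {f.disorder_name for f in nbs.evaluate_record(rec, rules)}
        got = {r.label for r in rules if res.iloc[i][r.label]}
        assert got == expected


@settings(derandomize=True, max_examples=40, deadline=None)
@given(factor=st.floats(min_value=1.0, max_value=50.0), seed=st.integers(0, 10_000))
def test_increasing_marker_never_unflags_gt_condition(factor, seed, defs, ranges, rules):
    """Monotonicity: raising the marker of a satisfied gt/ge condition keeps the flag."""
    (rec,) = random_panels(defs, ranges, 1, seed=seed)
    rec = nbs.compute_derived_markers(rec, defs)
    flags = nbs.evaluate_record(rec, rules)
    for flag in flags:
        for cond in flag.conditions:
            d = next(x for x in defs if x.name == cond.marker)
            if cond.comparator not in ("gt", "ge") or d.kind == "ratio":
                continue
            # only single-marker perturbations that cannot break sibling conditions
            group = next(r for r in rules if r.label == flag.disorder_name).groups[
                flag.satisfied_group_index
            ]
            if len(group.conditions) > 1:
                continue
            bumped = nbs.PanelRecord(
                rec.specimen_id,
                {**{k: v for k, v in rec.values.items()}, cond.marker: cond.value * factor},
            )
            again = nbs.evaluate_record(bumped, rules)
            assert any(f.disorder_name == flag.disorder_name for f in again)


class TestTriage:
    def test_no_flags_is_negative(self):
        assert nbs.triage([]) == "negative"

    def test_extreme_low_c0_is_clear_aberrant(self, defs, ranges, rules):
        rec = case_panel({"C0": 1.94}, defs, ranges)
        flags = nbs.evaluate_record(rec, rules)
        assert nbs.triage(flags, nbs.TriagePolicy(k=2.0)) == "clear_aberrant"

    def test_borderline_phe_is_mild_positive(self, defs, ranges):
        # PHE 105.43 with TYR low enough that group 1 (PHE>100 & PHE/TYR>=1.4) fires
        rules = nbs.load_rules(defs=defs)
        rec = case_panel({"PHE": 105.43, "TYR": 70.0}, defs, ranges)
        flags = nbs.evaluate_record(rec, rules)
        assert any(f.disorder_name == "Hyperphenylalaninemia" for f in flags)
        assert nbs.triage(flags, nbs.TriagePolicy(k=2.0)) == "mild_positive"

    def test_k_must_exceed_one(self):
        with pytest.raises(ConfigError):
            nbs.TriagePolicy(k=1.0)

    def test_lower_tailed_clear_boundary(self, defs, ranges, rules):
        # C0 = 4.3 > 8.5/2: flagged but not clear; C0 = 4.2 < 4.25: clear
        mild = nbs.evaluate_record(case_panel({"C0": 4.3}, defs, ranges), rules)
        clear = nbs.evaluate_record(case_panel({"C0": 4.2}, defs, ranges), rules)
        assert nbs.triage(mild) == "mild_positive"
        assert nbs.triage(clear) == "clear_aberrant"
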