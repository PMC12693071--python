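"""Resistance-CNV calling: gene ratios, AR-specific and preexisting calls."""

import numpy as np
import pandas as pd
import pytest

from sccnv.resistance import (GeneRatioMatrix, annotate_function,
                              call_ar_specific, call_preexisting,
                              gene_ratio_matrix)


def make_grm(ratios: dict, baseline: list, resistant: list):
    return GeneRatioMatrix(ratios=pd.DataFrame(ratios).T,
                           baseline=baseline, resistant=resistant)


class TestGeneRatioMatrix:
    def _inputs(self):
        cells = [f"c{i}" for i in range(6)]
        ratios = pd.DataFrame(
            np.ones((6, 4)), index=cells, columns=range(4))
        ratios.iloc[:3, 2] = [0.8, 1.0, 1.2]   # subclone A at bin 2
        ratios.iloc[3:, 2] = 1.4               # subclone B at bin 2
        labels = pd.Series(["A"] * 3 + ["B"] * 3, index=cells)
        gene_map = pd.DataFrame({"gene": ["g"], "chrom": ["chr1"],
                                 "start": [0], "end": [1], "bins": [[2]]})
        dominance = pd.Series({"A": "baseline", "B": "resistant"})
        return ratios, labels, gene_map, dominance

    def test_median_of_medians(self):
        ratios, labels, gene_map, dominance = self._inputs()
        grm = gene_ratio_matrix(ratios, labels, gene_map, dominance)
        assert grm.ratios.loc["g", "A"] == pytest.approx(1.0)
        assert grm.ratios.loc["g", "B"] == pytest.approx(1.4)

    def test_cell_order_invariant(self):
        ratios, labels, gene_map, dominance = self._inputs()
        a = gene_ratio_matrix(ratios, labels, gene_map, dominance)
        perm = ratios.sample(frac=1, random_state=0)
        b = gene_ratio_matrix(perm, labels.loc[perm.index], gene_map,
                              dominance)
        pd.testing.assert_frame_equal(a.ratios, b.ratios)


class TestCallArSpecific:
    def test_amplified_above_baseline_max_plus_margin(self):
        grm = make_grm({"g": {"b1": 1.00, "b2": 1.02, "r1": 1.15}},
                       ["b1", "b2"], ["r1"])
        calls = call_ar_specific(grm)
        assert len(calls) == 1
        assert calls[0].direction == "amplified"
        assert calls[0].calling_subclones == ["r1"]

    def test_high_baseline_cv_gene_ineligible(self):
        grm = make_grm({"g": {"b1": 0.7, "b2": 1.3, "r1": 2.0}},
                       ["b1", "b2"], ["r1"])
        assert call_ar_specific(grm) == []

    def test_margin_is_strict(self):
        # exceeds baseline max by exactly 0.08 < 0.09: no call
        grm = make_grm({"g": {"b1": 1.00, "b2": 1.02, "r1": 1.10}},
                       ["b1", "b2"], ["r1"])
        assert call_ar_specific(grm) == []

    def test_deleted_below_baseline_min_minus_margin(self):
        grm = make_grm({"g": {"b1": 1.00, "b2": 0.98, "r1": 0.85}},
                       ["b1", "b2"], ["r1"])
        calls = call_ar_specific(grm)
        assert calls[0].direction == "deleted"

    def test_privacy_flag(self):
        grm = make_grm({"g": {"b1": 1.0, "r1": 1.3, "r2": 1.0}},
                       ["b1"], ["r1", "r2"])
        assert call_ar_specific(grm)[0].privacy == "private"
        grm2 = make_grm({"g": {"b1": 1.0, "r1": 1.3, "r2": 1.3}},
                        ["b1"], ["r1", "r2"])
        assert call_ar_specific(grm2)[0].privacy == "shared"

    def test_no_baseline_subclones_rejected(self):
        grm = make_grm({"g": {"r1": 1.3}}, [], ["r1"])
        with pytest.raises(ValueError):
            call_ar_specific(grm)


class TestCallPreexisting:
    def test_hand_computed_amplified_pair(self):
        # baseline {1.0, 1.0, 1.6}: CV ~= 0.27 > 0.18, z(b3) ~= 1.41 > 1;
        # AR at 1.6 and candidate at 1.6 both exceed non-candidate max 1.0
        # by 0.6 > 0.09
        grm = make_grm({"g": {"b1": 1.0, "b2": 1.0, "b3": 1.6, "r1": 1.6}},
                       ["b1", "b2", "b3"], ["r1"])
        cv = grm.baseline_cv["g"]
        assert cv == pytest.approx(np.sqrt(0.08) / 1.2, abs=1e-4)
        calls = call_preexisting(grm)
        assert len(calls) == 1
        assert calls[0].preexisting_in == ["b3"]
        assert calls[0].direction == "amplified"

    def test_low_cv_gene_not_a_candidate(self):
        grm = make_grm({"g": {"b1": 1.0, "b2": 1.05, "b3": 1.1,
                              "r1": 1.6}},
                       ["b1", "b2", "b3"], ["r1"])
        assert call_preexisting(grm) == []

    def test_both_margin_criteria_required(self):
        # candidate at 1.2: criterion 1 (AR 1.6 > 1.0+0.09) and criterion 2
        # (1.2 > 1.0+0.09) both hold
        grm = make_grm({"g": {"b1": 1.0, "b2": 1.0, "b3": 1.0, "b4": 2.0,
                              "r1": 1.6}},
                       ["b1", "b2", "b3", "b4"], ["r1"])
        calls = call_preexisting(grm)
        assert calls and calls[0].preexisting_in == ["b4"]
        # candidate fails criterion 2: deviates but in the other direction
        grm2 = make_grm({"g": {"b1": 1.0, "b2": 1.0, "b3": 1.0, "b4": 0.2,
                               "r1": 1.6}},
                        ["b1", "b2", "b3", "b4"], ["r1"])
        amp = [c for c in call_preexisting(grm2)
               if c.direction == "amplified"]
        assert amp == []

    def test_needs_three_baseline_subclones(self):
        grm = make_grm({"g": {"b1": 1.0, "b2": 1.6, "r1": 1.6}},
                       ["b1", "b2"], ["r1"])
        with pytest.raises(ValueError):
            call_preexisting(grm)


def test_eligibility_branches_partition_genes():
    """No gene is evaluated by both branches (CV gate < vs >)."""
    rng = np.random.default_rng(8)
    base_cols = ["b1", "b2", "b3"]
    data = {}
    for i in range(30):
        base = 1.0 + rng.normal(0, rng.choice([0.01, 0.4]), 3)
        data[f"g{i}"] = dict(zip(base_cols, np.abs(base) + 0.1),
                             r1=float(rng.uniform(0.3, 2.0)))
    grm = make_grm(data, base_cols, ["r1"])
    ar_genes = {c.gene for c in call_ar_specific(grm)}
    pre_genes = {c.gene for c in call_preexisting(grm)}
    assert ar_genes.isdisjoint(pre_genes)
    cvs = grm.baseline_cv
    assert all(cvs[g] < 0.18 for g in ar_genes)
    assert all(cvs[g] > 0.18 for g in pre_genes)


def test_calls_invariant_to_subclone_relabeling():
    grm = make_grm({"g1": {"b1": 1.0, "b2": 1.02, "r1": 1.2, "r2": 1.0},
                    "g2": {"b1": 1.0, "b2": 0.98, "r1": 0.8, "r2": 0.8}},
                   ["b1", "b2"], ["r1", "r2"])
    ren = {"b1": "x2", "b2": "x1", "r1": "y2", "r2": "y1"}
    grm2 = GeneRatioMatrix(grm.ratios.rename(columns=ren),
                           ["x2", "x1"], ["y2", "y1"])
    calls1 = {(c.gene, c.direction, frozenset(ren[s] for s in
                                              c.calling_subclones))
              for c in call_ar_specific(grm)}
    calls2 = {(c.gene, c.direction, frozenset(c.calling_subclones))
              for c in call_ar_specific(grm2)}
    assert calls1 == calls2


class TestAnnotateFunction:
    EVIDENCE = pd.DataFrame({
        "gene": ["gdel", "gamp"],
        "direction": ["resister", "sensitizer"],
        "weight": [3, 2],
    })

    def test_deleted_call_gets_resister_weight(self):
        grm = make_grm({"gdel": {"b1": 1.0, "r1": 0.8}}, ["b1"], ["r1"])
        calls = annotate_function(call_ar_specific(grm), self.EVIDENCE)
        assert calls[0].evidence_weight == 3

    def test_absent_gene_weight_zero_call_retained(self):
        grm = make_grm({"novel": {"b1": 1.0, "r1": 1.3}}, ["b1"], ["r1"])
        calls = annotate_function(call_ar_specific(grm), self.EVIDENCE)
        assert calls[0].evidence_weight == 0

    def test_semicolon_label_for_opposite_directions(self):
        grm = make_grm({"g": {"b1": 1.0, "c2": 1.3, "c5": 0.8}},
                       ["b1"], ["c2", "c5"])
        calls = annotate_function(call_ar_specific(grm), self.EVIDENCE)
        labels = {c.report_label for c in calls}
        assert labels == {"c2:amplified;c5:deleted"}
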