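"""Recovery scoring against planted ground truth.

Shared by the test suite and the reproduction script: given a pipeline run
on a synthetic dataset, score subclone recovery (count, adjusted Rand
index, consensus-profile bin accuracy), diploid-cell recall, planted-clade
recovery, segmentation breakpoint localization, and resistance-call
precision/recall.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cnv import BinGrid, segment
from .pipeline import PipelineResult
from .resistance import call_ar_specific, call_preexisting
from .subclones import NOISE
from .synthetic import GroundTruth, simulate_gene_ratio_matrix

__all__ = ["score_pipeline", "breakpoint_recovery_rate",
           "resistance_recovery"]


def score_pipeline(result: PipelineResult, truth: GroundTruth) -> dict:
    """Recovery metrics of one pipeline run against its ground truth."""
    labels = result.subclones.labels
    assigned = labels[labels != NOISE]
    true_for_assigned = truth.cell_subclone.loc[assigned.index]
    ari = adjusted_rand_score(true_for_assigned, assigned)

    # consensus accuracy: map each discovered subclone to the planted
    # subclone contributing most of its members
    accs = []
    for name in result.subclones.names:
        members = labels.index[labels == name]
        planted_name = truth.cell_subclone.loc[members].mode()[0]
        if planted_name == "diploid":
            planted = np.full(len(result.subclones.consensus_integer), 2)
        else:
            planted = truth.profiles[planted_name].to_numpy()
        found = result.subclones.consensus_integer[name].to_numpy()
        accs.append(float((found == planted).mean()))

    report = result.qc_report
    dip_seen = [c for c in truth.diploid_cells
                if c in report.index and report.loc[c, "passed_basic"]]
    dip_recall = (float(report.loc[dip_seen, "is_diploid"].mean())
                  if dip_seen else float("nan"))
    aneu_seen = [c for c in report.index[report["passed_basic"]]
                 if truth.cell_subclone[c] != "diploid"]
    dip_fpr = (float(report.loc[aneu_seen, "is_diploid"].mean())
               if aneu_seen else float("nan"))

    out = {
        "n_subclones_found": len(result.subclones.names),
        "n_subclones_planted": truth.profiles.shape[1],
        "ari": float(ari),
        "consensus_accuracy": float(np.mean(accs)),
        "consensus_accuracy_min": float(np.min(accs)),
        "diploid_recall": dip_recall,
        "diploid_false_positive_rate": dip_fpr,
    }
    if result.tree is not None and truth.planted_newick:
        # resistant clade recovered iff the discovered subclones that map to
        # planted resistant subclones form one clade
        res_planted = _resistant_subclones(truth)
        mapped = set()
        for name in result.subclones.names:
            members = labels.index[labels == name]
            if truth.cell_subclone.loc[members].mode()[0] in res_planted:
                mapped.add(name)
        out["resistant_clade_recovered"] = float(
            frozenset(mapped) in result.tree.clade_leaf_sets())
    return out


def _resistant_subclones(truth: GroundTruth) -> set:
    return {n for n, g in truth.subclone_group.items() if g == "resistant"}


def breakpoint_recovery_rate(n_reps: int = 100, seed: int = 0,
                             n_bins: int = 200, break_at: int = 100,
                             step: float = 0.5, noise_sd: float = 0.05,
                             tol_bins: int = 1) -> float:
    """Fraction of replicates localizing a planted step within +/- tol bins.

    One chromosome of ``n_bins`` uniform bins, signal 1.0 before the
    breakpoint and 1.0 + step after, Gaussian noise.
    """
    grid = BinGrid(pd.DataFrame({
        "chrom": ["chr1"] * n_bins,
        "start": np.arange(n_bins) * 1000,
        "end": (np.arange(n_bins) + 1) * 1000,
        "gc": 0.45,
    }))
    hits = 0
    master = np.random.default_rng(seed)
    for _ in range(n_reps):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        x = np.concatenate([np.full(break_at, 1.0),
                            np.full(n_bins - break_at, 1.0 + step)])
        x += rng.normal(0, noise_sd, n_bins)
        table, _ = segment(x, grid, rng=rng)
        starts = sorted(table["start_bin"])[1:]  # interior breakpoints
        if any(abs(s - break_at) <= tol_bins for s in starts):
            hits += 1
    return hits / n_reps


def resistance_recovery(n_seeds: int = 100, seed: int = 0, **sim_kw) -> dict:
    """Pooled precision/recall of the resistance-call classifiers.

    Runs ``simulate_gene_ratio_matrix`` for ``n_seeds`` replicates and
    scores call_ar_specific (gene+direction level) and call_preexisting
    ((gene, subclone, direction) pairs).
    """
    master = np.random.default_rng(seed)
    tp = fp = fn = 0
    pre_found = pre_planted = pre_false = 0
    max_false_pairs = 0
    for _ in range(n_seeds):
        rep_seed = int(master.integers(2**31 - 1))
        grm, truth = simulate_gene_ratio_matrix(seed=rep_seed, **sim_kw)
        calls = call_ar_specific(grm)
        called = {(c.gene, c.direction) for c in calls}
        planted = {(g, d) for d in ("amplified", "deleted")
                   for g in truth[d]}
        tp += len(called & planted)
        fp += len(called - planted)
        fn += len(planted - called)

        pre_calls = call_preexisting(grm)
        pairs = {(c.gene, s, c.direction) for c in pre_calls
                 for s in c.preexisting_in}
        pre_found += len(pairs & truth["preexisting"])
        pre_planted += len(truth["preexisting"])
        n_false = len(pairs - truth["preexisting"])
        pre_false += n_false
        max_false_pairs = max(max_false_pairs, n_false)
    return {
        "ar_precision": tp / (tp + fp) if tp + fp else float("nan"),
        "ar_recall": tp / (tp + fn) if tp + fn else float("nan"),
        "preexisting_recall": pre_found / pre_planted,
        "preexisting_false_pairs_mean": pre_false / n_seeds,
        "preexisting_false_pairs_max": max_false_pairs,
        "n_seeds": n_seeds,
    }
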