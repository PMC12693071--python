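"""Bulk-cohort integration: recurrent relapse-specific CNV genes, CRISPR
screen collation, set overlap, and pairwise Fisher co-occurrence.

A gene is *DP-specific* in a patient when it is altered (in a given
direction) in at least one disease-progression (DP) tumor and in none of the
patient-matched baseline tumors; it is *recurrent* when DP-specific in at
least ``min_patients`` patients (3 for cataloging, 4 for enrichment input).
Screen hits become resister/sensitizer genes with concordant evidence in at
least two independent measurements.  Pairwise co-occurrence across patients
is tested with a two-sided Fisher's exact test (implemented from the
hypergeometric distribution, maftools-style) with Benjamini-Hochberg FDR
control; the display convention highlights pairs with p < 0.05 and odds
ratio > 1.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = ["dp_specific_recurrent", "collate_screen_hits", "overlap",
           "fisher_exact_2x2", "cooccurrence"]


def dp_specific_recurrent(table: pd.DataFrame, alteration: str,
                          min_patients: int = 3
                          ) -> pd.Series:
    """Genes altered DP-specifically in >= ``min_patients`` patients.

    ``table`` columns: patient, gene, alteration, compartment
    (baseline | DP); multiple tumors per compartment are unioned per
    patient.  Returns a Series gene -> patient count, restricted to genes
    meeting the recurrence floor.
    """
    t = table[table["alteration"] == alteration]
    counts: dict[str, int] = {}
    for patient, sub in t.groupby("patient"):
        has_baseline = (table[table["patient"] == patient]["compartment"]
                        == "baseline").any()
        if not has_baseline:
            warnings.warn(f"patient {patient} has no baseline tumor; "
                          "excluded from recurrence counting")
            continue
        dp_genes = set(sub.loc[sub["compartment"] == "DP", "gene"])
        base_genes = set(sub.loc[sub["compartment"] == "baseline", "gene"])
        for g in dp_genes - base_genes:
            counts[g] = counts.get(g, 0) + 1
    s = pd.Series(counts, dtype=int).sort_index()
    return s[s >= min_patients]


def collate_screen_hits(hits: pd.DataFrame, min_evidence: int = 2
                        ) -> tuple[pd.Series, pd.Series]:
    """Resister and sensitizer gene sets with per-gene evidence weights.

    ``hits`` columns: gene, screen, direction (resister | sensitizer),
    measurement.  A gene enters a direction's set when that direction is
    supported by >= ``min_evidence`` measurements; the weight is the
    measurement count.  A gene with enough evidence in both directions
    appears in both sets (conflicts are kept, not resolved).
    """
    weights = (hits.groupby(["gene", "direction"])["measurement"]
               .nunique())
    res = weights.xs("resister", level="direction") \
        if "resister" in weights.index.get_level_values(1) else pd.Series(
            dtype=int)
    sen = weights.xs("sensitizer", level="direction") \
        if "sensitizer" in weights.index.get_level_values(1) else pd.Series(
            dtype=int)
    return (res[res >= min_evidence].sort_index(),
            sen[sen >= min_evidence].sort_index())


def overlap(set_a, set_b, patient_counts: pd.Series | None = None
            ) -> pd.DataFrame:
    """Exact intersection of two gene sets, with optional patient counts."""
    common = sorted(set(set_a) & set(set_b))
    out = pd.DataFrame({"gene": common})
    if patient_counts is not None:
        out["n_patients"] = [int(patient_counts.get(g, 0)) for g in common]
    return out


def _log_hyper_pmf(a: int, r1: int, r2: int, c1: int) -> float:
    """log P(table) for fixed margins under the hypergeometric null."""
    n = r1 + r2
    return (gammaln(r1 + 1) - gammaln(a + 1) - gammaln(r1 - a + 1)
            + gammaln(r2 + 1) - gammaln(c1 - a + 1)
            - gammaln(r2 - c1 + a + 1)
            - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1)))


def fisher_exact_2x2(a: int, b: int, c: int, d: int
                     ) -> tuple[float, float]:
    """Two-sided Fisher's exact test from the hypergeometric definition.

    Returns (p, odds ratio).  p sums the probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (with a 1+1e-7 relative tolerance against rounding, as in R).
    The odds ratio is a*d / (b*c), ``inf`` when b*c == 0 with a*d > 0 and
    ``nan`` for an all-zero table (p = 1, OR undefined).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0, math.nan
    r1, c1 = a + b, a + c
    r2 = c + d
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = _log_hyper_pmf(a, r1, r2, c1)
    p = 0.0
    for k in range(lo, hi + 1):
        lp = _log_hyper_pmf(k, r1, r2, c1)
        if lp <= obs + 1e-7:
            p += math.exp(lp)
    p = min(p, 1.0)
    if b * c == 0:
        orr = math.inf if a * d > 0 else math.nan
    else:
        orr = (a * d) / (b * c)
    return p, orr


@dataclass
class CooccurrenceResult:
    gene_a: str
    gene_b: str
    table: tuple[int, int, int, int]  # (both, a_only, b_only, neither)
    odds_ratio: float
    p: float
    q: float = math.nan

    @property
    def cooccurring(self) -> bool:
        """Display rule: p < 0.05 and odds ratio > 1."""
        return self.p < 0.05 and self.odds_ratio > 1


def cooccurrence(alterations: pd.DataFrame, genes: list[str] | None = None,
                 ) -> list[CooccurrenceResult]:
    """Pairwise patient-level co-occurrence with BH-adjusted q-values.

    ``alterations`` columns: patient, gene (one row per altered
    gene/patient; direction-agnostic).  For every gene pair a 2x2 table over
    the patient cohort (altered/not x altered/not) feeds the exact test;
    q-values are BH-adjusted over all tested pairs.
    """
    patients = sorted(alterations["patient"].unique())
    by_gene = {g: set(sub["patient"])
               for g, sub in alterations.groupby("gene")}
    if genes is None:
        genes = sorted(by_gene)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    n = len(patients)
    results = []
    for ga, gb in itertools.combinations(genes, 2):
        pa, pb = by_gene.get(ga, set()), by_gene.get(gb, set())
        both = len(pa & pb)
        a_only = len(pa) - both
        b_only = len(pb) - both
        neither = n - both - a_only - b_only
        p, orr = fisher_exact_2x2(both, a_only, b_only, neither)
        results.append(CooccurrenceResult(ga, gb,
                                          (both, a_only, b_only, neither),
                                          orr, p))
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
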