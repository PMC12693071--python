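"""Resistance-CNV calling: AR-specific, subclone-private, preexisting genes.

The classifier works on a genes x subclones matrix of median copy-number
ratios ("the ratio"): for each gene and subclone, the median over member
cells of the median bin ratio across the gene's bins.

Two mutually exclusive branches, gated on the coefficient of variation (CV
= sd/mean) of the gene's ratios across baseline-dominant subclones:

* CV < 0.18 (stable baseline) -> ``call_ar_specific``: the gene is
  amplified when some resistant-dominant subclone exceeds the baseline
  maximum ratio by more than 0.09, deleted when below the baseline minimum
  by more than 0.09.  Calls made by a strict subset of resistant-dominant
  subclones are *private*.
* CV > 0.18 (a baseline subclone deviates) -> ``call_preexisting``:
  baseline-dominant subclones with |z| > 1 across baseline ratios are
  candidates; a (gene, candidate) pair is confirmed when BOTH a
  resistant-dominant subclone AND the candidate itself exceed (amplified) /
  fall below (deleted) the extreme ratio of the non-candidate baseline
  subclones by more than the 0.09 margin.

Genes with CV exactly equal to the gate fall in neither branch.  Calls are
functionalized against CRISPR-screen evidence: deleted genes pick up
resister weights, amplified genes sensitizer weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PipelineParams, DEFAULT_PARAMS

__all__ = ["GeneRatioMatrix", "ResistanceCall", "gene_ratio_matrix",
           "call_ar_specific", "call_preexisting", "annotate_function"]

log = logging.getLogger(__name__)


@dataclass
class GeneRatioMatrix:
    ratios: pd.DataFrame        # genes x subclones
    baseline: list[str]         # baseline-dominant subclone names
    resistant: list[str]        # resistant-dominant subclone names

    @property
    def baseline_cv(self) -> pd.Series:
        """Per-gene CV of ratios across baseline-dominant subclones.

        Population (n-denominator) standard deviation over mean.
        """
        sub = self.ratios[self.baseline]
        return (sub.std(axis=1, ddof=0) / sub.mean(axis=1)).rename("cv")


@dataclass
class ResistanceCall:
    gene: str
    direction: str                       # amplified | deleted
    calling_subclones: list[str]
    privacy: str                         # shared | private
    preexisting_in: list[str] = field(default_factory=list)
    evidence_weight: int = 0
    report_label: str = ""


def gene_ratio_matrix(ratios: pd.DataFrame, labels: pd.Series,
                      gene_map: pd.DataFrame,
                      dominance: pd.Series) -> GeneRatioMatrix:
    """Median copy-number ratio per gene per subclone.

    ``ratios`` is cells x bins, ``labels`` maps cell to subclone,
    ``gene_map`` carries a ``bins`` column (grid bin indices per gene), and
    ``dominance`` maps subclone to baseline/resistant/none.  Genes covered
    by no bin are dropped with a warning.
    """
    subclones = [s for s in dominance.index]
    cells_by_sub = {s: labels.index[labels == s] for s in subclones}
    mat = ratios.to_numpy(float)
    cell_pos = {c: i for i, c in enumerate(ratios.index)}

    rows, genes = [], []
    for _, row in gene_map.iterrows():
        bins = row["bins"]
        if len(bins) == 0:
            log.warning("gene %s covered by no bins; dropped", row["gene"])
            continue
        genes.append(row["gene"])
        entry = []
        for s in subclones:
            idx = [cell_pos[c] for c in cells_by_sub[s]]
            per_cell = np.median(mat[np.ix_(idx, list(bins))], axis=1)
            entry.append(float(np.median(per_cell)))
        rows.append(entry)
    table = pd.DataFrame(rows, index=genes, columns=subclones)
    return GeneRatioMatrix(
        ratios=table,
        baseline=[s for s in subclones if dominance[s] == "baseline"],
        resistant=[s for s in subclones if dominance[s] == "resistant"],
    )


def call_ar_specific(grm: GeneRatioMatrix,
                     cv_max: float = DEFAULT_PARAMS.gene_cv_max,
                     margin: float = DEFAULT_PARAMS.ratio_margin
                     ) -> list[ResistanceCall]:
    """AR/recurrence-specific amplified and deleted gene calls.

    Eligibility: baseline CV strictly below ``cv_max``.  A call requires a
    resistant-dominant subclone ratio beyond the baseline extreme by
    strictly more than ``margin``.
    """
    if not grm.baseline:
        raise ValueError("no baseline-dominant subclones")
    if not grm.resistant:
        raise ValueError("no resistant-dominant subclones")
    cvs = grm.baseline_cv
    calls: list[ResistanceCall] = []
    n_res = len(grm.resistant)
    for gene, row in grm.ratios.iterrows():
        if not cvs[gene] < cv_max:
            continue
        base_max = row[grm.baseline].max()
        base_min = row[grm.baseline].min()
        amp = [s for s in grm.resistant if row[s] > base_max + margin]
        dele = [s for s in grm.resistant if row[s] < base_min - margin]
        for direction, subs in (("amplified", amp), ("deleted", dele)):
            if subs:
                calls.append(ResistanceCall(
                    gene=gene, direction=direction, calling_subclones=subs,
                    privacy="private" if len(subs) < n_res else "shared"))
    return calls


def call_preexisting(grm: GeneRatioMatrix,
                     cv_min: float = DEFAULT_PARAMS.gene_cv_max,
                     z_threshold: float = DEFAULT_PARAMS.z_threshold,
                     margin: float = DEFAULT_PARAMS.ratio_margin
                     ) -> list[ResistanceCall]:
    """(gene, baseline subclone) preexistence calls.

    Z-scores use the population standard deviation across baseline-dominant
    subclone ratios.  Needs at least three baseline-dominant subclones so
    that candidates leave a non-candidate reference.
    """
    if len(grm.baseline) < 3:
        raise ValueError("preexistence calling needs >= 3 baseline-dominant "
                         "subclones")
    cvs = grm.baseline_cv
    calls: list[ResistanceCall] = []
    for gene, row in grm.ratios.iterrows():
        if not cvs[gene] > cv_min:
            continue
        base = row[grm.baseline]
        sd = base.std(ddof=0)
        if sd == 0:
            continue
        z = (base - base.mean()) / sd
        candidates = [s for s in grm.baseline
                      if abs(z[s]) > z_threshold]
        noncand = [s for s in grm.baseline if s not in candidates]
        if not candidates:
            continue
        if not noncand:
            log.warning("gene %s: every baseline subclone is a candidate; "
                        "no reference, skipped", gene)
            continue
        ref_max = row[noncand].max()
        ref_min = row[noncand].min()
        for direction, ref, sign in (("amplified", ref_max, 1),
                                     ("deleted", ref_min, -1)):
            ar_ok = [s for s in grm.resistant
                     if sign * (row[s] - ref) > margin]
            if not ar_ok:
                continue
            confirmed = [s for s in candidates
                         if sign * (row[s] - ref) > margin]
            if confirmed:
                calls.append(ResistanceCall(
                    gene=gene, direction=direction,
                    calling_subclones=ar_ok, privacy="private",
                    preexisting_in=confirmed))
    return calls


def annotate_function(calls: list[ResistanceCall],
                      screen_evidence: pd.DataFrame) -> list[ResistanceCall]:
    """Attach screen-evidence weights and build report labels.

    ``screen_evidence`` has columns gene, direction (resister|sensitizer),
    weight.  Deleted calls match resister evidence, amplified calls
    sensitizer evidence; absent genes keep weight 0.  When one gene is
    amplified in some subclones and deleted in others, the report label
    separates the two subclone groups with a semicolon.
    """
    weights = {(r["gene"], r["direction"]): int(r["weight"])
               for _, r in screen_evidence.iterrows()}
    match = {"deleted": "resister", "amplified": "sensitizer"}
    by_gene: dict[str, list[ResistanceCall]] = {}
    for call in calls:
        call.evidence_weight = weights.get(
            (call.gene, match[call.direction]), 0)
        by_gene.setdefault(call.gene, []).append(call)
    for gene_calls in by_gene.values():
        parts = [f"{','.join(c.calling_subclones)}:{c.direction}"
                 for c in gene_calls]
        label = ";".join(parts)
        for c in gene_calls:
            c.report_label = label
    return calls
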