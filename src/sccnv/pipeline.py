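"""End-to-end single-cell CNV pipeline.

``run_pipeline`` takes a cells x bins count matrix, the bin grid, a sample
sheet and per-sample DAPI peak medians and runs: GC normalization ->
bin ratios -> segmentation -> three-stage QC -> UMAP + density clustering
into subclones -> consensus integer profiles (DAPI-scaled) -> diploid-rooted
minimum-event-distance tree -> (optionally, given a gene map) AR-specific /
preexisting resistance calls with screen-evidence annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qc as qc_mod
from .cnv import (BinGrid, compute_ratios, estimate_ploidy, gc_normalize,
                  integer_cn, segment)
from .params import PipelineParams, DEFAULT_PARAMS
from .phylogeny import CloneTree, build_tree
from .resistance import (ResistanceCall, annotate_function, call_ar_specific,
                         call_preexisting, gene_ratio_matrix)
from .subclones import SubcloneSet, discover_subclones

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    qc_report: pd.DataFrame
    ratios: pd.DataFrame            # retained cells x bins
    segment_ratios: pd.DataFrame    # retained cells x bins
    integer_cn: pd.DataFrame        # retained cells x bins
    ploidy: dict                    # sample -> DAPI-derived ploidy
    subclones: SubcloneSet
    tree: CloneTree | None = None
    ar_calls: list[ResistanceCall] = field(default_factory=list)
    preexisting_calls: list[ResistanceCall] = field(default_factory=list)


def _profile_cells(counts: pd.DataFrame, grid: BinGrid,
                   params: PipelineParams,
                   rng: np.random.Generator) -> tuple[pd.DataFrame,
                                                      pd.DataFrame]:
    ratios = np.empty((len(counts), len(grid)))
    seg = np.empty_like(ratios)
    for i, (_, row) in enumerate(counts.iterrows()):
        norm = gc_normalize(row.to_numpy(float), grid.gc,
                            span=params.lowess_span,
                            iters=params.lowess_iters)
        ratios[i] = compute_ratios(norm)
        _, seg[i] = segment(ratios[i], grid, alpha=params.cbs_alpha,
                            min_width=params.cbs_min_width,
                            n_perm=params.cbs_n_perm, rng=rng)
    idx = counts.index
    return (pd.DataFrame(ratios, index=idx, columns=counts.columns),
            pd.DataFrame(seg, index=idx, columns=counts.columns))


def run_pipeline(counts: pd.DataFrame, grid: BinGrid,
                 sample_sheet: pd.DataFrame, dapi: pd.DataFrame,
                 params: PipelineParams = DEFAULT_PARAMS,
                 gene_map: pd.DataFrame | None = None,
                 screen_evidence: pd.DataFrame | None = None,
                 seed: int = 0) -> PipelineResult:
    """Run the full pipeline; see the module docstring for the stages.

    ``dapi`` needs columns sample, a_median, d_median.  ``seed`` drives the
    segmentation permutation tests (the embedding seed lives in
    ``params.embed_seed``).
    """
    rng = np.random.default_rng(seed)
    sheet = sample_sheet.set_index("cell_id")
    mapq = sheet["mapq"] if "mapq" in sheet.columns else None

    basic = qc_mod.basic_qc(counts, mapq=mapq, params=params)
    stage1 = basic.index[basic["passed_basic"]]
    log.info("basic QC retained %d/%d cells", len(stage1), len(counts))

    ratios, seg_ratios = _profile_cells(counts.loc[stage1], grid, params, rng)
    cvs = pd.Series(
        seg_ratios.std(axis=1).to_numpy() /
        seg_ratios.mean(axis=1).to_numpy(),
        index=seg_ratios.index, name="cv")

    knn_pass, knn_corr = qc_mod.knn_filter(seg_ratios, k=params.knn_k,
                                           min_corr=params.knn_min_corr)
    # diploid classification sees all basic-passing cells: flat diploid
    # profiles may fail the correlation filter, but must still be labeled
    dip = qc_mod.identify_diploid(cvs.loc[stage1],
                                  n_sim=params.n_sim_diploid,
                                  sd_sim=params.diploid_cv_sd,
                                  mult=params.diploid_sd_mult,
                                  seed=params.em_seed,
                                  literal=params.diploid_literal)
    report = basic.copy()
    report["knn_pass"] = knn_pass.reindex(report.index, fill_value=False)
    report["knn_mean_corr"] = knn_corr.reindex(report.index)
    report["cv"] = cvs.reindex(report.index)
    report["is_diploid"] = dip.reindex(report.index, fill_value=False)
    report["retained"] = (report["passed_basic"] & report["knn_pass"] &
                          ~report["is_diploid"])
    retained = report.index[report["retained"]]
    log.info("QC retained %d cells (%d flagged diploid)", len(retained),
             int(report["is_diploid"].sum()))

    ploidy = {r["sample"]: estimate_ploidy(r["a_median"], r["d_median"])
              for _, r in dapi.iterrows()}
    cn = pd.DataFrame(
        {c: integer_cn(seg_ratios.loc[c],
                       ploidy[sheet.loc[c, "sample"]])
         for c in retained}).T
    cn.columns = counts.columns

    subs = discover_subclones(seg_ratios.loc[retained],
                              ratios.loc[retained], cn,
                              sample_sheet, params)

    tree = None
    if subs.consensus_integer.shape[1] >= 2:
        tree = build_tree(subs.consensus_integer,
                          boundaries=grid.chromosome_boundaries())

    ar_calls: list[ResistanceCall] = []
    pre_calls: list[ResistanceCall] = []
    if gene_map is not None:
        dom = subs.dominant_group
        have_both = (dom == "baseline").any() and (dom == "resistant").any()
        if have_both:
            grm = gene_ratio_matrix(ratios.loc[retained],
                                    subs.labels, gene_map, dom)
            ar_calls = call_ar_specific(grm, cv_max=params.gene_cv_max,
                                        margin=params.ratio_margin)
            if len(grm.baseline) >= 3:
                pre_calls = call_preexisting(
                    grm, cv_min=params.gene_cv_max,
                    z_threshold=params.z_threshold,
                    margin=params.ratio_margin)
            if screen_evidence is not None:
                annotate_function(ar_calls + pre_calls, screen_evidence)
        else:
            log.warning("dominance groups incomplete; resistance calling "
                        "skipped")

    return PipelineResult(
        qc_report=report,
        ratios=ratios.loc[retained],
        segment_ratios=seg_ratios.loc[retained],
        integer_cn=cn,
        ploidy=ploidy,
        subclones=subs,
        tree=tree,
        ar_calls=ar_calls,
        preexisting_calls=pre_calls,
    )
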