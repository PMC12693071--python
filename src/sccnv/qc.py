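"""Cell-level quality control and diploid-cell identification.

Three filters, applied in order:

1. ``basic_qc`` — drop libraries with mean mapping quality < 1, read counts
   below 10% of the cohort mean (the 100K floor at a nominal 1M reads/cell),
   or more than 10% empty bins.
2. ``knn_filter`` — drop cells whose mean Pearson correlation of segment
   ratios with their k most-correlated neighbors falls below a threshold
   (k=5 / 0.8 for human, k=4 / 0.7 for mouse), in the style of CopyKit.
3. ``identify_diploid`` — flag diploid (flat-profile) cells by pooling the
   observed segment-ratio CVs with 1,000 CVs simulated from N(0, 0.01)
   truncated at zero, fitting a two-component normal mixture by EM, and
   calling a cell diploid when its CV lies within ``mult`` standard
   deviations of the mean of the component that captured the simulated mass.

Note on the third filter: simulated diploid CVs are near zero, so diploid
cells are the LOW-CV component.  A literal mode that instead flags cells
whose CV *exceeds* the threshold is available via ``literal=True``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .params import PipelineParams, DEFAULT_PARAMS

__all__ = ["basic_qc", "knn_filter", "identify_diploid", "run_qc"]


def basic_qc(counts: pd.DataFrame, mapq: pd.Series | None = None,
             params: PipelineParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Per-cell basic filters; returns a report indexed by cell.

    The read floor is ``min_reads_frac`` x the cohort mean read count unless
    ``params.min_reads_absolute`` is set.
    """
    reads = counts.sum(axis=1)
    floor = (params.min_reads_absolute if params.min_reads_absolute
             is not None else params.min_reads_frac * reads.mean())
    empty_frac = (counts == 0).mean(axis=1)
    report = pd.DataFrame(index=counts.index)
    report["reads"] = reads
    report["empty_bin_frac"] = empty_frac
    report["fail_reads"] = reads < floor
    report["fail_empty_bins"] = empty_frac > params.max_empty_bin_frac
    if mapq is not None:
        report["mapq"] = mapq.reindex(counts.index)
        report["fail_mapq"] = report["mapq"] < params.min_mapq
    else:
        report["fail_mapq"] = False
    report["passed_basic"] = ~(report["fail_reads"] |
                               report["fail_empty_bins"] |
                               report["fail_mapq"])
    return report


def knn_filter(segment_ratios: pd.DataFrame, k: int = 5,
               min_corr: float = 0.8) -> tuple[pd.Series, pd.Series]:
    """Keep mask (and mean neighbor correlation) per cell.

    ``segment_ratios`` is cells x bins.  A cell is excluded when the mean
    Pearson correlation of its segment-ratio profile with its k nearest
    (most-correlated) other cells is below ``min_corr``.
    """
    n = len(segment_ratios)
    if n < k + 1:
        raise ValueError(f"k-NN filter needs at least {k + 1} cells, got {n}")
    x = segment_ratios.to_numpy(float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        # constant profiles correlate perfectly with each other by convention
        x = x + np.random.default_rng(0).normal(0, 1e-12, x.shape)
    corr = np.corrcoef(x)
    np.fill_diagonal(corr, -np.inf)
    top = np.sort(corr, axis=1)[:, -k:]
    mean_corr = top.mean(axis=1)
    return pd.Series(mean_corr >= min_corr, index=segment_ratios.index,
                     name="knn_pass"), pd.Series(
                         mean_corr, index=segment_ratios.index,
                         name="knn_mean_corr")


def identify_diploid(cvs: pd.Series, n_sim: int = 1000, sd_sim: float = 0.01,
                     mult: float = 5.0, seed: int = 0,
                     literal: bool = False) -> pd.Series:
    """Diploid mask from a two-component normal mixture over CVs.

    Simulated diploid CVs are drawn from N(0, sd_sim) truncated at 0 (a CV
    is non-negative), pooled with the observed CVs, and a 2-component
    Gaussian mixture is fitted by EM (k-means init, tol 1e-8, <=500
    iterations).  The component holding the larger share of simulated mass
    is the diploid component with mean m and standard deviation s; a cell is
    diploid iff CV <= m + mult*s (or, under ``literal=True``, iff its CV
    exceeds that threshold).  Falls back to a fixed cutoff of mult*sd_sim if
    EM fails to converge.
    """
    obs = cvs.to_numpy(float)
    if len(obs) < 10:
        raise ValueError("need at least 10 observed CVs")
    rng = np.random.default_rng(seed)
    sim = np.abs(rng.normal(0.0, sd_sim, size=n_sim))
    pooled = np.concatenate([obs, sim]).reshape(-1, 1)
    gm = GaussianMixture(n_components=2, tol=1e-8, max_iter=500,
                         init_params="kmeans",
                         random_state=np.random.default_rng(seed).integers(
                             2**31 - 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(pooled)
    if not gm.converged_:
        warnings.warn("EM did not converge; falling back to the fixed "
                      "CV cutoff mult * sd_sim")
        thresh = mult * sd_sim
        mask = obs <= thresh if not literal else obs > thresh
        return pd.Series(mask, index=cvs.index, name="is_diploid")
    resp_sim = gm.predict_proba(sim.reshape(-1, 1))
    dip = int(np.argmax(resp_sim.mean(axis=0)))
    m = float(gm.means_[dip, 0])
    s = float(np.sqrt(gm.covariances_[dip].ravel()[0]))
    thresh = m + mult * s
    mask = obs <= thresh if not literal else obs > thresh
    return pd.Series(mask, index=cvs.index, name="is_diploid")


def run_qc(counts: pd.DataFrame, segment_ratios: pd.DataFrame,
           cvs: pd.Series, mapq: pd.Series | None = None,
           params: PipelineParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Apply the three filters; returns the full QC report.

    The k-NN filter sees basic-passing cells; diploid classification also
    sees basic-passing cells (independently of the k-NN outcome).  The
    returned frame carries per-filter flags and the final ``retained`` mask:
    passed_basic AND knn_pass AND NOT is_diploid.
    """
    report = basic_qc(counts, mapq=mapq, params=params)
    report["knn_mean_corr"] = np.nan
    report["knn_pass"] = False
    report["cv"] = cvs.reindex(report.index)
    report["is_diploid"] = False

    stage1 = report.index[report["passed_basic"]]
    knn_pass, knn_corr = knn_filter(segment_ratios.loc[stage1],
                                    k=params.knn_k,
                                    min_corr=params.knn_min_corr)
    report.loc[stage1, "knn_pass"] = knn_pass
    report.loc[stage1, "knn_mean_corr"] = knn_corr

    # diploid identification is a classification of normal contaminants,
    # not a quality filter: it sees every basic-passing cell, since flat
    # diploid profiles can legitimately fail the correlation filter
    stage2 = stage1
    dip = identify_diploid(cvs.loc[stage2], n_sim=params.n_sim_diploid,
                           sd_sim=params.diploid_cv_sd,
                           mult=params.diploid_sd_mult,
                           seed=params.em_seed,
                           literal=params.diploid_literal)
    report.loc[stage2, "is_diploid"] = dip
    report["retained"] = (report["passed_basic"] & report["knn_pass"] &
                          ~report["is_diploid"])
    return report
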