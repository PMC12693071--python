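"""Pipeline-wide numeric parameters.

Every tunable threshold of the single-cell CNV pipeline lives here so that a
run is fully described by one :class:`PipelineParams` instance.  Defaults are
the values used throughout the analysis: shallow (~1M-read) single-cell WGS
QC floors, CopyKit-style k-nearest-neighbor filtering presets for human and
mouse, the simulated-diploid mixture-model settings, UMAP/HDBSCAN clustering
settings, and the resistance-call thresholds (CV gate 0.18, ratio margin
0.09, |z| > 1, >50% sample dominance).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PipelineParams:
    # GC normalization
    lowess_span: float = 0.3
    lowess_iters: int = 3

    # segmentation
    cbs_alpha: float = 0.01
    cbs_min_width: int = 3
    cbs_n_perm: int = 1000

    # basic QC: reads floor is 0.1 x cohort mean (100K at a nominal 1M),
    # switchable to an absolute count
    min_reads_frac: float = 0.1
    min_reads_absolute: float | None = None
    max_empty_bin_frac: float = 0.10
    min_mapq: float = 1.0

    # k-nearest-neighbor correlation filter (human preset; mouse: k=4, 0.7)
    knn_k: int = 5
    knn_min_corr: float = 0.8

    # simulated-diploid EM mixture
    n_sim_diploid: int = 1000
    diploid_cv_sd: float = 0.01
    diploid_sd_mult: float = 5.0
    diploid_literal: bool = False  # literal "exceeds k sd" reading
    em_seed: int = 0

    # embedding + clustering
    embed_seed: int = 31
    embed_min_dist: float = 0.1
    embed_n_neighbors: int = 20
    embed_metric: str = "manhattan"
    embed_spread: float = 3.0
    min_subclone_cells: int = 6
    cluster_method: str = "hdbscan"  # or "dbscan"
    dbscan_eps: float = 0.5

    # dominance and resistance calls
    dominance_frac: float = 0.5
    gene_cv_max: float = 0.18
    ratio_margin: float = 0.09
    z_threshold: float = 1.0

    # bulk integration
    recurrence_min_patients: int = 3
    screen_min_evidence: int = 2

    def mouse(self) -> "PipelineParams":
        """Return a copy with the mouse k-NN preset (k=4, min corr 0.7)."""
        import dataclasses

        return dataclasses.replace(self, knn_k=4, knn_min_corr=0.7)


DEFAULT_PARAMS = PipelineParams()
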