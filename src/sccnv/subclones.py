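"""Subclone discovery: embedding, density clustering, consensus profiles.

Retained cells are embedded in two dimensions by UMAP on log2 segment
ratios (seed 31, min_dist 0.1, n_neighbors 20, manhattan metric, spread 3)
and clustered with hierarchical density-based clustering (HDBSCAN-style,
minimum cluster size 6; plain DBSCAN available behind a flag).  Noise cells
and clusters below the minimum size are discarded.  Each subclone gets a
consensus integer profile (per-bin median of member integer CNs, ties
rounded half away from zero), a consensus ratio profile, its per-sample
composition, and a dominance class: a subclone is resistant-dominant when
more than half its cells come from resistant-group samples, baseline-
dominant in the mirror case, else unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import umap
from sklearn.cluster import DBSCAN, HDBSCAN
from sklearn.neighbors import NearestNeighbors

from .cnv import round_half_away
from .params import PipelineParams, DEFAULT_PARAMS

__all__ = ["SubcloneSet", "embed", "cluster", "consensus_profile",
           "classify_dominance", "discover_subclones"]

NOISE = "noise"


@dataclass
class SubcloneSet:
    """Cell labels plus per-subclone consensus profiles and composition."""

    labels: pd.Series                   # cell_id -> subclone name or NOISE
    consensus_integer: pd.DataFrame     # bins x subclones
    consensus_ratio: pd.DataFrame       # bins x subclones
    composition: pd.DataFrame           # subclones x samples, cell counts
    dominant_group: pd.Series           # subclone -> baseline|resistant|none
    embedding: pd.DataFrame | None = None

    @property
    def names(self) -> list[str]:
        return list(self.consensus_integer.columns)


def embed(log2_segment_ratios: pd.DataFrame,
          params: PipelineParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """2-D UMAP embedding of cells, deterministic for a fixed seed."""
    n = len(log2_segment_ratios)
    if n < params.embed_n_neighbors + 1:
        raise ValueError(
            f"need at least {params.embed_n_neighbors + 1} cells to embed")
    reducer = umap.UMAP(
        n_components=2,
        random_state=params.embed_seed,
        min_dist=params.embed_min_dist,
        n_neighbors=params.embed_n_neighbors,
        metric=params.embed_metric,
        spread=params.embed_spread,
    )
    coords = reducer.fit_transform(log2_segment_ratios.to_numpy(float))
    return pd.DataFrame(coords, index=log2_segment_ratios.index,
                        columns=["umap1", "umap2"])


def cluster(embedding: pd.DataFrame,
            min_cluster_size: int = 6,
            method: str = "hdbscan",
            eps: float = 0.5) -> pd.Series:
    """Density-based cluster labels over the embedding.

    Noise cells keep the label ``"noise"``; clusters smaller than
    ``min_cluster_size`` are dissolved into noise.  Clusters are renamed
    c1..cK in order of decreasing size.

    UMAP equalizes density, so hierarchical density clustering is run with
    a scale-aware cluster-selection epsilon (twice the median distance to
    the min_cluster_size-th neighbor) and a single root cluster allowed;
    without this a homogeneous population fragments into noise.
    """
    x = embedding.to_numpy(float)
    if method == "hdbscan":
        k = min(min_cluster_size, len(x) - 1)
        nn_d, _ = (NearestNeighbors(n_neighbors=k + 1).fit(x)
                   .kneighbors(x))
        eps_sel = 2.0 * float(np.median(nn_d[:, -1]))
        raw = HDBSCAN(min_cluster_size=min_cluster_size,
                      allow_single_cluster=True,
                      cluster_selection_epsilon=eps_sel,
                      copy=True).fit_predict(x)
    elif method == "dbscan":
        raw = DBSCAN(eps=eps, min_samples=min_cluster_size).fit_predict(x)
    else:
        raise ValueError(f"unknown clustering method {method!r}")
    raw = pd.Series(raw, index=embedding.index)
    sizes = raw[raw >= 0].value_counts()
    keep = sizes[sizes >= min_cluster_size]
    if keep.empty:
        raise ValueError("all cells classified as noise; relax the "
                         "clustering parameters or embed more cells")
    rename = {old: f"c{i + 1}" for i, old in enumerate(keep.index)}
    return raw.map(lambda v: rename.get(v, NOISE)).rename("subclone")


def consensus_profile(member_integer_cn: pd.DataFrame) -> np.ndarray:
    """Per-bin median of member integer CNs, rounded to nearest integer.

    ``member_integer_cn`` is cells x bins; ties (x.5 medians from even-sized
    subclones) round half away from zero.
    """
    if len(member_integer_cn) == 0:
        raise ValueError("consensus of an empty member set")
    med = np.median(member_integer_cn.to_numpy(float), axis=0)
    return np.maximum(round_half_away(med), 0).astype(int)


def classify_dominance(composition: pd.Series, group_map: dict[str, str],
                       frac: float = 0.5) -> str:
    """baseline / resistant / none from sample-of-origin counts.

    Strict inequality: a subclone is dominant for a group only when that
    group contributes more than ``frac`` of its cells.
    """
    total = composition.sum()
    if total == 0:
        raise ValueError("empty composition")
    res = sum(c for s, c in composition.items()
              if group_map.get(s) == "resistant")
    base = sum(c for s, c in composition.items()
               if group_map.get(s) == "baseline")
    if res / total > frac:
        return "resistant"
    if base / total > frac:
        return "baseline"
    return "none"


def discover_subclones(segment_ratios: pd.DataFrame,
                       ratios: pd.DataFrame,
                       integer_cn: pd.DataFrame,
                       sample_sheet: pd.DataFrame,
                       params: PipelineParams = DEFAULT_PARAMS
                       ) -> SubcloneSet:
    """Full subclone step: embed, cluster, consensus, dominance.

    ``segment_ratios``, ``ratios`` and ``integer_cn`` are cells x bins over
    the same retained cells; ``sample_sheet`` maps cell_id to sample and
    group.
    """
    log2 = np.log2(np.maximum(segment_ratios.to_numpy(float), 1e-3))
    log2 = pd.DataFrame(log2, index=segment_ratios.index)
    coords = embed(log2, params)
    labels = cluster(coords, min_cluster_size=params.min_subclone_cells,
                     method=params.cluster_method, eps=params.dbscan_eps)

    sheet = sample_sheet.set_index("cell_id")
    group_map = (sheet.groupby("sample")["group"].first().to_dict())

    cons_int, cons_ratio, comp_rows, dom = {}, {}, {}, {}
    for name in [l for l in labels.unique() if l != NOISE]:
        members = labels.index[labels == name]
        cons_int[name] = consensus_profile(integer_cn.loc[members])
        cons_ratio[name] = np.median(ratios.loc[members].to_numpy(float),
                                     axis=0)
        comp = sheet.loc[members, "sample"].value_counts()
        comp_rows[name] = comp
        dom[name] = classify_dominance(comp, group_map,
                                       frac=params.dominance_frac)

    names = sorted(cons_int, key=lambda n: int(n[1:]))
    composition = pd.DataFrame(comp_rows).T.fillna(0).astype(int).loc[names]
    return SubcloneSet(
        labels=labels,
        consensus_integer=pd.DataFrame({n: cons_int[n] for n in names}),
        consensus_ratio=pd.DataFrame({n: cons_ratio[n] for n in names}),
        composition=composition,
        dominant_group=pd.Series({n: dom[n] for n in names},
                                 name="dominant_group"),
        embedding=coords,
    )
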