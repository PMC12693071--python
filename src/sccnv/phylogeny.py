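"""Minimum-event-distance phylogeny over subclone consensus profiles.

An *event* adds or subtracts one copy on a contiguous run of bins within a
single chromosome.  A bin at copy number 0 is absorbing: it can never be
re-gained (and cannot go below zero), so a profile with CN 0 where the
target has CN > 0 is unreachable (infinite distance).

``med_distance`` computes the minimum number of such events transforming
one integer profile into another.  Per chromosome, the difference profile
is split into its gain part p and loss part q; because each bin moves
monotonically toward its target, the minimum equals the sum of positive
increments of p plus those of q (events cover maximal contiguous runs).
This closed form is verified against exhaustive shortest-path search in the
test suite.

Trees are built by neighbor joining on the pairwise MED matrix and rooted
at an all-CN-2 diploid node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = ["EventList", "CloneTree", "count_events", "med_distance",
           "med_matrix", "build_tree"]

ROOT_NAME = "diploid"


@dataclass
class CloneTree:
    tree: TreeNode          # rooted at the diploid node
    distances: pd.DataFrame  # pairwise MED including the root
    newick: str

    def clade_leaf_sets(self) -> list[frozenset]:
        """Leaf-name sets of every internal node (monophyly queries)."""
        out = []
        for node in self.tree.non_tips(include_self=True):
            out.append(frozenset(t.name for t in node.tips()))
        return out


def count_events(profile, grid=None, boundaries=None,
                 base_cn: int = 2) -> tuple[pd.DataFrame, int]:
    """CNV events of a consensus integer profile, per chromosome.

    Maximal runs of constant CN that differ from ``base_cn`` delimit
    breakpoints; runs spanning a single bin are listed but excluded from
    the total count.  Pass either a BinGrid or an array of chromosome
    boundary indices.
    """
    profile = np.asarray(profile, dtype=int)
    if boundaries is None:
        if grid is None:
            boundaries = np.array([0, len(profile)])
            chrom_names = ["chr"]
        else:
            boundaries = grid.chromosome_boundaries()
            chrom_names = [c for c, _ in grid.chromosome_slices()]
    else:
        boundaries = np.asarray(boundaries, dtype=int)
        chrom_names = [f"chr{i + 1}" for i in range(len(boundaries) - 1)]

    rows = []
    for name, lo, hi in zip(chrom_names, boundaries[:-1], boundaries[1:]):
        x = profile[lo:hi]
        i = 0
        while i < len(x):
            j = i
            while j < len(x) and x[j] == x[i]:
                j += 1
            if x[i] != base_cn:
                direction = "gain" if x[i] > base_cn else "loss"
                rows.append((name, lo + i, lo + j, direction,
                             abs(int(x[i]) - base_cn), j - i))
            i = j
    events = pd.DataFrame(rows, columns=["chrom", "start_bin", "end_bin",
                                         "direction", "magnitude", "length"])
    total = int((events["length"] > 1).sum()) if len(events) else 0
    return events, total


def _med_one_chromosome(a: np.ndarray, b: np.ndarray) -> float:
    if np.any((a == 0) & (b != 0)):
        return math.inf
    d = b.astype(int) - a.astype(int)
    total = 0
    for sign in (1, -1):
        part = np.maximum(sign * d, 0)
        prev = 0
        for v in part:
            if v > prev:
                total += v - prev
            prev = int(v)
    return float(total)


def med_distance(profile_a, profile_b, boundaries=None) -> float:
    """Minimum event distance between two equal-length integer profiles.

    ``boundaries`` holds chromosome start indices plus the total length
    (events never span chromosomes); omit it for a single chromosome.
    Returns ``math.inf`` when the zero-absorption rule makes the target
    unreachable.
    """
    a = np.asarray(profile_a, dtype=int)
    b = np.asarray(profile_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("copy numbers must be non-negative")
    if boundaries is None:
        boundaries = [0, len(a)]
    boundaries = np.asarray(boundaries, dtype=int)
    return float(sum(_med_one_chromosome(a[lo:hi], b[lo:hi])
                     for lo, hi in zip(boundaries[:-1], boundaries[1:])))


def med_matrix(profiles: pd.DataFrame, boundaries=None,
               root_name: str = ROOT_NAME) -> pd.DataFrame:
    """Pairwise MED over subclone profiles plus an all-CN-2 diploid root.

    MED is not symmetric in general (zero absorption), but consensus tumor
    profiles reachable from diploid rarely hit zero; for tree building the
    matrix entry is the symmetrized minimum of the two directions.
    """
    cols = list(profiles.columns)
    mat = profiles.to_numpy(int).T
    root = np.full(mat.shape[1], 2, dtype=int)
    names = [root_name] + cols
    prof = np.vstack([root, mat])
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = min(med_distance(prof[i], prof[j], boundaries),
                    med_distance(prof[j], prof[i], boundaries))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=names, columns=names)


def build_tree(profiles: pd.DataFrame, boundaries=None,
               root_name: str = ROOT_NAME) -> CloneTree:
    """Neighbor-joining tree on the MED matrix, rooted at the diploid node.

    ``profiles`` is bins x subclones.  Raises when any pairwise distance is
    infinite (mutually unreachable profiles under the zero rule).
    """
    if profiles.shape[1] < 2:
        raise ValueError("need at least two subclones to build a tree")
    dm = med_matrix(profiles, boundaries, root_name)
    bad = [(a, b) for a in dm.index for b in dm.columns
           if a < b and math.isinf(dm.loc[a, b])]
    if bad:
        raise ValueError(f"infinite minimum event distance for pairs: {bad}")
    tree = nj(DistanceMatrix(dm.to_numpy(), ids=list(dm.index)))
    rooted = tree.root_at(tree.find(root_name).parent)
    newick = str(rooted).strip()
    return CloneTree(tree=rooted, distances=dm, newick=newick)
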