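"""Plain-text readers and writers for the pipeline's tabular artifacts.

Bin grids travel as BED-like TSV (chrom, start, end, gc); counts as a TSV
matrix (cell_id index x bins) or sparse triplets; sample sheets, gene maps
and screen-hit tables as TSV; trees as newick.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cnv import BinGrid

__all__ = ["write_bin_grid", "read_bin_grid", "write_counts", "read_counts",
           "write_counts_triplets", "read_counts_triplets",
           "write_gene_map", "read_gene_map"]


def write_bin_grid(grid: BinGrid, path) -> None:
    grid.table.to_csv(path, sep="\t", index=False)


def read_bin_grid(path) -> BinGrid:
    return BinGrid(pd.read_csv(path, sep="\t"))


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="cell_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="cell_id")


def write_counts_triplets(counts: pd.DataFrame, path) -> None:
    """Sparse (cell, bin, count) triplets; zero bins omitted."""
    long = counts.stack()
    long = long[long > 0]
    long.rename_axis(["cell_id", "bin"]).rename("count") \
        .reset_index().to_csv(path, sep="\t", index=False)


def read_counts_triplets(path, bins: list[str] | None = None
                         ) -> pd.DataFrame:
    long = pd.read_csv(path, sep="\t")
    wide = long.pivot(index="cell_id", columns="bin",
                      values="count").fillna(0).astype(int)
    if bins is not None:
        wide = wide.reindex(columns=bins, fill_value=0)
    return wide


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    t = gene_map.copy()
    t["bins"] = t["bins"].map(lambda b: ",".join(map(str, b)))
    t.to_csv(path, sep="\t", index=False)


def read_gene_map(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    t["bins"] = t["bins"].map(
        lambda s: [int(v) for v in str(s).split(",")])
    return t
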