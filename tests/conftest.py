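import warnings

import numpy as np
import pandas as pd
import pytest

from sccnv.cnv import BinGrid
from sccnv.pipeline import run_pipeline
from sccnv.synthetic import (default_study_spec, make_bin_grid,
                             simulate_cells, simulate_dapi)

STUDY_SEED = 1


@pytest.fixture(scope="session")
def study_dataset():
    """The default desk-scale study dataset (seed-fixed)."""
    spec = default_study_spec(seed=STUDY_SEED)
    grid = make_bin_grid(spec)
    counts, sheet, truth = simulate_cells(spec, grid)
    dapi = simulate_dapi(spec, grid)
    return {"spec": spec, "grid": grid, "counts": counts, "sheet": sheet,
            "truth": truth, "dapi": dapi}


@pytest.fixture(scope="session")
def study_result(study_dataset):
    """Full pipeline run on the study dataset (shared; ~1 min)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(study_dataset["counts"], study_dataset["grid"],
                            study_dataset["sheet"], study_dataset["dapi"],
                            seed=STUDY_SEED)


@pytest.fixture
def flat_grid():
    """Small two-chromosome grid with uniform bins and mid-range GC."""
    rows = []
    for chrom, n in (("chr1", 50), ("chr2", 50)):
        for i in range(n):
            rows.append((chrom, i * 1000, (i + 1) * 1000, 0.45))
    return BinGrid(pd.DataFrame(rows,
                                columns=["chrom", "start", "end", "gc"]))
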