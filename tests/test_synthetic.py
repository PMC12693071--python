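"""Synthetic-data generator: grid geometry, noise model, ground truth."""

import numpy as np
import pandas as pd
import pytest

from sccnv.synthetic import (SimSpec, SubcloneSpec, default_study_spec,
                             make_bin_grid, make_gene_map, simulate_cells,
                             simulate_dapi)


def two_clone_spec(**kw):
    defaults = dict(
        n_bins=500,
        chromosomes=[("chr1", 250), ("chr2", 250)],
        subclones=[
            SubcloneSpec("base", 20, "P"),
            SubcloneSpec("gain", 20, "AR", events=[("chr1", 50, 150, 4)]),
        ],
        groups={"P": "baseline", "AR": "resistant"},
        reads_per_cell=1e5,
        dropout_cell_fraction=0.0,
        low_mapq_cell_fraction=0.0,
        seed=7,
    )
    defaults.update(kw)
    return SimSpec(**defaults)


class TestMakeBinGrid:
    def test_bin_layout_is_contiguous_per_chromosome(self):
        spec = SimSpec(n_bins=100, chromosomes=[("chrA", 50), ("chrB", 50)],
                       subclones=[SubcloneSpec("s", 5, "P")])
        grid = make_bin_grid(spec)
        assert len(grid) == 100
        for _, sl in grid.chromosome_slices():
            sub = grid.table.iloc[sl]
            assert (sub["start"].to_numpy()[1:] ==
                    sub["end"].to_numpy()[:-1]).all()

    def test_mean_width_tracks_target(self):
        grid = make_bin_grid(two_clone_spec())
        assert abs(grid.widths.mean() - 220_000) / 220_000 < 0.10

    def test_grid_deterministic_under_seed(self):
        spec = two_clone_spec()
        g1 = make_bin_grid(spec)
        g2 = make_bin_grid(spec)
        pd.testing.assert_frame_equal(g1.table, g2.table)

    def test_rejects_tiny_grid(self):
        with pytest.raises(ValueError):
            SimSpec(n_bins=5, subclones=[SubcloneSpec("s", 5, "P")])


class TestSimulateCells:
    def test_mean_count_scales_with_copy_number(self):
        spec = two_clone_spec(gc_bias_strength=0.0, overdispersion=0.0)
        grid = make_bin_grid(spec)
        counts, sheet, truth = simulate_cells(spec, grid)
        gain_cells = truth.cell_subclone[truth.cell_subclone == "gain"].index
        x = counts.loc[gain_cells].mean(axis=0).to_numpy()
        cn4 = x[50:150].mean()
        cn2 = np.concatenate([x[:50], x[150:250]]).mean()
        assert abs(cn4 / cn2 - 2.0) < 0.05 * 2.0

    def test_diploid_contaminant_count_is_binomial(self):
        spec = two_clone_spec(
            subclones=[SubcloneSpec("a", 200, "P"),
                       SubcloneSpec("b", 200, "AR")],
            diploid_fraction=0.2)
        grid = make_bin_grid(spec)
        _, _, truth = simulate_cells(spec, grid)
        n_dip = len(truth.diploid_cells)
        # Binomial(500, 0.2): mean 100, sd ~8.9; allow 4 sd
        assert 64 <= n_dip <= 136

    def test_row_sums_match_drawn_depths(self):
        # with depth variation switched off the drawn depth is exactly the
        # nominal mean, and the overdispersed totals concentrate within 1%
        spec = two_clone_spec(overdispersion=0.05, reads_sigma=0.0)
        grid = make_bin_grid(spec)
        counts, _, _ = simulate_cells(spec, grid)
        totals = counts.sum(axis=1)
        assert (np.abs(totals - 1e5) / 1e5 < 0.05).all()
        assert totals.mean() == pytest.approx(1e5, rel=0.005)

    def test_identical_seed_identical_dataset(self):
        spec = two_clone_spec()
        grid = make_bin_grid(spec)
        c1, s1, _ = simulate_cells(spec, grid)
        c2, s2, _ = simulate_cells(spec, grid)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_empty_subclone_list_rejected(self):
        spec = two_clone_spec()
        spec.subclones = []
        grid = make_bin_grid(two_clone_spec())
        with pytest.raises(ValueError):
            simulate_cells(spec, grid)

    def test_event_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            two_clone_spec(subclones=[
                SubcloneSpec("bad", 5, "P",
                             events=[("chr1", 200, 300, 3)])])


class TestGeneTruth:
    def test_ar_specific_sets_match_planted_differences(self):
        spec = two_clone_spec(
            subclones=[
                SubcloneSpec("p1", 10, "P"),
                SubcloneSpec("p2", 10, "P"),
                SubcloneSpec("r1", 10, "AR",
                             events=[("chr1", 0, 100, 3),
                                     ("chr2", 0, 100, 1)]),
            ])
        grid = make_bin_grid(spec)
        gene_map = pd.DataFrame({
            "gene": ["amp_g", "del_g", "flat_g"],
            "chrom": ["chr1", "chr2", "chr1"],
            "start": [0, 0, 0], "end": [1, 1, 1],
            "bins": [[10, 11], [260, 261], [200, 201]],
        })
        _, _, truth = simulate_cells(spec, grid, gene_map=gene_map)
        assert truth.ar_amplified == {"amp_g"}
        assert truth.ar_deleted == {"del_g"}
        assert truth.preexisting == set()

    def test_preexisting_pair_recorded_for_deviant_baseline_subclone(self):
        spec = two_clone_spec(
            subclones=[
                SubcloneSpec("p1", 10, "P"),
                SubcloneSpec("p2", 10, "P"),
                SubcloneSpec("p3", 10, "P",
                             events=[("chr1", 0, 100, 3)]),
                SubcloneSpec("r1", 10, "AR",
                             events=[("chr1", 0, 100, 3)]),
            ])
        grid = make_bin_grid(spec)
        gene_map = pd.DataFrame({
            "gene": ["g"], "chrom": ["chr1"], "start": [0], "end": [1],
            "bins": [[50]],
        })
        _, _, truth = simulate_cells(spec, grid, gene_map=gene_map)
        assert truth.ar_amplified == {"g"}
        assert truth.preexisting == {("g", "p3", "amplified")}


class TestSimulateDapi:
    def test_diploid_sample_has_equal_peaks(self):
        spec = two_clone_spec(subclones=[SubcloneSpec("flat", 10, "P")])
        grid = make_bin_grid(spec)
        dapi = simulate_dapi(spec, grid)
        row = dapi.iloc[0]
        assert row["a_median"] == pytest.approx(row["d_median"])

    def test_triploid_sample_peak_ratio(self):
        spec = two_clone_spec(subclones=[
            SubcloneSpec("tri", 10, "P", base_ploidy=3)])
        grid = make_bin_grid(spec)
        dapi = simulate_dapi(spec, grid)
        row = dapi.iloc[0]
        assert row["a_median"] / row["d_median"] == pytest.approx(1.5)

    def test_noisy_peaks_recover_ploidy_within_5pct(self):
        from sccnv.cnv import estimate_ploidy
        spec = two_clone_spec(subclones=[
            SubcloneSpec("tri", 10, "P", base_ploidy=3)])
        grid = make_bin_grid(spec)
        rng = np.random.default_rng(11)
        errs = []
        for _ in range(100):
            dapi = simulate_dapi(spec, grid, noise_sd=0.02, rng=rng)
            est = estimate_ploidy(dapi.iloc[0]["a_median"],
                                  dapi.iloc[0]["d_median"])
            errs.append(abs(est - 3.0) / 3.0)
        assert np.mean(errs) < 0.05


def test_make_gene_map_covers_every_gene(flat_grid):
    gm = make_gene_map(flat_grid, n_genes=25, seed=3)
    assert len(gm) == 25
    assert (gm["bins"].map(len) >= 1).all()
    for _, row in gm.iterrows():
        assert all(flat_grid.chrom[b] == row["chrom"] for b in row["bins"])


def test_default_study_spec_shape():
    spec = default_study_spec(seed=0)
    assert spec.n_bins == 2000
    assert len(spec.subclones) == 5
    assert spec.diploid_fraction == 0.15
    assert {sc.sample_label for sc in spec.subclones} == {"P", "AR"}
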