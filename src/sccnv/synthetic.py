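"""Synthetic single-cell WGS bin-count datasets with planted subclones.

Emulates the data regime of shallow single-cell whole-genome sequencing of
tumors: variable genomic bins (~220 kb genome-wide; desk-scale defaults use
fewer, proportionally sized bins), per-cell depth drawn log-normally around a
nominal target with a dropout tail, a unimodal GC-dependent count bias,
negative-binomial (Poisson-gamma) count noise, integer-copy-number subclone
structure with shared / private / preexisting events, and a diploid
contaminant fraction.  Every dataset carries its ground truth so downstream
stages (segmentation, QC, clustering, phylogeny, resistance calls) can be
scored exactly.

What it does not model: read-level artifacts (FASTQ/BAM), mappability-driven
bin-width derivation, doublets, replication-timing bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv import BinGrid

__all__ = [
    "SubcloneSpec",
    "SimSpec",
    "GroundTruth",
    "make_bin_grid",
    "simulate_cells",
    "simulate_dapi",
    "make_gene_map",
    "default_study_spec",
]


@dataclass
class SubcloneSpec:
    """One planted subclone: cell count, sample of origin, CNV events.

    ``events`` are (chromosome, bin_start, bin_end, integer CN) with 0-based
    half-open chromosome-local bin indices, overriding ``base_ploidy``.
    """

    name: str
    n_cells: int
    sample_label: str
    events: list[tuple[str, int, int, int]] = field(default_factory=list)
    base_ploidy: int = 2


@dataclass
class SimSpec:
    """Full description of one synthetic dataset.

    ``diploid_fraction`` is the expected proportion of diploid contaminant
    cells in the final pool; the contaminant count is drawn binomially so the
    realized fraction fluctuates as it would in a sorted nuclei suspension.
    """

    n_bins: int = 2000
    mean_bin_size: int = 220_000
    chromosomes: list[tuple[str, int]] | None = None
    gc_range: tuple[float, float] = (0.3, 0.7)
    subclones: list[SubcloneSpec] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)  # sample -> group
    diploid_fraction: float = 0.0
    reads_per_cell: float = 1e5
    reads_sigma: float = 0.25  # log-normal scale of depth variation
    dropout_cell_fraction: float = 0.05
    low_mapq_cell_fraction: float = 0.02
    gc_bias_strength: float = 0.5
    overdispersion: float = 0.05
    bin_width_concentration: float = 50.0
    seed: int = 0
    planted_newick: str | None = None

    def __post_init__(self):
        if self.n_bins < 10:
            raise ValueError("n_bins must be at least 10")
        if not 0 <= self.diploid_fraction <= 1:
            raise ValueError("diploid_fraction must lie in [0, 1]")
        if self.chromosomes is None:
            # split bins over 10 equal chromosomes by default
            n_chr = min(10, max(1, self.n_bins // 100))
            per = self.n_bins // n_chr
            sizes = [per] * n_chr
            sizes[-1] += self.n_bins - per * n_chr
            self.chromosomes = [(f"chr{i + 1}", s)
                                for i, s in enumerate(sizes)]
        if sum(s for _, s in self.chromosomes) != self.n_bins:
            raise ValueError("chromosome bin counts must sum to n_bins")
        for sc in self.subclones:
            chrom_sizes = dict(self.chromosomes)
            for chrom, a, b, cn in sc.events:
                if cn < 0:
                    raise ValueError("event CN must be non-negative")
                if chrom not in chrom_sizes:
                    raise ValueError(f"unknown chromosome {chrom!r}")
                if not (0 <= a < b <= chrom_sizes[chrom]):
                    raise ValueError(
                        f"event interval [{a},{b}) outside {chrom}")

    def _rngs(self, n: int) -> list[np.random.Generator]:
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class GroundTruth:
    """Planted truth for one simulated dataset."""

    cell_subclone: pd.Series  # cell_id -> subclone name ('diploid' allowed)
    profiles: pd.DataFrame    # bins x subclones, planted integer CN
    diploid_cells: list[str]
    subclone_group: dict = field(default_factory=dict)  # name -> group
    ar_amplified: set = field(default_factory=set)
    ar_deleted: set = field(default_factory=set)
    preexisting: set = field(default_factory=set)  # (gene, subclone, dir)
    planted_newick: str | None = None


def make_bin_grid(spec: SimSpec) -> BinGrid:
    """Variable-width bin grid: Dirichlet-perturbed widths, uniform GC."""
    rng = spec._rngs(3)[0]
    rows = []
    lo, hi = spec.gc_range
    for chrom, n in spec.chromosomes:
        alpha = np.full(n, spec.bin_width_concentration)
        shares = rng.dirichlet(alpha)
        widths = np.maximum((shares * n * spec.mean_bin_size).round(), 1)
        starts = np.concatenate([[0], np.cumsum(widths)[:-1]]).astype(int)
        gc = rng.uniform(lo, hi, size=n)
        for s, w, g in zip(starts, widths, gc):
            rows.append((chrom, int(s), int(s + w), float(g)))
    return BinGrid(pd.DataFrame(rows, columns=["chrom", "start", "end", "gc"]))


def _subclone_profiles(spec: SimSpec, grid: BinGrid) -> pd.DataFrame:
    """Planted integer CN per bin for every subclone (columns)."""
    chrom_offsets = {c: sl.start for c, sl in grid.chromosome_slices()}
    profiles = {}
    for sc in spec.subclones:
        cn = np.full(len(grid), sc.base_ploidy, dtype=int)
        for chrom, a, b, val in sc.events:
            off = chrom_offsets[chrom]
            cn[off + a: off + b] = val
        profiles[sc.name] = cn
    return pd.DataFrame(profiles)


def simulate_cells(spec: SimSpec, grid: BinGrid,
                   gene_map: pd.DataFrame | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw the cells x bins count matrix, sample sheet, and ground truth.

    Counts are Poisson-gamma: ``counts[c, b]`` has mean proportional to
    depth_c x CN(subclone(c), b) x bin width share x GC bias, with relative
    overdispersion ``spec.overdispersion``.  Diploid contaminants are CN=2
    everywhere and cycle through the sample labels.
    """
    if not spec.subclones:
        raise ValueError("spec must declare at least one subclone")
    _, rng, rng_noise = spec._rngs(3)

    profiles = _subclone_profiles(spec, grid)
    labels: list[str] = []
    samples: list[str] = []
    for sc in spec.subclones:
        labels += [sc.name] * sc.n_cells
        samples += [sc.sample_label] * sc.n_cells

    n_tumor = len(labels)
    f = spec.diploid_fraction
    sample_cycle = sorted({sc.sample_label for sc in spec.subclones})
    if f > 0:
        target = int(round(n_tumor / (1 - f)))
        n_dip = rng.binomial(target, f)
        for i in range(n_dip):
            labels.append("diploid")
            samples.append(sample_cycle[i % len(sample_cycle)])

    n_cells = len(labels)
    order = rng.permutation(n_cells)
    labels = [labels[i] for i in order]
    samples = [samples[i] for i in order]
    cell_ids = [f"cell_{i:04d}" for i in range(n_cells)]

    # per-cell depth: log-normal around the nominal mean, with dropouts
    mu = np.log(spec.reads_per_cell) - spec.reads_sigma**2 / 2
    depth = rng.lognormal(mu, spec.reads_sigma, size=n_cells)
    dropout = rng.random(n_cells) < spec.dropout_cell_fraction
    depth[dropout] *= rng.uniform(0.02, 0.08, size=dropout.sum())

    # per-cell mean mapping quality, with a low-quality tail
    mapq = rng.normal(35.0, 3.0, size=n_cells)
    low_q = rng.random(n_cells) < spec.low_mapq_cell_fraction
    mapq[low_q] = rng.uniform(0.0, 0.9, size=low_q.sum())

    # variable bins are count-equalized: in a diploid genome every bin has
    # the same expected read count, so intensity scales with CN and GC bias
    # only, never with the bin's physical width
    gc_bias = np.exp(-spec.gc_bias_strength *
                     ((grid.gc - 0.5) / 0.2) ** 2)

    counts = np.empty((n_cells, len(grid)), dtype=np.int64)
    diploid_profile = np.full(len(grid), 2, dtype=float)
    for i, lab in enumerate(labels):
        cn = diploid_profile if lab == "diploid" \
            else profiles[lab].to_numpy(float)
        w = cn * gc_bias
        p = w / w.sum()
        mean = depth[i] * p
        if spec.overdispersion > 1e-9:
            lam = rng_noise.gamma(1.0 / spec.overdispersion,
                                  spec.overdispersion * mean)
        else:
            lam = mean
        counts[i] = rng_noise.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(cell_ids,
                                                    name="cell_id"),
                             columns=[f"bin_{j}" for j in range(len(grid))])
    sheet = pd.DataFrame({
        "cell_id": cell_ids,
        "sample": samples,
        "group": [spec.groups.get(s, "baseline") for s in samples],
        "mapq": mapq,
    })

    gt = GroundTruth(
        cell_subclone=pd.Series(labels, index=cell_ids, name="subclone"),
        profiles=profiles,
        diploid_cells=[c for c, l in zip(cell_ids, labels) if l == "diploid"],
        subclone_group={sc.name: spec.groups.get(sc.sample_label, "baseline")
                        for sc in spec.subclones},
        planted_newick=spec.planted_newick,
    )
    if gene_map is not None:
        _gene_truth(spec, profiles, gene_map, gt)
    return counts_df, sheet, gt


def _gene_truth(spec: SimSpec, profiles: pd.DataFrame,
                gene_map: pd.DataFrame, gt: GroundTruth) -> None:
    """Derive planted AR-specific gene sets and preexistence pairs.

    Per gene, the reference baseline copy number is the modal CN among
    baseline-labeled subclones; resistant subclones above (below) it make the
    gene amplified (deleted); baseline subclones deviating in the same
    direction are preexistence carriers.
    """
    group = {sc.name: spec.groups.get(sc.sample_label, "baseline")
             for sc in spec.subclones}
    base = [n for n in profiles.columns if group[n] == "baseline"]
    res = [n for n in profiles.columns if group[n] == "resistant"]
    if not base or not res:
        return
    for _, row in gene_map.iterrows():
        gene = row["gene"]
        bins = row["bins"]
        cn = {n: float(np.median(profiles[n].to_numpy()[bins]))
              for n in profiles.columns}
        base_cns = [cn[n] for n in base]
        vals, counts_ = np.unique(base_cns, return_counts=True)
        modal = float(vals[np.argmax(counts_)])
        if any(cn[n] > modal for n in res):
            gt.ar_amplified.add(gene)
            for n in base:
                if cn[n] > modal:
                    gt.preexisting.add((gene, n, "amplified"))
        if any(cn[n] < modal for n in res):
            gt.ar_deleted.add(gene)
            for n in base:
                if cn[n] < modal:
                    gt.preexisting.add((gene, n, "deleted"))


def simulate_dapi(spec: SimSpec, grid: BinGrid, noise_sd: float = 0.0,
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-sample DAPI A- and D-peak medians consistent with planted ploidy.

    The D peak is the diploid reference; the A peak median scales with the
    cell-weighted, bin-width-weighted mean planted copy number of the
    sample's aneuploid cells, so 2 x (A/D) recovers the planted ploidy up to
    the multiplicative noise ``noise_sd``.
    """
    rng = spec._rngs(3)[1] if rng is None else rng
    profiles = _subclone_profiles(spec, grid)
    wshare = grid.widths / grid.widths.sum()
    rows = []
    for sample in sorted({sc.sample_label for sc in spec.subclones}):
        members = [sc for sc in spec.subclones if sc.sample_label == sample]
        weights = np.array([sc.n_cells for sc in members], float)
        ploidies = np.array([
            float(np.sum(profiles[sc.name].to_numpy(float) * wshare))
            for sc in members])
        ploidy = float(np.average(ploidies, weights=weights))
        d_med = 100.0
        a_med = d_med * ploidy / 2.0
        if noise_sd > 0:
            a_med *= 1.0 + rng.normal(0.0, noise_sd)
            d_med *= 1.0 + rng.normal(0.0, noise_sd)
        rows.append((sample, a_med, d_med, ploidy))
    return pd.DataFrame(rows, columns=["sample", "a_median", "d_median",
                                       "planted_ploidy"])


def make_gene_map(grid: BinGrid, n_genes: int,
                  seed: int = 0, max_bins_per_gene: int = 3) -> pd.DataFrame:
    """Random gene-to-bin projection: each gene covers 1-3 adjacent bins."""
    rng = np.random.default_rng(seed)
    rows = []
    chrom_slices = grid.chromosome_slices()
    for i in range(n_genes):
        chrom, sl = chrom_slices[rng.integers(len(chrom_slices))]
        span = int(rng.integers(1, max_bins_per_gene + 1))
        n = sl.stop - sl.start
        start = int(rng.integers(0, n - span + 1))
        bins = list(range(sl.start + start, sl.start + start + span))
        g0 = grid.table.iloc[bins[0]]
        g1 = grid.table.iloc[bins[-1]]
        rows.append((f"gene_{i:04d}", chrom, int(g0["start"]),
                     int(g1["end"]), bins))
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end",
                                       "bins"])


def simulate_gene_ratio_matrix(seed: int = 0, n_null: int = 40,
                               n_amp: int = 6, n_del: int = 6,
                               n_pre_amp: int = 2, n_pre_del: int = 2,
                               n_baseline: int = 4, n_resistant: int = 3,
                               delta: float = 0.25, pre_delta: float = 0.6,
                               jitter_sd: float = 0.02):
    """Gene-ratio experiment with planted AR-specific and preexisting CNVs.

    Returns a ``GeneRatioMatrix`` plus the planted truth: the baseline
    subclone ratios sit at 1.0 with multiplicative jitter (CV <= ~0.05);
    AR-specific genes shift a random nonempty subset of resistant-dominant
    subclones by ``delta`` (>= 0.2, i.e. about half a copy); preexisting
    genes shift every resistant subclone AND one baseline candidate by
    ``pre_delta`` (a full 0.6 ratio step, large enough to push the baseline
    CV past the 0.18 gate).
    """
    from .resistance import GeneRatioMatrix

    rng = np.random.default_rng(seed)
    base_names = [f"b{i + 1}" for i in range(n_baseline)]
    res_names = [f"r{i + 1}" for i in range(n_resistant)]
    cols = base_names + res_names

    rows, genes = [], []
    truth = {"amplified": {}, "deleted": {}, "preexisting": set()}

    def jitter(n):
        return 1.0 + rng.normal(0.0, jitter_sd, n)

    for i in range(n_null):
        genes.append(f"null_{i}")
        rows.append(np.concatenate([jitter(n_baseline), jitter(n_resistant)]))
    for direction, n_genes, sign in (("amplified", n_amp, 1),
                                     ("deleted", n_del, -1)):
        for i in range(n_genes):
            g = f"{direction[:3]}_{i}"
            genes.append(g)
            k = int(rng.integers(1, n_resistant + 1))
            subset = list(rng.choice(n_resistant, size=k, replace=False))
            res = jitter(n_resistant)
            res[subset] += sign * delta
            rows.append(np.concatenate([jitter(n_baseline), res]))
            truth[direction][g] = {res_names[j] for j in subset}
    for direction, n_genes, sign in (("amplified", n_pre_amp, 1),
                                     ("deleted", n_pre_del, -1)):
        for i in range(n_genes):
            g = f"pre_{direction[:3]}_{i}"
            genes.append(g)
            cand = int(rng.integers(n_baseline))
            base = jitter(n_baseline)
            base[cand] += sign * pre_delta
            res = jitter(n_resistant) + sign * pre_delta
            rows.append(np.concatenate([base, res]))
            truth["preexisting"].add((g, base_names[cand], direction))

    table = pd.DataFrame(rows, index=genes, columns=cols)
    grm = GeneRatioMatrix(ratios=table, baseline=base_names,
                          resistant=res_names)
    return grm, truth


def default_study_spec(seed: int = 0) -> SimSpec:
    """The default desk-scale study conditions.

    2,000 bins over 10 chromosomes, five tumor subclones of 51 cells each
    (two baseline-sample subclones c4/c5, three resistant-sample subclones
    c1-c3 forming a derived clade, mirroring a parental-line-versus-
    acquired-resistance design), 15% diploid contaminants, ~1e5 reads per
    cell.  Events are 60-120 bins wide so that every pair of subclones is
    separated by at least one ratio step of ~0.5.
    """
    trunk = [("chr1", 20, 80, 3), ("chr2", 50, 120, 1)]
    ar_clade = [("chr3", 30, 100, 1), ("chr4", 100, 180, 3)]
    p_clade = [("chr8", 30, 110, 3)]
    subclones = [
        SubcloneSpec("c1", 51, "AR", trunk + ar_clade +
                     [("chr5", 40, 100, 3)]),
        SubcloneSpec("c2", 51, "AR", trunk + ar_clade +
                     [("chr6", 60, 140, 1)]),
        SubcloneSpec("c3", 51, "AR", trunk + ar_clade +
                     [("chr7", 20, 90, 3)]),
        SubcloneSpec("c4", 51, "P", trunk + p_clade +
                     [("chr9", 50, 130, 1)]),
        SubcloneSpec("c5", 51, "P", trunk + p_clade +
                     [("chr10", 80, 160, 3)]),
    ]
    return SimSpec(
        n_bins=2000,
        subclones=subclones,
        groups={"P": "baseline", "AR": "resistant"},
        diploid_fraction=0.15,
        seed=seed,
        planted_newick="(((c1,c2,c3),(c4,c5)),diploid);",
    )
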