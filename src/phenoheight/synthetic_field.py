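"""Synthetic field-trial simulator with known ground truth.

Emulates a UAV phenotyping campaign over a gridded cotton trial: smooth
terrain, per-plot canopies growing along logistic curves sampled at a handful
of flight dates, LiDAR-like point clouds with sensor noise and gross
outliers, an RGB-like surface model, and a genotyped panel with population
structure and planted causal SNPs driving the growth-curve parameters.

Every generator is deterministic given its inputs and seed, and every output
carries its ground truth so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .genotypes import MISSING, GenotypeMatrix
from .pointcloud import GROUND, NOISE, NON_GROUND, PointCloud
from .rasters import DEFAULT_NODATA, RasterGrid, grid_for_bounds


@dataclass
class FieldDesign:
    """Rectangular grid of equal plots separated by alleys.

    Plots default to the 4.5 m x 5.0 m layout of a dense cotton trial.
    Plot indices run row-major from the south-west corner; plot k maps to
    accession k.
    """

    n_rows: int
    n_cols: int
    plot_width_m: float = 4.5  # east-west extent
    plot_length_m: float = 5.0  # north-south extent
    alley_m: float = 0.5
    origin: tuple[float, float] = (0.0, 0.0)  # south-west corner

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols < 1:
            raise ValueError("field must contain at least one plot")
        if self.plot_width_m <= 0 or self.plot_length_m <= 0:
            raise ValueError("plot dimensions must be positive")
        if self.alley_m < 0:
            raise ValueError("alley width cannot be negative")

    @property
    def n_plots(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def pitch(self) -> tuple[float, float]:
        return (self.plot_width_m + self.alley_m, self.plot_length_m + self.alley_m)

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) including a half-alley border."""
        px, py = self.pitch
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * px, y0 + self.n_rows * py)

    def plot_rectangle(self, index: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one plot's planted rectangle."""
        if not 0 <= index < self.n_plots:
            raise IndexError("plot index out of range")
        r, c = divmod(index, self.n_cols)
        px, py = self.pitch
        x0 = self.origin[0] + c * px + self.alley_m / 2
        y0 = self.origin[1] + r * py + self.alley_m / 2
        return (x0, y0, x0 + self.plot_width_m, y0 + self.plot_length_m)

    def plot_ids(self) -> list[str]:
        width = len(str(self.n_plots))
        return [f"P{i + 1:0{width}d}" for i in range(self.n_plots)]


@dataclass
class GrowthTruth:
    """True per-accession growth curves and their cluster structure."""

    heights: np.ndarray  # accessions x time points, metres
    cluster_id: np.ndarray  # per-accession cluster label (0..k-1)
    curve_params: np.ndarray  # accessions x 3: (asymptote, rate, midpoint)
    times: np.ndarray  # days after first flight

    @property
    def n_accessions(self) -> int:
        return self.heights.shape[0]

    @property
    def n_times(self) -> int:
        return self.heights.shape[1]


@dataclass
class SensorConfig:
    """Acquisition conditions for one simulated flight."""

    point_density: float = 100.0  # returns per square metre
    noise_sd: float = 0.02  # metres, vertical
    outlier_rate: float = 0.01  # fraction of gross +-5 m outliers
    canopy_cover: float = 0.6  # fraction of plot area under canopy
    seed: int = 0

    def __post_init__(self) -> None:
        if self.point_density <= 0:
            raise ValueError("point density must be positive")
        for name in ("outlier_rate", "canopy_cover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd cannot be negative")


@dataclass
class GenotypeTruth:
    """Planted genetic architecture for the simulated panel."""

    causal_indices: np.ndarray = field(default_factory=lambda: np.array([], int))
    effect_sizes: np.ndarray = field(default_factory=lambda: np.array([], float))
    h2: float = 0.5
    n_subpop: int = 2
    fst_like: float = 0.1

    def __post_init__(self) -> None:
        self.causal_indices = np.asarray(self.causal_indices, dtype=int)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("h2 must lie in (0, 1]")
        if len(self.causal_indices) != len(self.effect_sizes):
            raise ValueError("one effect size per causal SNP is required")


def generate_terrain(
    design: FieldDesign, relief_amplitude: float, cell: float, seed: int
) -> RasterGrid:
    """Smooth band-limited terrain covering the field extent.

    Gaussian-filtered white noise rescaled so the maximum deviation from the
    mean elevation equals ``relief_amplitude`` (hence max - min <= 2A).
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if relief_amplitude < 0:
        raise ValueError("relief amplitude cannot be negative")
    origin, shape = grid_for_bounds(design.extent(), cell)
    rng = np.random.default_rng(seed)
    values = np.zeros(shape)
    if relief_amplitude > 0:
        noise = rng.standard_normal(shape)
        # correlation length ~8 m keeps within-plot slopes gentle
        sigma_cells = max(1.0, 8.0 / cell)
        smooth = ndimage.gaussian_filter(noise, sigma=sigma_cells, mode="nearest")
        smooth -= smooth.mean()
        peak = np.abs(smooth).max()
        if peak > 0:
            values = smooth * (relief_amplitude / peak)
    return RasterGrid(values, origin, cell)


def _logistic(t: np.ndarray, K: np.ndarray, r: np.ndarray, t0: np.ndarray) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t0)))


def generate_growth_truth(
    n_accessions: int,
    n_times: int = 5,
    n_clusters: int = 5,
    separation: float = 4.0,
    seed: int = 0,
    season_days: float = 27.0,
) -> GrowthTruth:
    """Logistic growth curves for a panel, grouped into rate-ordered clusters.

    Cluster means of the logistic rate (and of the asymptote, mirroring the
    ordering of final heights across clusters) are spaced ``separation``
    within-cluster standard deviations apart. Heights are sampled at
    ``n_times`` evenly spaced flight dates across ``season_days`` days.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if n_clusters > n_accessions:
        raise ValueError("more clusters than accessions")
    if n_times < 2:
        raise ValueError("need at least two time points")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, season_days, n_times)

    # all accessions are sown on one date, so the curve midpoint varies far
    # less than asymptote and rate; separation acts on rate and asymptote
    sd_rate, sd_K, sd_t0 = 0.008, 0.025, 0.5
    base_rate, base_K, base_t0 = 0.12, 0.70, season_days / 2.0
    k_idx = np.arange(n_clusters)
    rate_means = base_rate + k_idx * separation * sd_rate
    K_means = base_K + k_idx * separation * sd_K

    # balanced assignment, shuffled so cluster labels are not positional
    cluster_id = np.resize(k_idx, n_accessions)
    rng.shuffle(cluster_id)

    rate = np.maximum(rng.normal(rate_means[cluster_id], sd_rate), 0.01)
    K = np.maximum(rng.normal(K_means[cluster_id], sd_K), 0.05)
    t0 = rng.normal(base_t0, sd_t0, n_accessions)
    heights = _logistic(times[None, :], K[:, None], rate[:, None], t0[:, None])
    params = np.column_stack([K, rate, t0])
    return GrowthTruth(heights, cluster_id, params, times)


def apply_genetic_effects(truth: GrowthTruth, shift_m: np.ndarray) -> GrowthTruth:
    """Shift per-accession asymptotes by a genetic value and resample curves.

    Links the genotype simulator to the growth simulator: an accession's
    genetic value (metres) moves its mature height, so causal SNPs become
    detectable in the extracted height series.
    """
    shift_m = np.asarray(shift_m, dtype=float)
    if shift_m.shape != (truth.n_accessions,):
        raise ValueError("one shift per accession is required")
    K = np.maximum(truth.curve_params[:, 0] + shift_m, 0.05)
    r = truth.curve_params[:, 1]
    t0 = truth.curve_params[:, 2]
    heights = _logistic(truth.times[None, :], K[:, None], r[:, None], t0[:, None])
    return GrowthTruth(
        heights, truth.cluster_id, np.column_stack([K, r, t0]), truth.times
    )


def canopy_rectangle(
    design: FieldDesign, plot_index: int, cover: float
) -> tuple[float, float, float, float]:
    """Centred rectangle over ``cover`` of the plot area (aspect preserved)."""
    xmin, ymin, xmax, ymax = design.plot_rectangle(plot_index)
    s = np.sqrt(cover)
    dx = (xmax - xmin) * (1 - s) / 2
    dy = (ymax - ymin) * (1 - s) / 2
    return (xmin + dx, ymin + dy, xmax - dx, ymax - dy)


def _plot_heights_at(truth: GrowthTruth, design: FieldDesign, time_point: int) -> np.ndarray:
    if not 0 <= time_point < truth.n_times:
        raise IndexError("time point outside the growth truth range")
    if truth.n_accessions < design.n_plots:
        raise ValueError("growth truth covers fewer accessions than plots")
    return truth.heights[: design.n_plots, time_point]


def generate_point_cloud(
    terrain: RasterGrid,
    design: FieldDesign,
    truth: GrowthTruth,
    time_point: int,
    sensor: SensorConfig,
) -> PointCloud:
    """LiDAR-like returns: soil on the terrain, canopy plateaus on the plots.

    Points fall uniformly over the field extent at ``sensor.point_density``;
    returns inside a plot's canopy rectangle sit at terrain + true height.
    A fraction ``outlier_rate`` is displaced by +-5 m to exercise denoising.
    Ground-truth class labels are retained in ``truth_class``.
    """
    heights = _plot_heights_at(truth, design, time_point)
    xmin, ymin, xmax, ymax = design.extent()
    area = (xmax - xmin) * (ymax - ymin)
    if area <= 0:
        raise ValueError("empty field extent")
    rng = np.random.default_rng(np.random.SeedSequence([sensor.seed, time_point]))
    n = rng.poisson(sensor.point_density * area)
    x = rng.uniform(xmin, xmax, n)
    y = rng.uniform(ymin, ymax, n)
    z = terrain.sample(x, y)
    truth_class = np.full(n, GROUND, dtype=np.int8)

    if sensor.canopy_cover > 0:
        px, py = design.pitch
        col = np.floor((x - design.origin[0]) / px).astype(int)
        row = np.floor((y - design.origin[1]) / py).astype(int)
        col = np.clip(col, 0, design.n_cols - 1)
        row = np.clip(row, 0, design.n_rows - 1)
        plot = row * design.n_cols + col
        # canopy rectangle test, vectorised via the shared inset geometry
        s = np.sqrt(sensor.canopy_cover)
        cx0 = design.origin[0] + col * px + _canopy_inset(design.alley_m, design.plot_width_m, s)
        cy0 = design.origin[1] + row * py + _canopy_inset(design.alley_m, design.plot_length_m, s)
        in_canopy = (
            (x >= cx0)
            & (x <= cx0 + design.plot_width_m * s)
            & (y >= cy0)
            & (y <= cy0 + design.plot_length_m * s)
        )
        z = np.where(in_canopy, z + heights[plot], z)
        truth_class[in_canopy] = NON_GROUND

    if sensor.noise_sd > 0:
        z = z + rng.normal(0.0, sensor.noise_sd, n)
    if sensor.outlier_rate > 0:
        out = rng.random(n) < sensor.outlier_rate
        z = np.where(out, z + rng.choice([-5.0, 5.0], n), z)
        truth_class[out] = NOISE
    return PointCloud(x, y, z, truth_class=truth_class)


def _canopy_inset(alley: float, dim: float, s: float) -> float:
    """Offset from the plot-pitch corner to the canopy rectangle edge."""
    return alley / 2 + dim * (1 - s) / 2


def generate_dsm(
    terrain: RasterGrid,
    design: FieldDesign,
    truth: GrowthTruth,
    time_point: int,
    sensor: SensorConfig,
    cell: float,
) -> RasterGrid:
    """RGB-photogrammetry-like surface model (no separate ground flight).

    One raster mixing soil cells at terrain elevation with canopy cells at
    terrain + true height, plus vertical noise — the single-surface product a
    structure-from-motion pipeline yields when bare-ground imagery was never
    acquired.
    """
    if cell <= 0:
        raise ValueError("cell size must be positive")
    if cell > min(design.plot_width_m, design.plot_length_m):
        raise ValueError("cell larger than a plot dimension")
    heights = _plot_heights_at(truth, design, time_point)
    origin, shape = grid_for_bounds(design.extent(), cell)
    grid = RasterGrid(np.zeros(shape), origin, cell)
    xc = grid.x_centers()
    yc = grid.y_centers()
    X, Y = np.meshgrid(xc, yc)
    values = terrain.sample(X, Y)

    px, py = design.pitch
    col = np.clip(np.floor((X - design.origin[0]) / px).astype(int), 0, design.n_cols - 1)
    row = np.clip(np.floor((Y - design.origin[1]) / py).astype(int), 0, design.n_rows - 1)
    plot = row * design.n_cols + col
    if sensor.canopy_cover > 0:
        s = np.sqrt(sensor.canopy_cover)
        cx0 = design.origin[0] + col * px + _canopy_inset(design.alley_m, design.plot_width_m, s)
        cy0 = design.origin[1] + row * py + _canopy_inset(design.alley_m, design.plot_length_m, s)
        in_canopy = (
            (X >= cx0)
            & (X <= cx0 + design.plot_width_m * s)
            & (Y >= cy0)
            & (Y <= cy0 + design.plot_length_m * s)
        )
        values = np.where(in_canopy, values + heights[plot], values)
    if sensor.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([sensor.seed, time_point, 1]))
        values = values + rng.normal(0.0, sensor.noise_sd, values.shape)
    return RasterGrid(values, origin, cell)


def generate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    missing_rate: float = 0.02,
    truth: GenotypeTruth | None = None,
    seed: int = 0,
    n_chrom: int = 5,
    chrom_length_bp: int = 100_000_000,
) -> GenotypeMatrix:
    """Structured diploid panel via a Balding-Nichols drift model.

    Ancestral allele frequencies are uniform on ``maf_range``; each of
    ``truth.n_subpop`` subpopulations draws its own frequency from a Beta
    distribution with differentiation ``truth.fst_like`` (0 = panmictic).
    Missing calls are MCAR at ``missing_rate``.
    """
    if truth is None:
        truth = GenotypeTruth()
    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    if truth.causal_indices.size and truth.causal_indices.max() >= n_snps:
        raise ValueError("causal index out of range")
    rng = np.random.default_rng(seed)

    p_anc = rng.uniform(lo, hi, n_snps)
    flip = rng.random(n_snps) < 0.5  # minor allele is ref or alt with equal odds
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    subpop = np.resize(np.arange(truth.n_subpop), n_samples)
    F = truth.fst_like
    dosages = np.empty((n_samples, n_snps), dtype=np.int8)
    for s in range(truth.n_subpop):
        if F > 0:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            p_s = np.clip(rng.beta(a, b), 1e-6, 1.0 - 1e-6)
        else:
            p_s = p_anc
        members = subpop == s
        dosages[members] = rng.binomial(2, p_s, (members.sum(), n_snps)).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages[miss] = MISSING

    per_chrom = np.array_split(np.arange(n_snps), n_chrom)
    chrom = np.empty(n_snps, dtype=object)
    pos = np.empty(n_snps, dtype=np.int64)
    for c, idx in enumerate(per_chrom):
        name = f"A{c + 1:02d}"
        chrom[idx] = name
        pos[idx] = np.sort(rng.choice(chrom_length_bp, size=len(idx), replace=False)) + 1
    snp_ids = np.array([f"{c}_{p}" for c, p in zip(chrom, pos)], dtype=object)
    sample_ids = np.array([f"ACC{i + 1:04d}" for i in range(n_samples)], dtype=object)
    return GenotypeMatrix(dosages, chrom, pos, sample_ids, snp_ids)


def generate_phenotypes(
    G: GenotypeMatrix,
    truth: GenotypeTruth,
    n_reps: int = 3,
    seed: int = 0,
    poly_frac: float = 0.3,
    strat_frac: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Replicated phenotype records from causal SNPs + a polygenic term.

    phenotype = sum(effect x dosage) + polygenic + residual. The polygenic
    term combines a multivariate-normal draw with covariance proportional to
    the panel's genomic relationship matrix (VanRaden GRM of standardised
    dosages) with, when the panel is structured, a systematic trait shift
    between subpopulations carrying ``strat_frac`` of the polygenic variance
    — the stratification signal a naive unadjusted scan confounds on. The
    polygenic block carries ``poly_frac`` of the genetic variance, and the
    residual is scaled so the realised narrow-sense heritability matches
    ``truth.h2``. Returns the long-format record table and the per-accession
    true genetic values.
    """
    if truth.causal_indices.size and truth.causal_indices.max() >= G.n_snps:
        raise ValueError("causal index out of range")
    if not 0.0 <= poly_frac < 1.0:
        raise ValueError("poly_frac must lie in [0, 1)")
    if not 0.0 <= strat_frac <= 1.0:
        raise ValueError("strat_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    X = G.imputed()
    n = G.n_samples

    causal = np.zeros(n)
    baseline = 0.0
    if truth.causal_indices.size:
        causal = X[:, truth.causal_indices] @ truth.effect_sizes
        baseline = causal.mean()
    genetic = causal - baseline  # centred causal component

    if poly_frac > 0:
        Z = X - X.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = 1.0
        Zs = Z / sd
        grm = Zs @ Zs.T / G.n_snps
        lam, U = np.linalg.eigh(grm)
        lam = np.clip(lam, 0.0, None)
        u = U @ (np.sqrt(lam) * rng.normal(0.0, 1.0, n))
        u -= u.mean()
        if truth.n_subpop > 1 and truth.fst_like > 0 and strat_frac > 0 and u.std() > 0:
            subpop = np.resize(np.arange(truth.n_subpop), n)
            contrast = (subpop == 0).astype(float)
            contrast -= contrast.mean()
            u = u * np.sqrt(1.0 - strat_frac) + contrast * (
                u.std() * np.sqrt(strat_frac) / contrast.std()
            )
        var_c = genetic.var()
        target = (
            var_c * poly_frac / (1.0 - poly_frac) if var_c > 0 else u.var() or 1.0
        )
        if u.var() > 0:
            u = u * np.sqrt(target / u.var())
        genetic = genetic + u

    var_g = genetic.var()
    var_e = var_g * (1.0 - truth.h2) / truth.h2 if var_g > 0 else 0.0
    records = []
    for rep in range(n_reps):
        resid = rng.normal(0.0, np.sqrt(var_e), n) if var_e > 0 else np.zeros(n)
        values = genetic + baseline + resid
        records.append(
            pd.DataFrame(
                {
                    "accession": G.sample_ids,
                    "replicate": rep + 1,
                    "value": values,
                }
            )
        )
    table = pd.concat(records, ignore_index=True)
    return table, genetic


def generate_annotation(
    G: GenotypeMatrix,
    truth: GenotypeTruth,
    genes_per_chrom: int = 20,
    gene_span_bp: int = 5_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy gene annotation: random genes plus one spanning each causal SNP.

    Returns 1-based inclusive gene records (chrom, start, end, gene_id, name).
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 1
    for c in dict.fromkeys(G.chrom.astype(str)):
        sel = G.chrom.astype(str) == c
        span = int(G.pos[sel].max()) + gene_span_bp
        starts = np.sort(rng.choice(max(span - gene_span_bp, 1), genes_per_chrom, replace=False)) + 1
        for s in starts:
            rows.append((c, int(s), int(s + gene_span_bp - 1), f"gene{counter:04d}"))
            counter += 1
    for idx in truth.causal_indices:
        c = str(G.chrom[idx])
        p = int(G.pos[idx])
        start = max(1, p - gene_span_bp // 2)
        rows.append((c, start, start + gene_span_bp - 1, f"causal_gene_{idx}"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
    df["name"] = df["gene_id"]
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_gff3(annotation: pd.DataFrame, path: str) -> None:
    """Write gene records as a minimal GFF3 file."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, r in annotation.iterrows():
            attrs = f"ID={r.gene_id};Name={r['name']}"
            fh.write(
                f"{r.chrom}\tsynthetic\tgene\t{r.start}\t{r.end}\t.\t+\t.\t{attrs}\n"
            )
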