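# Methods

`phenoheight` implements, end to end, the analysis chain of a UAV
multisensor plant-height phenotyping campaign over a gridded field trial —
from raw sensor geometry to per-plot heights, calibrated predictions, growth
clusters, and a kinship-corrected association scan — together with a
simulator that generates every input with known ground truth. This note
documents the models, the defaults and why they were chosen, and what the
synthetic data do and do not demonstrate.

## The synthetic field

**Layout.** Plots are 4.5 m x 5.0 m rectangles on a regular grid separated by
0.5 m alleys, plot k carrying accession k. The default demonstration field is
10 x 6 = 60 plots; all study-scale analyses (clustering, association) run on
419 accessions, the size of a realistic upland-cotton diversity panel.

**Terrain.** Gaussian-filtered white noise with an ~8 m correlation length,
rescaled so the maximum deviation from mean elevation equals
`relief_amplitude` (default 0.3 m). Within a plot the terrain is therefore
gentle but not flat, which is what makes the percentile height extraction
(rather than a fixed datum) necessary in the first place.

**Growth.** Each accession follows a 3-parameter logistic
h(t) = K / (1 + exp(-r (t - t0))) sampled at five flight dates across a
27-day window of rapid vegetative growth. Accessions belong to one of
`n_clusters` groups whose means of r and K are both spaced
`separation` x the within-cluster standard deviation apart (sd_r = 0.008 /d,
sd_K = 0.025 m), giving slow-to-tall orderings of both growth rate and final
height. The curve midpoint varies only a little (sd 0.5 d): all accessions
are sown on one date, so maturity timing, not onset, separates groups. This
matters — a large midpoint spread would dominate within-cluster height
variance and void the separation contract.

**Canopy and sensors.** A plot's canopy is a centred rectangular plateau
covering `canopy_cover` (default 0.6) of the plot at the accession's current
height: sufficient geometry for plot-level percentile extraction, which never
looks at individual stems. LiDAR-like clouds put uniform returns at
`point_density` (default 100 m^-2) on the terrain (soil) or on the plateau
(canopy), with Gaussian vertical noise (default sd 0.02 m) and a fraction
(default 1%) of gross +-5 m outliers to exercise denoising. The RGB branch
gets a single mixed surface raster (soil cells at terrain height, canopy
cells at terrain + plant height, plus noise) — the product a
structure-from-motion pipeline yields when no bare-ground flight exists.

**Genotypes and phenotypes.** Dosages follow a Balding–Nichols model:
ancestral frequencies uniform on the MAF range, subpopulation frequencies
Beta-drifted with differentiation `fst_like`, missing calls MCAR. The
phenotype is
`sum(effect x dosage) + polygenic + residual`, where the polygenic term is a
multivariate-normal draw with covariance proportional to the VanRaden
genomic relationship matrix plus — in structured panels — a systematic trait
shift between subpopulations (`strat_frac`, default half the polygenic
variance). The stratification component is deliberate: it is exactly the
confounder that inflates a naive unadjusted scan (observed genomic-control
lambda 5–19) and that the mixed model must absorb (observed lambda
0.95–1.08). The residual is scaled so realised narrow-sense heritability
matches the target h2. In the pipeline the per-accession genetic value also
shifts the growth-curve asymptote, so planted SNPs are detectable from
extracted heights.

## Surface models

The LiDAR chain is the standard open equivalent of commercial preprocessing:

1. **Voxel thinning** (default 0.03 m) keeps one point per voxel, the one
   closest to the voxel centroid.
2. **Statistical outlier removal** (k = 8 neighbours, 3 sigma on the mean
   k-NN distance) drops gross outliers.
3. **Ground classification**: per-cell minima on a 0.25 m grid, gap-filled
   from nearest cells, then a grey-scale morphological opening with a 4 m
   window — larger than any canopy footprint, so vegetated blobs are planed
   off the minimum surface. Points within `slope_tol` (0.10 m) above the
   opened surface are ground. On flat fields precision and recall against
   simulator truth both exceed 0.95; on undulating terrain recall drops
   (opening undershoots convex terrain) while precision stays near 1, which
   is the right trade for DTM fitting.
4. **DSM**: per-cell maximum of non-noise returns (empty cells nodata).
   **DTM**: Delaunay/linear interpolation of ground points,
   nearest-neighbour fill outside the hull. **CHM = DSM − DTM**, clamped at
   zero (negative canopy height is physically meaningless), nodata
   propagating.

Default raster cell is 0.05 m — fine enough that per-plot aggregation sees
thousands of cells, coarse enough to keep a 60-plot field in memory.

## Height extraction

RGB (no ground model): plot height is max(percentiles 95–98) −
min(percentiles 1–2) of within-mask DSM values, evaluated on the integer
percentile grid with linear interpolation (type-7). By percentile
monotonicity this equals p98 − p1; both band endpoints are evaluated and the
identity is exercised in tests. The construction is invariant to the
absolute elevation datum. LiDAR: the 95th percentile of within-mask CHM
values by default (robust to residual outliers; `max` and mean-top-decile
are available — the manual reference value averages a dozen stem tops, so a
high quantile, not the maximum, matches it best). Masks are plot rectangles
inset by `shrink` (default 0.1 per side) with cell-centre point-in-polygon
inclusion, boundary cells excluded.

On the 60-plot reference field the LiDAR branch recovers true heights with
RMSE ≈ 0.04 m under default noise and < 0.01 m noiseless. The RGB percentile
spread additionally absorbs the within-plot terrain relief into its estimate
(a real limitation of the method, not of the implementation); the
calibration stage removes the systematic part.

## Calibration

Polynomials of degree 1–3 plus twelve regression families (random forest,
k-NN, Huber, least-angle, ridge, LightGBM, decision tree, extra trees,
orthogonal matching pursuit, Bayesian ridge, AdaBoost, and gradient-boosted
trees standing in for CatBoost) map extracted to manually measured heights.
The protocol pools a small set of surveyed plots across all flights
(24 plots x 5 flights = 120 pairs by default), fits every family, scores the
training fit with R², MAE, MSE (RMSE = sqrt(MSE)), RMSLE and MAPE, selects
the family with the largest training R² (RMSE tiebreak), and validates by
Spearman rank correlation between predictions and whole-field measurements
at the last two flights, excluding cells used in training. Note the known
consequence of training-set selection: memorising families (trees, 1-NN)
reach R² = 1 on the training pairs and can win the label even when a
low-order polynomial generalises equally well; the held-out Spearman numbers
are the check on that. Metric edge cases: zero-variance measurements leave
R² undefined (NaN, never 0); RMSLE requires values > −1; MAPE skips
zero-valued measurements.

## Growth clustering

K-means (Lloyd, k-means++ starts, best of 10 restarts) on the raw
plots x flights height matrix in metres — absolute scale is the signal here,
so no z-scoring. Two cluster-count criteria are computed: the WCSS elbow
(largest second difference) and the gap statistic. The gap implementation
follows the reference R implementation's defaults: uniform reference sets
drawn in the PCA-aligned bounding box (growth trajectories are elongated
clouds; an axis-aligned box over-disperses references), within-cluster
dispersion from plain (unsquared) pairwise distances, and the
one-standard-error selection rule — the smallest k whose gap is within one
reference standard error of the next. The raw argmax of the gap curve is
also reported; on trajectory data it overshoots because splitting an
elongated cluster keeps paying. With the defaults, 5-cluster synthetic
panels (separation 4, n = 419, B = 50) are recovered as k = 5 in 95–100% of
seeds with adjusted Rand index ≈ 0.95.

## Association

Per-accession phenotypes are BLUEs from a two-way fixed-effects model
(accession + replicate, sum-to-zero replicate coding), which reduces exactly
to accession means on balanced designs and passes single-replicate records
through — both field layouts (single plot per accession, or three replicate
plots) are supported. SNPs are filtered at MAF strictly > 0.05 and
missingness strictly < 10%, frequencies computed on non-missing calls.

The scan is the EMMAX approximation to the single-marker mixed model
y = Xb + g*beta + u + e, u ~ N(0, sg2 K), e ~ N(0, se2 I) with K the
identity-by-state kinship (mean-imputed dosages): the variance ratio
delta = se2/sg2 is estimated once by REML under the null via the
eigendecomposition of K (grid search plus bounded 1-D refinement, tolerance
1e-8), then every marker is tested by generalised least squares with the
weights fixed, t-distributed Wald statistic on n − q − 1 degrees of freedom.
With K = I the procedure is algebraically identical to per-marker OLS
(verified to |Δ log10 p| < 1e-14). Missing dosages are mean-imputed for
kinship and scan; haplotype grouping instead excludes non-homozygous calls.

Significance uses the flat threshold −log10 p ≥ 5. Significant SNPs closer
than 500 kb merge into peaks; a peak is replicated when a peak from another
time point comes within the same window (strict interval intersection would
never replicate single-SNP peaks whose top markers sit a few bp apart).
Gene lookup is 1-based inclusive interval overlap (≥ 1 bp) against GFF3 gene
records. Manhattan export adds a cumulative genome coordinate; QQ export
uses expected quantiles −log10((i − 0.5)/m).

Measured operating characteristics at n = 419, 2,000 SNPs, 2
subpopulations, h2 = 0.5: type-I error 0.047–0.056 at alpha = 0.05 (binomial
CI half-width 0.010), genomic-control lambda 0.88–1.08 across seeds
(sampling spread of the median-based estimator is about 0.06), power 90–100%
for a causal SNP explaining 10% of phenotypic variance at the −log10 p = 5
threshold, and such a SNP is reported inside a cross-time replicated peak.

## Pipeline, formats, determinism

`phenoheight run` executes simulate → surfaces → extract → calibrate →
cluster → gwas from one YAML config; each stage gets a sub-seed derived from
the global seed via `SeedSequence`, and the manifest records parameters,
seeds, outputs and SHA-256 checksums. Two runs with the same seed produce
byte-identical tables. Because no LAS or GeoTIFF writer is available in the
dependency set, persistence uses open text formats throughout: gzipped
`x y z class` point clouds, ESRI ASCII grids for rasters, GeoJSON plot
polygons, VCF 4.2 (GT) genotypes read back through cyvcf2, GFF3 annotation,
and CSV/TSV tables.

## What the synthetic data do not show

The canopy is a plateau, so extraction never faces leaf-angle, row-gap or
penetration effects; sensor noise is homoscedastic Gaussian without strip
misalignment or georeferencing drift; genotypes are LD-free with exactly two
ancestral populations; growth is strictly logistic with no stress or lodging
events. Passing recovery tests here demonstrates the correctness of the
algorithms and their wiring, not field-grade accuracy; the real-data
headline correlations of the study motivating this design are not
reproducible from a simulator and are not claimed.

## Problem sizes used by tests and the acceptance script

Unit tests run on desk-scale fields (6–9 plots); the recovery analyses use
the 60-plot field for raster work and 419 accessions x 2,000 SNPs for
clustering and association; the power study uses 50 phenotype replicates on
one genotype panel; the determinism check uses a 9-plot, 3-flight, 300-SNP
run. These sizes keep every analysis comfortably reproducible on a laptop
while preserving the statistical regimes (n = 419 panels, 10%-variance
QTLs) that the operating characteristics depend on.
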