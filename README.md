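# phenoheight

High-throughput plant-height phenotyping from UAV sensors, and the genetics
downstream of it, as a tested Python library.

Field breeders increasingly replace manual height measurements with drone
campaigns: a LiDAR point cloud is classified into ground and canopy returns
and differenced into a canopy height model (CHM = DSM − DTM), while an RGB
photogrammetry surface — flown without any bare-ground reference — yields
plot height as the spread between a high percentile (stem tops, 95–98%) and
a low percentile (visible soil, 1–2%) of within-plot elevations. The
extracted heights are calibrated against a small manually surveyed subset,
the calibrated time series cluster accessions into growth types, and
per-flight heights feed a kinship-corrected genome-wide association scan
(EMMAX-style mixed model) whose significant peaks are intersected across
flights and annotated with overlapping genes.

`phenoheight` implements that entire chain, plus a synthetic field-trial
simulator (terrain, growing canopies, LiDAR-like point clouds, RGB-like
surface rasters, structured genotypes with planted causal SNPs) so every
stage can be tested against known truth without any downloads.

## The core statistics

* **Height extraction.** RGB: `PH = max(p95..p98) − min(p1..p2)` of
  within-mask DSM values (datum-free by construction). LiDAR: the 95th
  percentile of within-mask CHM values.
* **Calibration.** Polynomials (degree 1–3) and twelve standard regression
  families map extracted to measured height, scored with
  `R² = 1 − Σ(Zmᵢ−Zpᵢ)²/Σ(Zmᵢ−Z̄m)²`, MAE, MSE, `RMSE = √MSE`, RMSLE and
  MAPE, validated by Spearman rank correlation on held-out flights.
* **Cluster count.** Tibshirani's gap statistic,
  `gap(k) = E*[log Wₖ] − log Wₖ`, with PCA-aligned uniform references and
  one-standard-error selection, next to the WCSS elbow.
* **Association.** `y = Xb + gβ + u + e`, `u ~ N(0, σg²K)` with K the IBS
  kinship; variance components fit once by REML on the eigenbasis of K, each
  SNP then tested by GLS (the EMMAX approximation). Flat significance
  threshold −log10 p ≥ 5; peaks merged within 500 kb and flagged replicated
  across flights.

## Worked example

```python
import numpy as np
from phenoheight import synthetic_field as sf, surface_models as sm, plot_extraction as pe

design  = sf.FieldDesign(3, 2)                       # 6 plots of 4.5 m x 5 m
terrain = sf.generate_terrain(design, relief_amplitude=0.3, cell=0.05, seed=1)
growth  = sf.generate_growth_truth(design.n_plots, n_times=5, n_clusters=3, seed=2)
sensor  = sf.SensorConfig(point_density=100, noise_sd=0.02, outlier_rate=0.01,
                          canopy_cover=0.6, seed=3)

cloud = sf.generate_point_cloud(terrain, design, growth, time_point=4, sensor=sensor)
clean = sm.denoise(cloud, k_neighbors=8, n_sigma=3.0)
cls   = sm.classify_ground(clean, cell=0.25, slope_tol=0.10)
b     = design.extent()
chm   = sm.compute_chm(sm.rasterize_dsm(cls, 0.05, bounds=b),
                       sm.interpolate_dtm(cls, 0.05, bounds=b))
masks = pe.build_plot_masks(design, shrink=0.1)
extracted = np.array([pe.extract_lidar_ph(chm, m) for m in masks])

print(np.round(growth.heights[:, 4], 3))   # true heights
print(np.round(extracted, 3))              # LiDAR-extracted heights
```

prints

```
[0.546 0.862 0.834 0.698 0.58  0.716]
[0.585 0.905 0.868 0.74  0.624 0.758]
```

— per-plot heights recovered to a few centimetres under 2 cm sensor noise
and 1% gross outliers (the small positive bias is the per-cell-maximum DSM
convention; the calibration stage absorbs it). The full chain runs from one
config:

```bash
phenoheight run --config run.yaml --seed 1 --out results_dir
```

with subcommands `simulate`, `surfaces`, `extract`, `calibrate`, `cluster`
and `gwas` exposing the individual stages on files (gzipped XYZ point
clouds, ESRI ASCII grid rasters, GeoJSON plot polygons, VCF genotypes, GFF3
annotation, CSV tables).

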