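"""End-to-end orchestration: simulate -> surfaces -> extract -> calibrate ->
cluster -> gwas, driven by one config with a single global seed.

Every stochastic stage receives a sub-seed derived from the global seed via
``numpy.random.SeedSequence``, recorded in the run manifest together with
stage parameters, output files and their checksums, so a run is fully
self-describing and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import calibration as cal
from . import growth_clustering as gc
from . import plot_extraction as pe
from . import surface_models as sm
from . import synthetic_field as sf
from .genotypes import write_vcf
from .pointcloud import write_xyz
from .rasters import write_ascii_grid

log = logging.getLogger("phenoheight")

STAGES = ["simulate", "surfaces", "extract", "calibrate", "cluster", "gwas"]


@dataclass
class RunConfig:
    """Flat parameter blocks for each pipeline stage."""

    seed: int = 0
    outdir: str = "phenoheight_run"
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # field & simulation
    n_rows: int = 10
    n_cols: int = 6
    n_times: int = 5
    n_clusters: int = 5
    separation: float = 4.0
    relief_amplitude: float = 0.3
    raster_cell: float = 0.05
    point_density: float = 100.0
    noise_sd: float = 0.02
    outlier_rate: float = 0.01
    canopy_cover: float = 0.6
    # genotypes & phenotype architecture
    n_snps: int = 2000
    maf_min: float = 0.05
    maf_max: float = 0.5
    missing_rate: float = 0.02
    n_subpop: int = 2
    fst_like: float = 0.1
    h2: float = 0.6
    n_causal: int = 2
    causal_effect_m: float = 0.03
    poly_frac: float = 0.2
    n_reps: int = 1
    # extraction / calibration / clustering / scan
    shrink: float = 0.1
    lidar_aggregator: str = "p95"
    n_train_plots: int = 24
    measurement_noise_sd: float = 0.01
    families: list[str] = field(default_factory=lambda: list(cal.ALL_FAMILIES))
    k_max: int = 8
    gap_B: int = 50
    threshold_neg_log10: float = 5.0
    merge_window: int = 500_000

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: str, **kw) -> str:
    df.to_csv(path, float_format="%.8g", **kw)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; return the run manifest."""
    return _run(config, {})


def _require(state: dict, key: str, stage: str, upstream: str) -> None:
    if key not in state:
        raise ValueError(f"stage {stage!r} needs output of stage {upstream!r}")


def _stage_simulate(config: RunConfig, seed: int, state: dict, record) -> None:
    out = config.outdir
    design = sf.FieldDesign(config.n_rows, config.n_cols)
    n_acc = design.n_plots
    terrain = sf.generate_terrain(design, config.relief_amplitude, config.raster_cell, seed)
    growth = sf.generate_growth_truth(
        n_acc, config.n_times, config.n_clusters, config.separation, seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    causal = np.sort(rng.choice(config.n_snps, config.n_causal, replace=False))
    gtruth = sf.GenotypeTruth(
        causal_indices=causal,
        effect_sizes=np.full(config.n_causal, config.causal_effect_m),
        h2=config.h2,
        n_subpop=config.n_subpop,
        fst_like=config.fst_like,
    )
    G = sf.generate_genotypes(
        n_acc,
        config.n_snps,
        (config.maf_min, config.maf_max),
        config.missing_rate,
        gtruth,
        seed=seed + 3,
    )
    pheno, genetic = sf.generate_phenotypes(
        G, gtruth, n_reps=config.n_reps, seed=seed + 4, poly_frac=config.poly_frac
    )
    growth = sf.apply_genetic_effects(growth, genetic - genetic.mean())
    annotation = sf.generate_annotation(G, gtruth, seed=seed + 5)

    sensors = [
        sf.SensorConfig(
            config.point_density,
            config.noise_sd,
            config.outlier_rate,
            config.canopy_cover,
            seed=seed + 10,
        )
        for _ in range(config.n_times)
    ]
    clouds = [
        sf.generate_point_cloud(terrain, design, growth, t, sensors[t])
        for t in range(config.n_times)
    ]
    dsms_rgb = [
        sf.generate_dsm(terrain, design, growth, t, sensors[t], config.raster_cell)
        for t in range(config.n_times)
    ]

    outputs = []
    write_ascii_grid(terrain, os.path.join(out, "terrain.asc"))
    outputs.append(os.path.join(out, "terrain.asc"))
    for t, (cloud, dsm) in enumerate(zip(clouds, dsms_rgb)):
        cp = os.path.join(out, f"cloud_t{t}.xyz.gz")
        write_xyz(cloud, cp)
        rp = os.path.join(out, f"dsm_rgb_t{t}.asc")
        write_ascii_grid(dsm, rp)
        outputs += [cp, rp]
    truth_df = pd.DataFrame(
        growth.heights,
        index=design.plot_ids(),
        columns=[f"t{t}" for t in range(config.n_times)],
    )
    truth_df.insert(0, "cluster", growth.cluster_id)
    outputs.append(_write_csv(truth_df, os.path.join(out, "truth_heights.csv"), index_label="plot_id"))
    vcf_path = os.path.join(out, "genotypes.vcf")
    write_vcf(G, vcf_path)
    outputs.append(vcf_path)
    gff_path = os.path.join(out, "annotation.gff3")
    sf.write_gff3(annotation, gff_path)
    outputs.append(gff_path)
    outputs.append(
        _write_csv(pheno, os.path.join(out, "phenotype_records.csv"), index=False)
    )
    masks = pe.build_plot_masks(design, config.shrink)
    mask_path = os.path.join(out, "plots.geojson")
    pe.write_masks_geojson(masks, mask_path)
    outputs.append(mask_path)

    state.update(
        design=design,
        terrain=terrain,
        growth=growth,
        G=G,
        gtruth=gtruth,
        genetic=genetic,
        clouds=clouds,
        dsms_rgb=dsms_rgb,
        masks=masks,
        annotation=annotation,
    )
    record(
        "simulate",
        outputs,
        n_plots=n_acc,
        n_snps=config.n_snps,
        n_times=config.n_times,
        causal_indices=[int(i) for i in causal],
    )


def _stage_surfaces(config: RunConfig, state: dict, record) -> None:
    out = config.outdir
    design: sf.FieldDesign = state["design"]
    bounds = design.extent()
    chms, outputs = [], []
    for t, cloud in enumerate(state["clouds"]):
        clean = sm.denoise(cloud, k_neighbors=8, n_sigma=3.0)
        classified = sm.classify_ground(clean, cell=0.25, slope_tol=0.10)
        dsm = sm.rasterize_dsm(classified, config.raster_cell, bounds=bounds)
        dtm = sm.interpolate_dtm(classified, config.raster_cell, bounds=bounds)
        chm = sm.compute_chm(dsm, dtm)
        chms.append(chm)
        for name, grid in [("dsm_lidar", dsm), ("dtm", dtm), ("chm", chm)]:
            p = os.path.join(out, f"{name}_t{t}.asc")
            write_ascii_grid(grid, p)
            outputs.append(p)
    state["chms"] = chms
    record("surfaces", outputs, cell=config.raster_cell, k_neighbors=8, n_sigma=3.0)


def _stage_extract(config: RunConfig, state: dict, record) -> None:
    out = config.outdir
    masks: list[pe.PlotMask] = state["masks"]
    lidar_records, rgb_records = [], []
    for t, (chm, dsm) in enumerate(zip(state["chms"], state["dsms_rgb"])):
        for mask in masks:
            lidar_records.append(
                (mask.plot_id, t, pe.extract_lidar_ph(chm, mask, config.lidar_aggregator))
            )
            rgb_records.append((mask.plot_id, t, pe.extract_rgb_ph(dsm, mask)))
    series_lidar = pe.assemble_series(lidar_records, "lidar")
    series_rgb = pe.assemble_series(rgb_records, "rgb")
    state["series_lidar"] = series_lidar
    state["series_rgb"] = series_rgb
    p1 = os.path.join(out, "series_lidar.csv")
    p2 = os.path.join(out, "series_rgb.csv")
    series_lidar.to_csv(p1)
    series_rgb.to_csv(p2)
    record("extract", [p1, p2], aggregator=config.lidar_aggregator, shrink=config.shrink)


def _stage_calibrate(config: RunConfig, seed: int, state: dict, record) -> None:
    """Simulated manual survey + model fitting, mirroring the field protocol:
    a small training set of plots measured at every flight, the whole field
    measured at the last two flights."""
    out = config.outdir
    design: sf.FieldDesign = state["design"]
    growth: sf.GrowthTruth = state["growth"]
    rng = np.random.default_rng(seed)
    plot_ids = np.array(design.plot_ids(), dtype=object)
    n_train = min(config.n_train_plots, design.n_plots)
    train_plots = sorted(rng.choice(plot_ids, n_train, replace=False))
    test_times = [config.n_times - 2, config.n_times - 1] if config.n_times >= 2 else [0]

    measured = pd.DataFrame(
        np.nan, index=plot_ids, columns=range(config.n_times)
    )
    truth = pd.DataFrame(
        growth.heights[: design.n_plots], index=plot_ids, columns=range(config.n_times)
    )
    noise = rng.normal(0.0, config.measurement_noise_sd, truth.shape)
    noisy = truth + noise
    measured.loc[train_plots, :] = noisy.loc[train_plots, :]
    for t in test_times:
        measured[t] = noisy[t]

    outputs = []
    reports = {}
    for name in ["lidar", "rgb"]:
        series: pe.PlotHeightSeries = state[f"series_{name}"]
        series.measured = measured.copy()
        report = cal.train_test_protocol(
            series, list(train_plots), test_times, tuple(config.families), seed=seed
        )
        series.predicted = report.predicted
        reports[name] = report
        outputs.append(
            _write_csv(
                report.training_metrics,
                os.path.join(out, f"calibration_metrics_{name}.csv"),
            )
        )
        sp = os.path.join(out, f"series_{name}_calibrated.csv")
        series.to_csv(sp)
        outputs.append(sp)
        best = report.models[report.best_family]
        if best.coefficients is not None:
            mp = os.path.join(out, f"model_{name}.json")
            best.to_json(mp)
            outputs.append(mp)
    state["predicted"] = reports["lidar"].predicted
    state["reports"] = reports
    state["train_plots"] = list(train_plots)
    record(
        "calibrate",
        outputs,
        train_plots=list(map(str, train_plots)),
        test_times=test_times,
        best_family={k: r.best_family for k, r in reports.items()},
        test_spearman={k: r.test_spearman for k, r in reports.items()},
    )


def _stage_cluster(config: RunConfig, seed: int, state: dict, record) -> None:
    out = config.outdir
    series = gc.impute_series(state["predicted"].to_numpy(dtype=float))
    k_range = list(range(1, config.k_max + 1))
    gap = gc.gap_statistic(series, k_range, B=config.gap_B, seed=seed)
    result = gc.kmeans(series, gap.chosen_k, seed=seed)
    dyn = gc.cluster_dynamics(result, series)
    assignments = pd.DataFrame(
        {"plot_id": state["predicted"].index, "cluster": result.assignments}
    )
    outputs = [
        _write_csv(assignments, os.path.join(out, "cluster_assignments.csv"), index=False),
        _write_csv(
            pd.DataFrame({"k": gap.k_values, "gap": gap.gap, "sk": gap.sk}),
            os.path.join(out, "gap_statistic.csv"),
            index=False,
        ),
        _write_csv(
            dyn.assign(mean_curve=dyn["mean_curve"].map(lambda c: ";".join(f"{v:.4f}" for v in c))),
            os.path.join(out, "cluster_summary.csv"),
            index=False,
        ),
    ]
    state["cluster_result"] = result
    state["gap"] = gap
    record("cluster", outputs, chosen_k=gap.chosen_k, B=config.gap_B)


def _stage_gwas(config: RunConfig, state: dict, record) -> None:
    out = config.outdir
    G = assoc.filter_snps(state["G"], maf_min=config.maf_min, missing_max=0.10)
    K = assoc.kinship(G)
    predicted: pd.DataFrame = state["predicted"]
    # BLUE per accession and time point (single-plot design: pass-through)
    scans = []
    outputs = []
    for t in predicted.columns:
        records = pd.DataFrame(
            {
                "accession": G.sample_ids,
                "replicate": 1,
                "value": predicted[t].to_numpy(dtype=float),
            }
        )
        blue = assoc.compute_blue(records).reindex(G.sample_ids)
        res = assoc.mixed_scan(blue.to_numpy(), G, K, time_point=int(t))
        scans.append(res)
        outputs.append(
            _write_csv(res.table, os.path.join(out, f"scan_t{t}.csv"), index=False)
        )
        manhattan, qq = assoc.export_scan(res)
        outputs.append(
            _write_csv(manhattan, os.path.join(out, f"manhattan_t{t}.csv"), index=False)
        )
        outputs.append(_write_csv(qq, os.path.join(out, f"qq_t{t}.csv"), index=False))
    peaks = assoc.significant_peaks(
        scans, config.threshold_neg_log10, config.merge_window
    )
    bed = os.path.join(out, "peaks.tsv")
    assoc.write_peaks_bed(peaks, bed)
    outputs.append(bed)
    genes = []
    for pk in peaks:
        hit = assoc.genes_in_interval(state["annotation"], pk)
        if not hit.empty:
            hit = hit.assign(peak=f"{pk.chrom}:{pk.start}-{pk.end}", time_point=pk.time_point)
            genes.append(hit)
    gene_df = (
        pd.concat(genes, ignore_index=True)
        if genes
        else pd.DataFrame(columns=["chrom", "start", "end", "gene_id", "name", "peak", "time_point"])
    )
    outputs.append(_write_csv(gene_df, os.path.join(out, "peak_genes.csv"), index=False))
    state["scans"] = scans
    state["peaks"] = peaks
    record(
        "gwas",
        outputs,
        n_snps_after_filter=G.n_snps,
        threshold=config.threshold_neg_log10,
        n_peaks=len(peaks),
        n_replicated=sum(p.replicated for p in peaks),
    )


def validate_against_truth(state_or_outdir, manifest: dict | None = None) -> dict:
    """Recovery report: height RMSE, cluster ARI, causal-SNP detection.

    Accepts the in-memory state dict returned alongside a pipeline run (see
    ``run_pipeline_with_state``).
    """
    from sklearn.metrics import adjusted_rand_score

    state = state_or_outdir
    if "growth" not in state:
        raise ValueError("truth missing from the pipeline state")
    report: dict = {}
    growth: sf.GrowthTruth = state["growth"]
    design: sf.FieldDesign = state["design"]
    truth_h = growth.heights[: design.n_plots]
    if "series_lidar" in state:
        ext = state["series_lidar"].extracted.to_numpy(dtype=float)
        report["lidar_extracted_rmse_m"] = float(
            np.sqrt(np.nanmean((ext - truth_h) ** 2))
        )
    if "predicted" in state:
        pred = state["predicted"].to_numpy(dtype=float)
        report["lidar_predicted_rmse_m"] = float(
            np.sqrt(np.nanmean((pred - truth_h) ** 2))
        )
    if "cluster_result" in state:
        report["cluster_ari"] = float(
            adjusted_rand_score(
                growth.cluster_id[: design.n_plots],
                state["cluster_result"].assignments,
            )
        )
        report["chosen_k"] = int(state["gap"].chosen_k)
    if "peaks" in state and "gtruth" in state:
        G: "sf.GenotypeMatrix" = state["G"]
        causal_pos = [
            (str(G.chrom[i]), int(G.pos[i])) for i in state["gtruth"].causal_indices
        ]
        detected = []
        for chrom, pos in causal_pos:
            hit = any(
                pk.chrom == chrom and pk.start <= pos <= pk.end and pk.replicated
                for pk in state["peaks"]
            )
            detected.append(hit)
        report["causal_detected"] = detected
        report["causal_detection_rate"] = float(np.mean(detected)) if detected else float("nan")
    return report


def run_pipeline_with_state(config: RunConfig) -> tuple[dict, dict]:
    """Like ``run_pipeline`` but also return the in-memory stage state."""
    state: dict = {}
    manifest = _run(config, state)
    return manifest, state


def _run(config: RunConfig, state: dict) -> dict:
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    os.makedirs(config.outdir, exist_ok=True)
    seeds = {
        name: int(ss.generate_state(1)[0] % (2**31 - 1))
        for name, ss in zip(STAGES, np.random.SeedSequence(config.seed).spawn(len(STAGES)))
    }
    manifest: dict = {"config": asdict(config), "stage_seeds": seeds, "stages": []}

    def record(stage: str, outputs: list[str], **params) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seeds[stage],
                "params": params,
                "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
            }
        )
        log.info("stage %s done (%d outputs)", stage, len(outputs))

    for stage in STAGES:
        if stage not in config.stages:
            continue
        if stage == "simulate":
            _stage_simulate(config, seeds[stage], state, record)
        elif stage == "surfaces":
            _require(state, "clouds", "surfaces", "simulate")
            _stage_surfaces(config, state, record)
        elif stage == "extract":
            _require(state, "chms", "extract", "surfaces")
            _stage_extract(config, state, record)
        elif stage == "calibrate":
            _require(state, "series_lidar", "calibrate", "extract")
            _stage_calibrate(config, seeds[stage], state, record)
        elif stage == "cluster":
            _require(state, "predicted", "cluster", "calibrate")
            _stage_cluster(config, seeds[stage], state, record)
        elif stage == "gwas":
            _require(state, "predicted", "gwas", "calibrate")
            _stage_gwas(config, state, record)

    manifest_path = os.path.join(config.outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
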