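"""End-to-end orchestration: simulate -> fit -> threshold -> project ->
attribute -> report.

Each stage is a plain function over library objects so it can be driven from
the CLI, the analysis scripts or tests; ``run_pipeline`` ties them together,
writes standard-format artifacts (NetCDF fields, CSV tables, JSON models)
and records a manifest with hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr
from . import glm, scenario, synthetic, threshold
from .predictors import FireObservations, PredictorField

logger = logging.getLogger(__name__)

_DEFAULT_PERCENTILES = (0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6, 0.7, 0.75, 0.8, 0.9)


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    seed: int = 0
    nlon: int = 40
    nlat: int = 20
    spatial_scale: float = 3.0
    zero_fraction: float = 0.26
    threshold_percentile: float = 0.5
    percentiles: tuple[float, ...] = _DEFAULT_PERCENTILES
    sensitivity_percentiles: tuple[float, ...] = (0.25, 0.5, 0.75)
    shifts: dict = field(default_factory=lambda: dict(synthetic.DEFAULT_SHIFTS))
    rcps: tuple[str, ...] = scenario.RCPS
    gcms: tuple[str, ...] = scenario.GCMS
    tropics_band: float = 23.5
    outdir: str = "runs/demo"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = [k for k in doc if k not in known]
        if unknown:
            raise ValueError(f"unknown config keys: {unknown} (legal: {sorted(known)})")
        cfg = cls(**doc)
        for name in ("percentiles", "sensitivity_percentiles", "rcps", "gcms"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml
        doc = asdict(self)
        for name in ("percentiles", "sensitivity_percentiles", "rcps", "gcms"):
            doc[name] = list(doc[name])
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ------------------------------------------------------------------ stages

def stage_simulate(cfg: RunConfig) -> synthetic.SyntheticDataset:
    return synthetic.generate_dataset(
        seed=cfg.seed, nlon=cfg.nlon, nlat=cfg.nlat,
        spatial_scale=cfg.spatial_scale, zero_fraction=cfg.zero_fraction)


def stage_fit(dataset: synthetic.SyntheticDataset) -> dict[str, glm.FittedGLM]:
    """Fit the three GLMs: burnt area on all cells, size/intensity on
    observed-fire cells."""
    X = dataset.predictors
    fire = dataset.fire
    burning = (fire.BA > 0).ravel()
    return {
        "BA": glm.fit_glm(X, fire.BA.ravel(), "BA"),
        "FS": glm.fit_glm(X, fire.FS.ravel(), "FS", mask=burning),
        "FI": glm.fit_glm(X, fire.FI.ravel(), "FI", mask=burning),
    }


def stage_threshold(models: dict, dataset: synthetic.SyntheticDataset,
                    cfg: RunConfig) -> tuple[threshold.ThresholdReport, pd.DataFrame]:
    fitted = glm.predict(models["BA"], dataset.predictors).ravel()
    observed = dataset.fire.BA.ravel()
    report = threshold.derive_threshold(fitted, observed, cfg.threshold_percentile)
    curve = threshold.tss_curve(fitted, observed, sorted(cfg.percentiles))
    return report, curve


def _synthetic_economy(dataset: synthetic.SyntheticDataset, seed: int):
    """GDP and OECD layers for the road-density model demo."""
    rng = np.random.default_rng(seed)
    grid = dataset.grid
    popd = dataset.predictors["popd"]
    area = grid.cell_area
    gpc = np.exp(2.5 + 0.8 * synthetic._smooth_standard_normal(rng, grid.shape, 4.0))
    gdp_modern = gpc * popd * area
    oecd = (synthetic._smooth_standard_normal(rng, grid.shape, 5.0) > 0)
    return gdp_modern, oecd


def stage_project(dataset: synthetic.SyntheticDataset, cfg: RunConfig
                  ) -> tuple[scenario.ScenarioBundle,
                             list[tuple[scenario.ExperimentSpec, PredictorField]]]:
    """Build the scenario bundle (with road density projected by the linear
    model rather than shifted directly) and the 40-experiment matrix."""
    bundle = synthetic.generate_scenario(
        dataset.predictors, cfg.shifts, seed=cfg.seed + 2,
        rcps=cfg.rcps, gcms=cfg.gcms)

    gdp_modern, oecd = _synthetic_economy(dataset, cfg.seed + 3)
    area = dataset.grid.cell_area
    road_model = scenario.fit_road_model(
        dataset.predictors["popd"], gdp_modern, oecd, area,
        dataset.predictors["roads"])
    bundle.human_modern_sim["roads"] = scenario.project_road_density(
        dataset.predictors["popd"], gdp_modern, oecd, area,
        road_model.coefficients)
    for rcp in cfg.rcps:
        popd_future = bundle.human_future_sim[rcp]["popd"]
        gdp_future = gdp_modern * (popd_future / np.maximum(
            dataset.predictors["popd"], 1e-9)) * 1.5  # richer future world
        bundle.human_future_sim[rcp]["roads"] = scenario.project_road_density(
            popd_future, gdp_future, oecd, area, road_model.coefficients)

    experiments = scenario.build_experiment_matrix(bundle)
    return bundle, experiments


def predict_fire_properties(models: dict, X: PredictorField,
                            ignition_threshold: float) -> dict[str, np.ndarray]:
    """BA/FS/FI predictions in physical units with the ignition gate applied."""
    ba = glm.predict(models["BA"], X)
    fs = glm.predict(models["FS"], X, denormalise=True)
    fi = glm.predict(models["FI"], X, denormalise=True)
    fs, fi, unburnt = threshold.apply_threshold(ba, fs, fi, ignition_threshold)
    return {"BA": ba, "FS": fs, "FI": fi, "unburnt_pct": unburnt}


def _ensemble_mean(fields: list[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    return {k: np.mean([f[k] for f in fields], axis=0) for k in ("BA", "FS", "FI")}


def stage_attribute(dataset: synthetic.SyntheticDataset, models: dict,
                    report: threshold.ThresholdReport,
                    experiments, cfg: RunConfig) -> dict:
    """Biome aggregation, driver attribution, ignition expansion, change
    maps and the threshold-sensitivity table, per pathway."""
    grid = dataset.grid
    biome_map = synthetic.synthetic_biomes(dataset.predictors)
    modern = predict_fire_properties(models, dataset.predictors, report.threshold)
    lat = grid.lat_field()

    by_key = {spec.key: fld for spec, fld in experiments}
    out: dict = {"biome_tables": {}, "expansion": {}, "driver_freq": {},
                 "combined_change": {}, "modern": modern, "biome_map": biome_map}

    sens_rows = []
    for rcp in cfg.rcps:
        member_preds = []
        member_fields = []
        for gcm in cfg.gcms:
            fld = by_key[("realistic", rcp, gcm)]
            member_fields.append(fld)
            member_preds.append(
                predict_fire_properties(models, fld, report.threshold))
        future = _ensemble_mean(member_preds)

        out["biome_tables"][rcp] = attr.biome_aggregate(
            modern["BA"], biome_map, grid,
            biome_names=synthetic.BIOME_NAMES, ba_future=future["BA"])
        out["expansion"][rcp] = attr.ignition_expansion(
            modern["BA"], future["BA"], report.threshold, lat,
            tropics_band=cfg.tropics_band)
        out["combined_change"][rcp] = attr.combined_change_map(modern, future)

        mean_future_field = member_fields[0].copy()
        for name in mean_future_field.data:
            mean_future_field[name] = np.mean(
                [f[name] for f in member_fields], axis=0)
        freq = {}
        for resp in ("BA", "FS", "FI"):
            result = attr.predictor_contributions(
                models[resp], dataset.predictors, mean_future_field)
            _, _, freq[resp] = attr.dominant_driver_map(result, shape=grid.shape)
        out["driver_freq"][rcp] = freq

        # threshold-sensitivity block: FS/FI/unburnt under alternative gates
        for pct in cfg.sensitivity_percentiles:
            rep = threshold.derive_threshold(
                glm.predict(models["BA"], dataset.predictors).ravel(),
                dataset.fire.BA.ravel(), pct)
            for label, preds_x in (("modern", dataset.predictors),
                                   (rcp, mean_future_field)):
                p = predict_fire_properties(models, preds_x, rep.threshold)
                burning = p["FS"] > 0
                sens_rows.append({
                    "threshold_percentile": pct, "experiment": label,
                    "fire_size_km2": float(np.mean(p["FS"][burning]))
                    if burning.any() else 0.0,
                    "fire_intensity_w_km": float(np.mean(p["FI"][burning]))
                    if burning.any() else 0.0,
                    "unburnt_pct": p["unburnt_pct"]})
    out["sensitivity_table"] = (
        pd.DataFrame(sens_rows).drop_duplicates(
            subset=["threshold_percentile", "experiment"])
        if sens_rows else pd.DataFrame(columns=[
            "threshold_percentile", "experiment", "fire_size_km2",
            "fire_intensity_w_km", "unburnt_pct"]))
    return out


# --------------------------------------------------------------- full run

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, write per-stage artifacts under ``cfg.outdir`` and
    return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(cfg), "stages": {}, "outputs": {}}
    t_total = time.perf_counter()

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        for p in paths:
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        dataset = stage_simulate(cfg)
        dataset.predictors.to_netcdf(outdir / "predictors.nc")
        dataset.fire.to_netcdf(outdir / "fire.nc")
        record(stage, t0, [outdir / "predictors.nc", outdir / "fire.nc"])

        stage = "fit"
        t0 = time.perf_counter()
        models = stage_fit(dataset)
        paths = []
        for name, model in models.items():
            p = outdir / f"model_{name}.json"
            model.save(p)
            paths.append(p)
        record(stage, t0, paths)

        stage = "threshold"
        t0 = time.perf_counter()
        report, curve = stage_threshold(models, dataset, cfg)
        curve.to_csv(outdir / "tss_table.csv", index=False)
        record(stage, t0, [outdir / "tss_table.csv"])
        manifest["threshold"] = report.as_row()

        stage = "project"
        t0 = time.perf_counter()
        bundle, experiments = stage_project(dataset, cfg)
        expdir = outdir / "experiments"
        expdir.mkdir(exist_ok=True)
        paths = []
        for spec, fld in experiments:
            p = expdir / f"{spec.label}_{spec.scenario}_{spec.gcm}.nc"
            fld.to_netcdf(p)
            paths.append(p)
        record(stage, t0, paths)
        manifest["n_experiments"] = len(experiments)

        stage = "attribute"
        t0 = time.perf_counter()
        results = stage_attribute(dataset, models, report, experiments, cfg)
        paths = []
        for rcp, table in results["biome_tables"].items():
            p = outdir / f"biome_table_{rcp}.csv"
            table.to_csv(p, index=False)
            paths.append(p)
        for rcp, freq in results["driver_freq"].items():
            for resp, table in freq.items():
                p = outdir / f"drivers_{resp}_{rcp}.csv"
                table.to_csv(p, index=False)
                paths.append(p)
        p = outdir / "sensitivity_table.csv"
        results["sensitivity_table"].to_csv(p, index=False)
        paths.append(p)
        p = outdir / "ignition_expansion.json"
        with open(p, "w") as fh:
            json.dump(results["expansion"], fh, indent=2)
        paths.append(p)
        record(stage, t0, paths)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    manifest["total_seconds"] = round(time.perf_counter() - t_total, 3)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def report(outdir) -> dict[str, pd.DataFrame]:
    """Collect the summary tables of a completed run (threshold/TSS table,
    per-pathway biome tables, threshold-sensitivity table)."""
    outdir = Path(outdir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}; run the pipeline first")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    tables: dict[str, pd.DataFrame] = {}
    missing = []
    wanted = ["tss_table.csv", "sensitivity_table.csv"] + [
        f"biome_table_{rcp}.csv" for rcp in manifest["config"]["rcps"]]
    for name in wanted:
        p = outdir / name
        if not p.exists():
            missing.append(name)
        else:
            tables[name.removesuffix(".csv")] = pd.read_csv(p)
    if missing:
        raise FileNotFoundError(f"missing stage outputs: {missing}")
    return tables
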