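"""Future-forcing construction by the anomaly (delta) method.

Future predictor fields are built as ``baseline + (future_sim - picontrol_sim)``
per climate-model member, so that systematic model biases cancel and only the
simulated change is imposed on the observed baseline climatology.  The
factorial design crosses five experiments (realistic plus four sensitivity
experiments that hold factor groups at modern levels) with two concentration
pathways and four climate-model members: 40 experiments in total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import GridDefinition
from .predictors import (
    CLIMATE_PREDICTORS,
    CONSTANT_PREDICTORS,
    HUMAN_PREDICTORS,
    PREDICTORS,
    VEGETATION_PREDICTORS,
    PredictorField,
)

logger = logging.getLogger(__name__)

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

#: monthly climate variables carried in scenario climatologies
MONTHLY_VARS: tuple[str, ...] = ("DD", "VPD", "DTR", "wind", "tas")

RCPS: tuple[str, ...] = ("rcp26", "rcp60")
GCMS: tuple[str, ...] = ("GFDL-ESM2M", "HadGEM2-ES", "IPSL-CM5A-LR", "MIROC5")

#: experiment label -> factor groups allowed to change (all others held at
#: modern levels)
EXPERIMENT_LABELS: dict[str, frozenset[str]] = {
    "realistic": frozenset({"climate", "co2", "human"}),
    "climate_only": frozenset({"climate"}),
    "co2_only": frozenset({"co2"}),
    "climate_co2": frozenset({"climate", "co2"}),
    "human_only": frozenset({"human"}),
}

#: physical bounds applied after adding anomalies; "month" means the
#: per-month day count; None on a side means unbounded
CLIP_RULES: dict[str, tuple] = {
    "DD": (0.0, "month"),
    "VPD": (0.0, None),
    "DTR": (0.0, None),
    "wind": (0.0, None),
    "tas": (None, None),
    "GPP": (0.0, None),
    "GPP_s": (0.0, None),
    "grass": (0.0, 1.0),
    "shrub": (0.0, 1.0),
    "tree": (0.0, 1.0),
    "popd": (0.0, None),
    "crop": (0.0, 1.0),
    "roads": (0.0, None),
}


@dataclass(frozen=True)
class ExperimentSpec:
    """One cell of the factorial design."""

    label: str
    scenario: str  # rcp label
    gcm: str
    vary: frozenset[str]

    def __post_init__(self) -> None:
        if self.label not in EXPERIMENT_LABELS:
            raise ValueError(f"unknown experiment label {self.label!r}")
        if self.vary != EXPERIMENT_LABELS[self.label]:
            raise ValueError(
                f"label {self.label!r} requires vary={set(EXPERIMENT_LABELS[self.label])}"
            )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.label, self.scenario, self.gcm)


@dataclass
class ScenarioBundle:
    """Baseline climatology plus per-member piControl/future climatologies,
    vegetation deltas split by driver, human-activity layers and CO2 levels."""

    grid: GridDefinition
    baseline: PredictorField
    baseline_monthly: dict[str, np.ndarray]              # var -> (12, ny, nx)
    picontrol: dict[str, dict[str, np.ndarray]]          # gcm -> var -> (12, ny, nx)
    future: dict[str, dict[str, dict[str, np.ndarray]]]  # rcp -> gcm -> var
    veg_climate_delta: dict[str, dict[str, dict[str, np.ndarray]]]  # rcp -> gcm -> layer
    veg_co2_delta: dict[str, dict[str, np.ndarray]]      # rcp -> layer
    human_modern_sim: dict[str, np.ndarray]              # layer -> field
    human_future_sim: dict[str, dict[str, np.ndarray]]   # rcp -> layer -> field
    co2_modern: float = 401.0
    co2_future: dict[str, float] = field(
        default_factory=lambda: {"rcp26": 421.0, "rcp60": 670.0})
    rcps: tuple[str, ...] = RCPS
    gcms: tuple[str, ...] = GCMS

    def validate(self) -> None:
        missing = [g for g in self.gcms if g not in self.picontrol]
        for rcp in self.rcps:
            if rcp not in self.future:
                missing.append(rcp)
            else:
                missing.extend(
                    f"{rcp}/{g}" for g in self.gcms if g not in self.future[rcp])
        if missing:
            raise ValueError(f"incomplete scenario bundle; missing members: {missing}")


# --------------------------------------------------------------------- ops

def compute_anomaly(picontrol: dict[str, np.ndarray],
                    future: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-month, per-variable delta: ``future - picontrol``."""
    deltas = {}
    for var, ctrl in picontrol.items():
        if var not in future:
            raise ValueError(f"variable {var!r} missing from future climatology")
        fut = np.asarray(future[var])
        ctrl = np.asarray(ctrl)
        if fut.shape != ctrl.shape:
            raise ValueError(
                f"month/shape mismatch for {var!r}: {fut.shape} vs {ctrl.shape}")
        deltas[var] = fut - ctrl
    return deltas


def _clip(var: str, arr: np.ndarray, monthly: bool) -> np.ndarray:
    if var not in CLIP_RULES:
        raise ValueError(f"no clip rule registered for bounded variable {var!r}")
    lo, hi = CLIP_RULES[var]
    out = arr
    if lo is not None:
        out = np.maximum(out, lo)
    if hi == "month":
        if monthly:
            out = np.minimum(out, DAYS_IN_MONTH[:, None, None])
        else:
            out = np.minimum(out, DAYS_IN_MONTH.mean())
    elif hi is not None:
        out = np.minimum(out, hi)
    return out


def apply_anomaly(baseline: dict[str, np.ndarray],
                  delta: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Add monthly anomalies to the baseline climatology and clip to
    physical ranges (dry days to the day count of each month, non-negative
    VPD/wind, fractions to [0, 1])."""
    out = {}
    for var, base in baseline.items():
        d = delta.get(var)
        if d is None:
            out[var] = base.copy()
            continue
        if np.asarray(d).shape != base.shape:
            raise ValueError(f"shape mismatch for {var!r}")
        out[var] = _clip(var, base + d, monthly=(base.ndim == 3))
    return out


def summarise_climatology(monthly: dict[str, np.ndarray],
                          tas_monthly: np.ndarray | None = None
                          ) -> dict[str, np.ndarray]:
    """Collapse 12-month climatologies into the single-layer climate
    predictors: mean dry days plus their seasonality (range/mean), the value
    of the month with the largest DTR and highest VPD, wind speed of the
    hottest month, and mean lightning when present."""
    for var, arr in monthly.items():
        if np.asarray(arr).shape[0] != 12:
            raise ValueError(f"{var!r} climatology has fewer than 12 months")
    if tas_monthly is None:
        tas_monthly = monthly["tas"]
    if tas_monthly.shape[0] != 12:
        raise ValueError("tas climatology has fewer than 12 months")

    out: dict[str, np.ndarray] = {}
    dd = monthly["DD"]
    mean_dd = dd.mean(axis=0)
    out["DD"] = mean_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        seas = (dd.max(axis=0) - dd.min(axis=0)) / mean_dd
    out["DD_s"] = np.where(mean_dd > 0, seas, 0.0)
    out["VPD"] = monthly["VPD"].max(axis=0)
    out["DTR"] = monthly["DTR"].max(axis=0)
    hottest = np.argmax(tas_monthly, axis=0)
    out["wind"] = np.take_along_axis(monthly["wind"], hottest[None], axis=0)[0]
    if "light" in monthly:
        out["light"] = monthly["light"].mean(axis=0)
    return out


def apply_human_anomaly(baseline_human: dict[str, np.ndarray],
                        modern_sim: dict[str, np.ndarray],
                        future_sim: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Human-activity delta method: ``baseline + (future_sim - modern_sim)``
    with physical clipping (popd, roads >= 0; crop in [0, 1])."""
    out = {}
    for name, base in baseline_human.items():
        if modern_sim[name].shape != base.shape or future_sim[name].shape != base.shape:
            raise ValueError(f"shape mismatch for human layer {name!r}")
        out[name] = _clip(name, base + (future_sim[name] - modern_sim[name]),
                          monthly=False)
    return out


# ------------------------------------------------------------ road density

@dataclass
class RoadModel:
    """OLS model of road density on population density, GDP per capita,
    OECD membership and cell area."""

    coefficients: np.ndarray  # intercept, popd, gdp_pc, oecd, area
    adj_r2: float
    n_flagged_zero_pop: int = 0


def gdp_per_capita(gdp_total: np.ndarray, popd: np.ndarray,
                   area: np.ndarray) -> tuple[np.ndarray, int]:
    """Total GDP divided by population count (popd * area).  Cells with no
    population get the grid median GDP per capita; the count of such cells
    is returned for logging."""
    pop_count = popd * area
    ok = pop_count > 0
    gpc = np.full(gdp_total.shape, np.nan)
    gpc[ok] = gdp_total[ok] / pop_count[ok]
    n_flagged = int((~ok).sum())
    if n_flagged:
        gpc[~ok] = np.nanmedian(gpc)
        logger.warning("gdp_per_capita: %d zero-population cells set to grid median",
                       n_flagged)
    return gpc, n_flagged


def _road_design(popd, gdp_total, oecd, area):
    gpc, n_flagged = gdp_per_capita(np.asarray(gdp_total, float),
                                    np.asarray(popd, float),
                                    np.asarray(area, float))
    X = np.column_stack([
        np.ones(gpc.size),
        np.asarray(popd, float).ravel(),
        gpc.ravel(),
        np.asarray(oecd, float).ravel(),
        np.asarray(area, float).ravel(),
    ])
    return X, n_flagged


def fit_road_model(popd, gdp_total, oecd, area, roads) -> RoadModel:
    X, n_flagged = _road_design(popd, gdp_total, oecd, area)
    y = np.asarray(roads, float).ravel()
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("road-density design is rank deficient")
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n, p = X.shape
    adj_r2 = 1.0 - (ss_res / (n - p)) / (ss_tot / (n - 1)) if ss_tot > 0 else np.nan
    return RoadModel(coefficients=beta, adj_r2=adj_r2, n_flagged_zero_pop=n_flagged)


def project_road_density(popd, gdp_total, oecd, area,
                         coefficients: np.ndarray) -> np.ndarray:
    """Linear road-density prediction, clamped at zero."""
    popd = np.asarray(popd, float)
    X, _ = _road_design(popd, gdp_total, oecd, area)
    pred = (X @ np.asarray(coefficients, float)).reshape(popd.shape)
    return np.maximum(pred, 0.0)


# ------------------------------------------------------- experiment matrix

def _cap_cover(field_: PredictorField, modified: str) -> None:
    """Keep tree + grass + shrub <= 1 by capping only the modified layer."""
    others = [c for c in ("tree", "grass", "shrub") if c != modified]
    room = 1.0 - sum(field_[c] for c in others)
    field_[modified] = np.clip(field_[modified], 0.0, np.maximum(room, 0.0))


def build_experiment_matrix(bundle: ScenarioBundle
                            ) -> list[tuple[ExperimentSpec, PredictorField]]:
    """Emit the full factorial: 5 experiment labels x len(rcps) x len(gcms)
    predictor fields.  Layers of held-constant factor groups are the
    baseline arrays unchanged (bit-identical)."""
    bundle.validate()
    experiments: list[tuple[ExperimentSpec, PredictorField]] = []
    base = bundle.baseline
    human_baseline = {name: base[name] for name in HUMAN_PREDICTORS}

    for label, vary in EXPERIMENT_LABELS.items():
        for rcp in bundle.rcps:
            for gcm in bundle.gcms:
                fld = base.copy()
                if "climate" in vary:
                    delta = compute_anomaly(bundle.picontrol[gcm],
                                            bundle.future[rcp][gcm])
                    monthly = apply_anomaly(bundle.baseline_monthly, delta)
                    clim = summarise_climatology(monthly)
                    for name in CLIMATE_PREDICTORS:
                        fld[name] = clim[name]
                    for name, d in bundle.veg_climate_delta[rcp][gcm].items():
                        fld[name] = _clip(name, fld[name] + d, monthly=False)
                        if name in ("tree", "grass", "shrub"):
                            _cap_cover(fld, name)
                if "co2" in vary:
                    for name, d in bundle.veg_co2_delta[rcp].items():
                        fld[name] = _clip(name, fld[name] + d, monthly=False)
                        if name in ("tree", "grass", "shrub"):
                            _cap_cover(fld, name)
                if "human" in vary:
                    future_h = apply_human_anomaly(
                        human_baseline, bundle.human_modern_sim,
                        bundle.human_future_sim[rcp])
                    for name in HUMAN_PREDICTORS:
                        fld[name] = future_h[name]
                spec = ExperimentSpec(label=label, scenario=rcp, gcm=gcm, vary=vary)
                experiments.append((spec, fld))
    return experiments
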