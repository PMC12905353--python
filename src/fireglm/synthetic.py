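"""Synthetic gridded data with the statistical structure the analysis assumes.

Predictor layers are smooth transforms of spatially autocorrelated Gaussian
noise, so biome-like structure exists without any download.  Fire properties
are generated from known ground-truth coefficients: burnt area around the
inverse-logit of a linear predictor with quasi-binomial noise (a
mean-precision Beta, Var = phi * mu * (1 - mu)); fire size and intensity as
gamma-mixed Poisson counts (Var = phi * mu) rescaled to physical units.
Zero inflation is imposed by thresholding the latent burn probability: the
least fire-prone cells are recorded as unburnt, which is the structure the
ignition-threshold procedure exploits downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .grid import GridDefinition, demo_grid
from .predictors import PREDICTORS, FireObservations, PredictorField, check_layout
from .scenario import (
    GCMS,
    MONTHLY_VARS,
    RCPS,
    ScenarioBundle,
)

N_COEF = len(PREDICTORS) + 1  # intercept first


@dataclass
class GroundTruth:
    """Known generative parameters for the three fire-property models.

    Coefficient vectors are on the standardised-predictor scale, intercept
    first, then the 16 predictors in canonical order.
    """

    beta_BA: np.ndarray
    beta_FS: np.ndarray
    beta_FI: np.ndarray
    dispersion_FS: float = 3.0
    dispersion_FI: float = 3.0
    dispersion_BA: float = 0.01
    zero_fraction: float = 0.26
    fs_scale_km2: float = 0.1   # km^2 per latent count
    fi_scale_w_km: float = 0.5  # W km-1 per latent count

    def __post_init__(self) -> None:
        for name in ("beta_BA", "beta_FS", "beta_FI"):
            b = np.asarray(getattr(self, name), dtype=float)
            if b.shape != (N_COEF,):
                raise ValueError(f"{name} must have shape ({N_COEF},): intercept + "
                                 f"{len(PREDICTORS)} slopes in canonical order")
            setattr(self, name, b)
        if self.dispersion_FS <= 1 or self.dispersion_FI <= 1:
            raise ValueError("count dispersion factors must exceed 1")
        if not (0 <= self.zero_fraction < 1):
            raise ValueError("zero_fraction must be in [0, 1)")
        if not (0 < self.dispersion_BA < 1):
            raise ValueError("dispersion_BA must be in (0, 1) for Beta noise")


def default_ground_truth(zero_fraction: float = 0.26) -> GroundTruth:
    """Study-condition defaults.

    The burnt-area coefficients put the low tail of the burn-probability
    distribution near 1e-3 with roughly a quarter of cells recorded as
    unburnt; fire-size and fire-intensity intercepts give medians of about
    2 km^2 and 25 W km-1 in physical units.
    """
    beta_ba = np.array([-4.1,
                        0.9, 0.5, 0.8, 0.3, 0.2,       # DD DD_s VPD DTR wind
                        1.1, 0.4, 0.8, 0.2, -0.6,      # GPP GPP_s grass shrub tree
                        -0.4, -0.9, -0.7,              # popd crop roads
                        -0.2, -0.1, 0.3])              # VRM TPI light
    beta_fs = np.array([3.0,
                        0.35, 0.15, 0.40, 0.05, 0.30,
                        -0.20, 0.10, 0.25, 0.05, -0.30,
                        -0.30, -0.40, -0.35,
                        -0.10, 0.0, 0.05])
    beta_fi = np.array([3.9,
                        0.20, 0.05, 0.25, 0.10, 0.15,
                        0.45, -0.05, -0.10, 0.05, 0.35,
                        -0.20, -0.30, 0.15,
                        -0.05, 0.0, 0.10])
    return GroundTruth(beta_BA=beta_ba, beta_FS=beta_fs, beta_FI=beta_fi,
                       zero_fraction=zero_fraction)


@dataclass
class SyntheticDataset:
    grid: GridDefinition
    predictors: PredictorField
    fire: FireObservations
    truth: GroundTruth
    seed: int


# ----------------------------------------------------------------- fields

def _smooth_standard_normal(rng: np.random.Generator, shape: tuple[int, int],
                            spatial_scale: float) -> np.ndarray:
    """Unit-variance Gaussian field; autocorrelation length ~ spatial_scale
    cells.  spatial_scale == 1 means white noise (per-cell independence)."""
    g = rng.standard_normal(shape)
    if spatial_scale > 1:
        g = gaussian_filter(g, sigma=spatial_scale / 2.0, mode="reflect")
        g = (g - g.mean()) / g.std()
    return g


def generate_predictors(grid: GridDefinition, seed: int,
                        spatial_scale: float = 3.0) -> PredictorField:
    """All 16 predictor layers with plausible physical ranges.

    Each layer is a fixed monotone transform of an independent smoothed
    Gaussian latent; fractional covers come from a four-component softmax
    (tree, grass, shrub, bare) so their sum never exceeds one.
    """
    if spatial_scale < 1:
        raise ValueError("spatial_scale must be >= 1 cell")
    rng = np.random.default_rng(seed)
    z = {name: _smooth_standard_normal(rng, grid.shape, spatial_scale)
         for name in ("DD", "DD_s", "VPD", "DTR", "wind", "GPP", "GPP_s",
                      "popd", "crop", "roads", "VRM", "TPI", "light",
                      "u_tree", "u_grass", "u_shrub", "u_bare")}

    data: dict[str, np.ndarray] = {}
    data["DD"] = 20.0 * expit(0.9 * z["DD"] - 0.2)          # days, <= 20
    data["DD_s"] = expit(z["DD_s"])                          # range/mean, < 1
    data["VPD"] = np.exp(0.6 * z["VPD"])                     # kPa, lognormal
    data["DTR"] = np.clip(10.0 + 2.5 * z["DTR"], 1.0, 25.0)  # degC
    data["wind"] = np.exp(1.2 + 0.4 * z["wind"])             # m s-1
    data["GPP"] = np.exp(6.0 + 1.0 * z["GPP"])               # training units
    data["GPP_s"] = 1.5 * expit(z["GPP_s"])
    data["popd"] = np.exp(2.0 + 1.5 * z["popd"])             # persons km-2
    data["crop"] = expit(1.2 * z["crop"] - 1.0)
    data["roads"] = np.exp(-1.0 + 0.8 * z["roads"])          # km km-2
    data["VRM"] = 0.3 * expit(z["VRM"])
    data["TPI"] = 20.0 * z["TPI"]
    data["light"] = np.exp(-1.0 + z["light"])                # strikes month-1

    u = {c: np.exp(1.5 * z[f"u_{c}"]) for c in ("tree", "grass", "shrub", "bare")}
    total = sum(u.values())
    for c in ("tree", "grass", "shrub"):
        data[c] = u[c] / total

    fld = PredictorField(grid, data)
    fld.validate_ranges()
    return fld


# ------------------------------------------------------------------- fire

def standardise(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = [PREDICTORS[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant predictor layers cannot be standardised: {bad}")
    return (X - mu) / sd, mu, sd


def linear_predictor(predictors: PredictorField, beta: np.ndarray) -> np.ndarray:
    """eta = beta_0 + Z beta on z-scored predictors, reshaped to the grid."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (N_COEF,):
        missing = [] if beta.ndim == 1 else list(PREDICTORS)
        raise ValueError(
            f"coefficient vector has shape {beta.shape}, expected ({N_COEF},) "
            f"covering intercept + predictors {list(PREDICTORS)}; "
            f"unresolved names: {missing}")
    Z, _, _ = standardise(predictors.matrix())
    eta = beta[0] + Z @ beta[1:]
    return eta.reshape(predictors.grid.shape)


def _gamma_poisson(rng: np.random.Generator, mu: np.ndarray,
                   dispersion: float) -> np.ndarray:
    """Overdispersed counts with Var = dispersion * mu (gamma-mixed Poisson)."""
    shape = mu / (dispersion - 1.0)
    lam = rng.gamma(shape, scale=dispersion - 1.0)
    return rng.poisson(lam).astype(float)


def generate_fire(predictors: PredictorField, truth: GroundTruth,
                  seed: int) -> FireObservations:
    """Observed fire properties under the known ground truth.

    Burnt area is a Beta draw with mean inverse-logit(eta_BA) and variance
    dispersion_BA * mu * (1 - mu); the lowest ``zero_fraction`` of latent burn
    probabilities are recorded as unburnt (BA = FS = FI = 0).  Fire size and
    intensity are gamma-mixed Poisson counts around exp(eta) scaled to km^2
    and W km-1.
    """
    check_layout(predictors.data.keys())
    rng = np.random.default_rng(seed)
    grid = predictors.grid

    p = expit(linear_predictor(predictors, truth.beta_BA))
    nu = 1.0 / truth.dispersion_BA - 1.0
    # keep Beta parameters strictly positive on cells where expit saturates
    p_open = np.clip(p, 1e-10, 1.0 - 1e-10)
    ba = rng.beta(p_open * nu, (1.0 - p_open) * nu)

    mu_fs = np.exp(linear_predictor(predictors, truth.beta_FS))
    mu_fi = np.exp(linear_predictor(predictors, truth.beta_FI))
    fs = truth.fs_scale_km2 * _gamma_poisson(rng, mu_fs, truth.dispersion_FS)
    fi = truth.fi_scale_w_km * _gamma_poisson(rng, mu_fi, truth.dispersion_FI)

    if truth.zero_fraction > 0:
        cut = np.quantile(p, truth.zero_fraction)
        ba = np.where(p <= cut, 0.0, ba)
    # conservation: no fire size/intensity on unburnt cells (including Beta
    # draws that underflow to exactly zero)
    zero = ba == 0
    fs = np.where(zero, 0.0, fs)
    fi = np.where(zero, 0.0, fi)

    obs = FireObservations(grid=grid, BA=ba, FS=fs, FI=fi)
    obs.validate()
    return obs


# ------------------------------------------------------------- biome map

BIOME_NAMES: dict[int, str] = {
    0: "sparse/tundra",
    1: "shrubland",
    2: "grassland/savanna",
    3: "seasonal forest",
    4: "humid forest",
}


def synthetic_biomes(predictors: PredictorField) -> np.ndarray:
    """Deterministic biome-like classification from tree cover, grass cover
    and productivity quantiles; integer codes per BIOME_NAMES."""
    tree = predictors["tree"]
    grass = predictors["grass"]
    shrub = predictors["shrub"]
    gpp = predictors["GPP"]
    gpp_hi = gpp >= np.quantile(gpp, 0.6)
    biome = np.zeros(tree.shape, dtype=int)
    biome[shrub >= 0.25] = 1
    biome[grass >= 0.30] = 2
    biome[(tree >= 0.35) & ~gpp_hi] = 3
    biome[(tree >= 0.35) & gpp_hi] = 4
    return biome


# ------------------------------------------------------------- scenarios

def monthly_climatology(predictors: PredictorField) -> dict[str, np.ndarray]:
    """Seasonal cycles consistent with the single-layer predictors: the
    annual summary of these 12-month fields reproduces the DD, DD_s, VPD,
    DTR and wind layers exactly (peak month July)."""
    phase = np.cos(2 * np.pi * (np.arange(12) - 6) / 12.0)[:, None, None]
    dd, dds = predictors["DD"], predictors["DD_s"]
    monthly = {
        "DD": dd * (1.0 + (dds / 2.0) * phase),
        "VPD": predictors["VPD"] * (0.6 + 0.4 * phase),
        "DTR": predictors["DTR"] * (0.75 + 0.25 * phase),
        "wind": predictors["wind"] * (1.0 - 0.15 * (1.0 - phase)),
        "tas": 10.0 + (5.0 + 0.5 * predictors["DTR"]) * phase,
    }
    return monthly


_DEFAULT_RCP_SCALE = {"rcp26": 0.4, "rcp60": 1.0}

#: additive end-of-century deltas under the low-mitigation pathway; the
#: high-mitigation pathway applies 40% of the climate/CO2 signal.  Human
#: deltas follow one middle-of-the-road socioeconomic pathway in both.
DEFAULT_SHIFTS: dict[str, float] = {
    "DD": 3.0,      # days
    "VPD": 0.6,     # kPa
    "DTR": 0.8,     # degC
    "wind": 0.1,    # m s-1
    "tas": 3.5,     # degC
    "popd": 4.0,    # persons km-2
    "crop": 0.05,   # fraction
    "roads": 0.08,  # km km-2
}

#: CO2-driven vegetation deltas, as fractions of the baseline layer (GPP)
#: or absolute cover fractions (tree), at low mitigation
DEFAULT_VEG_CO2 = {"GPP": 0.20, "tree": 0.04}
#: climate-driven vegetation deltas at low mitigation
DEFAULT_VEG_CLIMATE = {"GPP": -0.05, "grass": 0.02}

_CLIMATE_SHIFT_VARS = set(MONTHLY_VARS)
_HUMAN_SHIFT_VARS = {"popd", "crop", "roads"}
_VEG_VARS = {"GPP", "GPP_s", "grass", "shrub", "tree"}


def generate_scenario(predictors: PredictorField,
                      shifts: dict[str, float] | None = None,
                      seed: int = 0,
                      *,
                      veg_co2_shifts: dict[str, float] | None = None,
                      veg_climate_shifts: dict[str, float] | None = None,
                      rcp_scale: dict[str, float] | None = None,
                      rcps: tuple[str, ...] = RCPS,
                      gcms: tuple[str, ...] = GCMS,
                      noise_frac: float = 0.02) -> ScenarioBundle:
    """Paired piControl/future climatologies with known shifts.

    ``shifts`` maps predictor (or ``tas``) names to additive deltas imposed
    on the future climatology; unspecified variables shift by zero.  Climate
    and CO2-driven vegetation shifts scale with ``rcp_scale`` per pathway;
    human shifts do not (one socioeconomic pathway).  Climate members get
    smooth member-specific biases that cancel in the anomaly.  Human layers
    are only perturbed when their shift is nonzero, so sensitivity
    experiments that hold them constant see bit-identical baselines.
    """
    shifts = dict(shifts or {})
    veg_co2_shifts = dict(DEFAULT_VEG_CO2 if veg_co2_shifts is None else veg_co2_shifts)
    veg_climate_shifts = dict(
        DEFAULT_VEG_CLIMATE if veg_climate_shifts is None else veg_climate_shifts)
    rcp_scale = dict(_DEFAULT_RCP_SCALE if rcp_scale is None else rcp_scale)
    known = _CLIMATE_SHIFT_VARS | _HUMAN_SHIFT_VARS
    unknown = [k for k in shifts if k not in known]
    if unknown:
        raise ValueError(f"shifts for unknown predictors: {unknown} "
                         f"(legal: {sorted(known)})")
    bad_veg = [k for k in list(veg_co2_shifts) + list(veg_climate_shifts)
               if k not in _VEG_VARS]
    if bad_veg:
        raise ValueError(f"vegetation shifts for unknown layers: {bad_veg}")

    rng = np.random.default_rng(seed)
    grid = predictors.grid
    baseline_monthly = monthly_climatology(predictors)

    def scale_of(var: str) -> float:
        ref = np.abs(baseline_monthly[var]).mean()
        return float(ref) if ref > 0 else 1.0

    picontrol: dict[str, dict[str, np.ndarray]] = {}
    future: dict[str, dict[str, dict[str, np.ndarray]]] = {r: {} for r in rcps}
    veg_climate_delta: dict[str, dict[str, dict[str, np.ndarray]]] = {
        r: {} for r in rcps}

    for gcm in gcms:
        bias = {var: noise_frac * scale_of(var)
                * _smooth_standard_normal(rng, grid.shape, 4.0)
                for var in MONTHLY_VARS}
        picontrol[gcm] = {var: baseline_monthly[var] + bias[var][None]
                          for var in MONTHLY_VARS}
        for rcp in rcps:
            s = rcp_scale[rcp]
            fut = {}
            for var in MONTHLY_VARS:
                delta = s * shifts.get(var, 0.0)
                eps = (noise_frac / 2.0) * scale_of(var) \
                    * _smooth_standard_normal(rng, grid.shape, 4.0)
                fut[var] = picontrol[gcm][var] + delta + eps[None]
            future[rcp][gcm] = fut
            vcd = {}
            for name, frac in veg_climate_shifts.items():
                base = predictors[name]
                d = s * frac * (base if name in ("GPP", "GPP_s") else np.ones_like(base))
                eps = 0.1 * np.abs(d).mean() \
                    * _smooth_standard_normal(rng, grid.shape, 4.0) if np.any(d) else 0.0
                vcd[name] = d + eps
            veg_climate_delta[rcp][gcm] = vcd

    veg_co2_delta = {}
    for rcp in rcps:
        s = rcp_scale[rcp]
        veg_co2_delta[rcp] = {
            name: s * frac * (predictors[name] if name in ("GPP", "GPP_s")
                              else np.ones_like(predictors[name]))
            for name, frac in veg_co2_shifts.items()}

    human_modern_sim = {name: predictors[name].copy()
                        for name in ("popd", "crop", "roads")}
    human_future_sim: dict[str, dict[str, np.ndarray]] = {}
    for rcp in rcps:
        layers = {}
        for name in ("popd", "crop", "roads"):
            delta = shifts.get(name, 0.0)
            if delta == 0.0:
                layers[name] = human_modern_sim[name].copy()
            else:
                eps = 0.1 * abs(delta) * _smooth_standard_normal(rng, grid.shape, 4.0)
                layers[name] = human_modern_sim[name] + delta + eps
        human_future_sim[rcp] = layers

    co2_future = {r: 401.0 + rcp_scale[r] * 269.0 for r in rcps}  # 670 at s=1
    return ScenarioBundle(
        grid=grid, baseline=predictors, baseline_monthly=baseline_monthly,
        picontrol=picontrol, future=future,
        veg_climate_delta=veg_climate_delta, veg_co2_delta=veg_co2_delta,
        human_modern_sim=human_modern_sim, human_future_sim=human_future_sim,
        co2_modern=401.0, co2_future=co2_future, rcps=tuple(rcps),
        gcms=tuple(gcms))


# ------------------------------------------------------------------ suite

def generate_dataset(seed: int = 0, nlon: int = 40, nlat: int = 20,
                     spatial_scale: float = 3.0,
                     truth: GroundTruth | None = None,
                     zero_fraction: float | None = None) -> SyntheticDataset:
    """One-call synthetic study: grid, predictors and fire observations."""
    grid = demo_grid(nlon=nlon, nlat=nlat)
    if truth is None:
        truth = default_ground_truth()
    if zero_fraction is not None:
        truth = replace(truth, zero_fraction=zero_fraction)
    predictors = generate_predictors(grid, seed=seed, spatial_scale=spatial_scale)
    fire = generate_fire(predictors, truth, seed=seed + 1)
    return SyntheticDataset(grid=grid, predictors=predictors, fire=fire,
                            truth=truth, seed=seed)
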