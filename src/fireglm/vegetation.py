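"""Vegetation input synthesis.

fAPAR from LAI via the Beer-Lambert law, fAPAR rescaling against an
observational reference, PPFD from shortwave radiation, C3/C4 GPP mixing,
cloud cover from shortwave radiation via a baseline linear fit, and
biome-mean fractional-cover assignment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: quantum-efficiency conversion, micromol photons per joule of shortwave
KEC_UMOL_PER_J = 2.04
#: open-interval upper bound for fAPAR after rescaling
_FAPAR_MAX = 1.0 - 1e-9


def fapar_from_lai(lai, k: float = 0.5):
    """Beer-Lambert fAPAR = 1 - exp(-k * LAI), element-wise.

    ``k`` is the canopy light-extinction coefficient (~0.5).  Negative LAI is
    an error, not clamped.
    """
    lai = np.asarray(lai, dtype=float)
    if k <= 0:
        raise ValueError("extinction coefficient k must be positive")
    if np.any(lai < 0):
        raise ValueError("LAI must be non-negative")
    return 1.0 - np.exp(-k * lai)


def rescale_fapar(simulated, reference, baseline_simulated):
    """Bias-correct simulated fAPAR by the baseline ratio reference/simulated.

    The ratio is computed on the baseline period and applied to any
    experiment's simulated field; output clipped to [0, 1).  Cells where the
    baseline simulation is zero but the reference is not get ratio 1 with a
    logged warning.
    """
    simulated = np.asarray(simulated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    baseline_simulated = np.asarray(baseline_simulated, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = reference / baseline_simulated
    bad = (baseline_simulated == 0) & (reference != 0)
    if np.any(bad):
        logger.warning("rescale_fapar: %d cells with zero baseline fAPAR but "
                       "nonzero reference; ratio set to 1", int(bad.sum()))
    ratio = np.where(baseline_simulated == 0, 1.0, ratio)
    return np.clip(simulated * ratio, 0.0, _FAPAR_MAX)


def ppfd_from_shortwave(rsds, kec: float = KEC_UMOL_PER_J):
    """PPFD (mol photons m-2 day-1) from shortwave radiation (W m-2):
    86400 s/day * 1e-6 mol/umol * kEC * rsds."""
    rsds = np.asarray(rsds, dtype=float)
    if np.any(rsds < 0):
        raise ValueError("shortwave radiation must be non-negative")
    return 60.0 * 60.0 * 24.0 * 1e-6 * kec * rsds


def combine_gpp(gpp_c3, gpp_c4, c4_fraction):
    """Convex combination GPP_c3 * (1 - f_C4) + GPP_c4 * f_C4."""
    gpp_c3 = np.asarray(gpp_c3, dtype=float)
    gpp_c4 = np.asarray(gpp_c4, dtype=float)
    c4 = np.asarray(c4_fraction, dtype=float)
    if np.any((c4 < 0) | (c4 > 1)):
        raise ValueError("C4 fraction must lie in [0, 1]")
    return gpp_c3 * (1.0 - c4) + gpp_c4 * c4


def fit_cloud_model(rsds_baseline, cloud_baseline) -> tuple[float, float]:
    """Least-squares slope/intercept of fractional cloud cover on mean
    monthly shortwave radiation over a paired baseline period."""
    x = np.asarray(rsds_baseline, dtype=float).ravel()
    y = np.asarray(cloud_baseline, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("baseline pairs must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 baseline pairs to fit the cloud model")
    if np.ptp(x) == 0:
        raise ValueError("degenerate baseline: constant shortwave radiation")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def cloud_cover_from_rsds(rsds_monthly, slope: float, intercept: float):
    """Predicted fractional cloud cover slope*rsds + intercept, clipped to
    [0, 1]."""
    rsds = np.asarray(rsds_monthly, dtype=float)
    return np.clip(slope * rsds + intercept, 0.0, 1.0)


def biome_cover_table(biome_map, tree, grass, shrub) -> pd.DataFrame:
    """Per-biome mean tree/grass/shrub fractions (columns: biome_id, tree,
    grass, shrub), the lookup table for biome_cover_assignment."""
    df = pd.DataFrame({
        "biome_id": np.asarray(biome_map).ravel(),
        "tree": np.asarray(tree, dtype=float).ravel(),
        "grass": np.asarray(grass, dtype=float).ravel(),
        "shrub": np.asarray(shrub, dtype=float).ravel(),
    })
    return df.groupby("biome_id", as_index=False).mean()


def biome_cover_assignment(biome_map, cover_table: pd.DataFrame
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assign each cell its biome's mean tree/grass/shrub cover.

    Within-biome variance of the outputs is exactly zero.  Biome ids present
    in the map but absent from the table are an error.
    """
    biome_map = np.asarray(biome_map)
    table = cover_table.set_index("biome_id")
    ids = np.unique(biome_map)
    unmapped = [int(i) for i in ids if i not in table.index]
    if unmapped:
        raise ValueError(f"biome ids without a cover-table row: {unmapped}")
    out = []
    for col in ("tree", "grass", "shrub"):
        lut = table[col].to_dict()
        out.append(np.vectorize(lut.__getitem__, otypes=[float])(biome_map))
    return tuple(out)
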