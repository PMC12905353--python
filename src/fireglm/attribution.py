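"""Per-cell driver attribution and biome aggregation.

The change in each fire property between a future experiment and the modern
baseline is decomposed on the linear-predictor scale as the first-order
(linearised) contribution of each predictor: Delta x_j * beta_j on the
standardised scale the model was fitted on.  The contributions sum exactly
to the total linear-predictor change, and the per-cell largest positive and
negative contributors give dominant-driver maps.  Burnt area is aggregated
to biomes as area-weighted totals in km^2 with global percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import FittedGLM, _standardised_design
from .grid import GridDefinition
from .predictors import PREDICTORS

logger = logging.getLogger(__name__)


@dataclass
class AttributionResult:
    """Signed per-cell, per-predictor contributions on the link scale.

    ``contributions`` has shape (n_cells, 16) in canonical predictor order;
    ``delta_eta`` is the total linear-predictor change per cell.
    ``top_positive``/``top_negative`` hold predictor indices, -1 where no
    strictly positive (negative) contribution exists.
    """

    contributions: np.ndarray
    delta_eta: np.ndarray
    top_positive: np.ndarray
    top_negative: np.ndarray
    layout: tuple[str, ...] = PREDICTORS

    def label(self, idx: int) -> str | None:
        return None if idx < 0 else self.layout[idx]


def predictor_contributions(model: FittedGLM, x_modern,
                            x_future) -> AttributionResult:
    """First-order decomposition (x_future,j - x_modern,j) * beta_j on the
    standardised linear-predictor scale.

    Ties for the largest positive/negative contributor break to the lowest
    predictor index; exact-zero contributions never win.
    """
    z_modern = _standardised_design(model, x_modern)
    z_future = _standardised_design(model, x_future)
    if z_modern.shape != z_future.shape:
        raise ValueError("modern/future designs have different shapes")
    contrib = (z_future - z_modern) * model.beta[1:]
    delta_eta = contrib.sum(axis=1)

    # argmax returns the lowest index on ties, which is the documented rule
    top_pos = np.argmax(contrib, axis=1)
    top_pos = np.where(contrib[np.arange(len(top_pos)), top_pos] > 0, top_pos, -1)
    top_neg = np.argmin(contrib, axis=1)
    top_neg = np.where(contrib[np.arange(len(top_neg)), top_neg] < 0, top_neg, -1)

    return AttributionResult(contributions=contrib, delta_eta=delta_eta,
                             top_positive=top_pos, top_negative=top_neg)


def dominant_driver_map(result: AttributionResult, shape=None
                        ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Integer-coded maps of the largest positive and negative contributors
    plus a frequency table of how often each predictor dominates."""
    pos, neg = result.top_positive, result.top_negative
    if shape is not None:
        pos, neg = pos.reshape(shape), neg.reshape(shape)
    rows = []
    for j, name in enumerate(result.layout):
        rows.append({"predictor": name,
                     "n_top_positive": int((result.top_positive == j).sum()),
                     "n_top_negative": int((result.top_negative == j).sum())})
    freq = pd.DataFrame(rows)
    return pos, neg, freq


def biome_aggregate(ba, biome_map, grid: GridDefinition,
                    biome_names: dict[int, str] | None = None,
                    ba_future=None) -> pd.DataFrame:
    """Area-weighted burnt area per biome.

    Columns: biome_id (+name), burnt_area_km2 = sum(BA * cell area), and
    global_pct against the global total; pct_change when a future field is
    given.
    """
    ba = np.asarray(ba, dtype=float)
    biome_map = np.asarray(biome_map)
    if ba.shape != biome_map.shape or ba.shape != grid.shape:
        raise ValueError("BA, biome map and grid must be co-registered")
    if biome_names is not None:
        unmapped = sorted(int(i) for i in np.unique(biome_map)
                          if int(i) not in biome_names)
        if unmapped:
            raise ValueError(f"biome ids without a name: {unmapped}")
    area = grid.cell_area
    burnt = ba * area
    total = float(burnt.sum())
    rows = []
    for bid in np.unique(biome_map):
        sel = biome_map == bid
        km2 = float(burnt[sel].sum())
        row = {"biome_id": int(bid),
               "burnt_area_km2": km2,
               "global_pct": 100.0 * km2 / total if total > 0 else np.nan}
        if biome_names is not None:
            row["biome"] = biome_names[int(bid)]
        if ba_future is not None:
            fut = float((np.asarray(ba_future, dtype=float) * area)[sel].sum())
            row["future_burnt_area_km2"] = fut
            row["pct_change"] = 100.0 * (fut - km2) / km2 if km2 > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def global_percentages(burnt_km2, global_total: float | None = None) -> np.ndarray:
    """Biome shares of the global burnt-area total, in percent."""
    burnt = np.asarray(burnt_km2, dtype=float)
    if global_total is None:
        global_total = float(burnt.sum())
    return 100.0 * burnt / global_total


def ignition_expansion(ba_modern, ba_future, threshold: float,
                       lat_field, tropics_band: float = 23.5) -> dict:
    """Threshold-crossing bookkeeping between two burnt-area fields.

    Counts cells above the ignition threshold in each field, the percentage
    change in that count, upward crossings (future >= threshold > modern)
    and the share of those crossings north of the tropics band.
    """
    if not (0 < tropics_band < 90):
        raise ValueError("tropics band must lie in (0, 90) degrees")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    modern = np.asarray(ba_modern, dtype=float)
    future = np.asarray(ba_future, dtype=float)
    lat = np.asarray(lat_field, dtype=float)
    if not (modern.shape == future.shape == lat.shape):
        raise ValueError("fields must be co-registered")
    above_modern = modern >= threshold
    above_future = future >= threshold
    gained = above_future & ~above_modern
    lost = above_modern & ~above_future
    n_modern, n_future = int(above_modern.sum()), int(above_future.sum())
    pct_change = (100.0 * (n_future - n_modern) / n_modern
                  if n_modern > 0 else np.nan)
    n_gained = int(gained.sum())
    northern_share = (100.0 * float((gained & (lat > tropics_band)).sum()) / n_gained
                      if n_gained > 0 else np.nan)
    return {"n_above_modern": n_modern, "n_above_future": n_future,
            "pct_change_above": pct_change, "n_gained": n_gained,
            "n_lost": int(lost.sum()), "northern_share_pct": northern_share}


INCREASE, DECREASE, NONE = 1, -1, 0


def change_map(modern, future, min_change: float = 0.05
               ) -> tuple[np.ndarray, int]:
    """Signed categorical field of relative change: +1 where
    (future - modern)/modern > min_change, -1 where < -min_change, else 0.
    Modern-zero cells are excluded (label 0) and counted."""
    modern = np.asarray(modern, dtype=float)
    future = np.asarray(future, dtype=float)
    if modern.shape != future.shape:
        raise ValueError("fields must be co-registered")
    ok = modern != 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("change_map: %d modern-zero cells excluded", n_excluded)
    rel = np.zeros_like(modern)
    rel[ok] = (future[ok] - modern[ok]) / modern[ok]
    labels = np.where(rel > min_change, INCREASE,
                      np.where(rel < -min_change, DECREASE, NONE))
    labels[~ok] = NONE
    return labels, n_excluded


def combined_change_map(modern: dict[str, np.ndarray],
                        future: dict[str, np.ndarray],
                        min_change: float = 0.05) -> np.ndarray:
    """Agreement map over BA, FS and FI: +1 (-1) only where all three
    properties change by more than ``min_change`` in the same direction."""
    labels = [change_map(modern[k], future[k], min_change)[0]
              for k in ("BA", "FS", "FI")]
    stacked = np.stack(labels)
    out = np.where((stacked == INCREASE).all(axis=0), INCREASE,
                   np.where((stacked == DECREASE).all(axis=0), DECREASE, NONE))
    return out
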