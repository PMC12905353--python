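"""Ignition threshold and True Skill Statistic evaluation.

Because the burnt-area model is probabilistic its fitted values never reach
zero, but the fire-size and fire-intensity models return a value for every
cell whether or not ignition is possible.  A threshold on fitted burnt area
separates burnable from unburnable cells: it is taken as a quantile
(default the median) of the fitted values on cells whose observed burnt
area is zero, and evaluated as a presence/absence classifier with the True
Skill Statistic, TSS = sensitivity + specificity - 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: CSV column order for threshold reports
REPORT_COLUMNS = ("percentile", "threshold", "TSS", "sensitivity",
                  "specificity", "maxTSS")


@dataclass(frozen=True)
class ThresholdReport:
    percentile: float
    threshold: float
    sensitivity: float
    specificity: float
    n_zero_cells: int

    @property
    def TSS(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    @property
    def maxTSS(self) -> float:
        # reported alongside TSS in the skill table; identically TSS + 1
        # (equivalently sensitivity + specificity)
        return self.TSS + 1.0

    def as_row(self) -> dict[str, float]:
        return {"percentile": self.percentile, "threshold": self.threshold,
                "TSS": self.TSS, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "maxTSS": self.maxTSS}


def tss(fitted_ba, observed_ba, threshold: float
        ) -> tuple[float, float, float, float]:
    """Classification skill of ``fitted >= threshold`` against observed
    presence (observed BA > 0).

    Returns (sensitivity, specificity, TSS, maxTSS).  Undefined without both
    positive and negative observed cells.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fitted = np.asarray(fitted_ba, dtype=float).ravel()
    observed = np.asarray(observed_ba, dtype=float).ravel()
    if fitted.shape != observed.shape:
        raise ValueError("fitted/observed shape mismatch")
    pos = observed > 0
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ValueError("TSS undefined: need both burnt and unburnt observed cells")
    pred_pos = fitted >= threshold
    sensitivity = float((pred_pos & pos).sum() / pos.sum())
    specificity = float((~pred_pos & neg).sum() / neg.sum())
    t = sensitivity + specificity - 1.0
    return sensitivity, specificity, t, t + 1.0


def derive_threshold(fitted_ba, observed_ba,
                     percentile: float = 0.5) -> ThresholdReport:
    """Ignition threshold from the fitted-value distribution on observed-zero
    cells (linear-interpolation quantile), with classification metrics at
    that threshold."""
    if not (0 < percentile < 1):
        raise ValueError("percentile must lie in (0, 1)")
    fitted = np.asarray(fitted_ba, dtype=float).ravel()
    observed = np.asarray(observed_ba, dtype=float).ravel()
    if fitted.shape != observed.shape:
        raise ValueError("fitted/observed shape mismatch")
    zero = observed == 0
    if not zero.any():
        raise ValueError("no observed-zero cells; cannot derive a threshold")
    thr = float(np.quantile(fitted[zero], percentile))
    sens, spec, _, _ = tss(fitted, observed, thr)
    return ThresholdReport(percentile=percentile, threshold=thr,
                           sensitivity=sens, specificity=spec,
                           n_zero_cells=int(zero.sum()))


def tss_curve(fitted_ba, observed_ba, percentiles) -> pd.DataFrame:
    """One ThresholdReport row per percentile, in the standard column order
    (percentile, threshold, TSS, sensitivity, specificity, maxTSS)."""
    percentiles = list(percentiles)
    if any(not (0 < p < 1) for p in percentiles):
        raise ValueError("percentiles must lie in (0, 1)")
    if sorted(percentiles) != percentiles:
        raise ValueError("percentiles must be sorted ascending")
    rows = [derive_threshold(fitted_ba, observed_ba, p).as_row()
            for p in percentiles]
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def apply_threshold(ba_pred, fs_pred, fi_pred, threshold: float
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Zero fire size/intensity where predicted burnt area is below the
    ignition threshold.  Returns (FS gated, FI gated, unburnt %)."""
    ba = np.asarray(ba_pred, dtype=float)
    fs = np.asarray(fs_pred, dtype=float)
    fi = np.asarray(fi_pred, dtype=float)
    if not (ba.shape == fs.shape == fi.shape):
        raise ValueError("BA/FS/FI fields must be co-registered")
    unburnable = ba < threshold
    fs_gated = np.where(unburnable, 0.0, fs)
    fi_gated = np.where(unburnable, 0.0, fi)
    unburnt_pct = 100.0 * float(unburnable.mean())
    return fs_gated, fi_gated, unburnt_pct
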