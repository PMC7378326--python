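"""Canopy fruit-distribution summaries and visible-to-total extrapolation.

Top-view imagery only ever shows part of a tree's crop, so detected counts
underestimate the true per-tree load. Extrapolation works by calibrating a
linear regression of reference totals (harvested or field-counted) on
detected counts over a sample of trees, then predicting totals for every
tree from its detected count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .evaluation import RegressionFit, linear_fit, round_half_up

__all__ = [
    "CalibrationPair",
    "canopy_distribution",
    "fit_calibration",
    "predict_total",
]

CANOPY_COLUMNS = ["Nfcvt", "Nfcvm", "Nfcvun", "Total", "Top (%)",
                  "Middle (%)", "Underside (%)"]


@dataclass(frozen=True)
class CalibrationPair:
    """Per-tree (detected-on-imagery, reference-total) count pair."""

    tree_id: str
    detected: int
    reference: int

    def __post_init__(self):
        if self.detected < 0 or self.reference < 0:
            raise ValueError("counts must be nonnegative")


def canopy_distribution(counts, ids: Sequence | None = None,
                        presented: bool = False) -> pd.DataFrame:
    """Per-tree stratum totals and percentage shares, plus an Average row.

    ``counts`` is an (n, 3) array-like of visual counts per canopy stratum
    (top, middle, underside) — the Nfcvt/Nfcvm/Nfcvun columns. Percentages
    are ``100 * count / total`` per tree; the Average row is the column-wise
    arithmetic mean of the unrounded values. ``presented=True`` rounds every
    cell to 2 decimals, half-up. A zero-total tree is an error (its shares
    are undefined).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] == 0:
        raise ValueError("counts must be a nonempty (n, 3) array of stratum counts")
    if (arr < 0).any():
        raise ValueError("stratum counts must be nonnegative")
    index = list(ids) if ids is not None else list(range(1, arr.shape[0] + 1))
    if len(index) != arr.shape[0]:
        raise ValueError("ids length must match counts")
    totals = arr.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"tree {index[zero[0]]!r} has zero total fruits")
    pct = 100.0 * arr / totals[:, None]
    df = pd.DataFrame(
        np.column_stack([arr, totals, pct]),
        index=pd.Index(index, name="Id"), columns=CANOPY_COLUMNS)
    df.loc["Average"] = df.iloc[: arr.shape[0]].mean(axis=0)
    if presented:
        df = df.map(round_half_up)
    return df


def fit_calibration(pairs: Sequence[CalibrationPair] | pd.DataFrame
                    ) -> RegressionFit:
    """OLS calibration of reference totals on detected counts.

    Regresses ``reference`` (y) on ``detected`` (x) — the direction needed to
    predict totals from imagery counts — and reports slope, intercept, R²,
    MAE and RMSE of the fit. Needs >= 3 pairs with non-constant detected
    counts.
    """
    if isinstance(pairs, pd.DataFrame):
        detected = pairs["detected"].to_numpy(dtype=float)
        reference = pairs["reference"].to_numpy(dtype=float)
    else:
        detected = np.array([p.detected for p in pairs], dtype=float)
        reference = np.array([p.reference for p in pairs], dtype=float)
    return linear_fit(detected, reference)


def predict_total(fit: RegressionFit, detected) -> int | np.ndarray:
    """Predicted total fruit count for one or many detected counts:
    ``round(slope * detected + intercept)``, half-up, clamped at >= 0."""
    raw = fit.predict(detected)
    clamped = np.maximum(np.floor(raw + 0.5), 0.0).astype(int)
    if np.isscalar(detected) or np.ndim(detected) == 0:
        return int(clamped)
    return clamped
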