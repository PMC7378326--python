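"""Detection evaluation and count-series statistics.

Implements the standard object-detection metric family over IoU-matched
boxes — per-picture TP/FP/FN, precision ``TP/(TP+FP)``, recall
``TP/(TP+FN)``, F1 ``2PR/(P+R)`` — plus an accuracy ``A = TP/Nfp`` defined
against the manually counted number of fruits in the picture (Nfp), and the
count-series statistics MAE, RMSE and ordinary-least-squares R² used to
compare counted and harvested fruit numbers.

All internal arithmetic is unrounded; presentation rounding (2 decimals,
half-up, matching how such tables are printed) happens only in
:func:`round_half_up` / ``metrics_table(..., presented=True)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import BBox

__all__ = [
    "MatchResult",
    "MetricsRow",
    "RegressionFit",
    "iou",
    "match_detections",
    "detection_metrics",
    "metrics_table",
    "mae",
    "rmse",
    "linear_fit",
    "round_half_up",
]

TABLE_COLUMNS = ["TP", "FP", "FN", "P", "R", "F1", "Nfp", "A"]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (as printed tables round)."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MatchResult:
    """One-to-one detection/truth pairing for a single image."""

    pairs: list[tuple[int, int, float]]   # (detection idx, truth idx, IoU)
    n_detections: int
    n_truth: int

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fp(self) -> int:
        return self.n_detections - self.tp

    @property
    def fn(self) -> int:
        return self.n_truth - self.tp


@dataclass
class MetricsRow:
    """One evaluation-picture row: counts plus the four metrics.

    Undefined ratios (e.g. precision with no detections) are ``nan``, never
    silently zero.
    """

    picture_id: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    nfp: int
    accuracy: float


@dataclass
class RegressionFit:
    """Simple OLS fit y = slope*x + intercept with goodness-of-fit numbers."""

    slope: float
    intercept: float
    r_squared: float
    mae: float
    rmse: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two half-open boxes."""
    ix = max(0.0, min(a.xmax, b.xmax) - max(a.xmin, b.xmin))
    iy = max(0.0, min(a.ymax, b.ymax) - max(a.ymin, b.ymin))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def match_detections(detections: Sequence[BBox], truth: Sequence[BBox],
                     iou_min: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching of detections to ground-truth boxes.

    Detections are visited in descending score order (ties by (ymin, xmin));
    each takes the unmatched truth box of highest IoU, provided
    IoU >= ``iou_min``; IoU ties are broken by the truth box's (ymin, xmin).
    A matched detection is a TP, an unmatched detection an FP, an unmatched
    truth box an FN.
    """
    det_order = sorted(range(len(detections)),
                       key=lambda i: (-(detections[i].score or 0.0),
                                      detections[i].ymin, detections[i].xmin))
    unmatched = set(range(len(truth)))
    pairs = []
    for di in det_order:
        best = None
        for ti in sorted(unmatched,
                         key=lambda t: (truth[t].ymin, truth[t].xmin)):
            val = iou(detections[di], truth[ti])
            if val >= iou_min and (best is None or val > best[1]):
                best = (ti, val)
        if best is not None:
            unmatched.discard(best[0])
            pairs.append((di, best[0], best[1]))
    return MatchResult(pairs=pairs, n_detections=len(detections),
                       n_truth=len(truth))


def detection_metrics(match: MatchResult | tuple[int, int, int], nfp: int,
                      picture_id: str = "") -> MetricsRow:
    """Compute the per-picture metric row from match counts and Nfp.

    ``match`` may be a :class:`MatchResult` or a raw ``(tp, fp, fn)`` triple
    (useful when re-deriving metrics from published count columns). Raises
    when ``nfp`` is inconsistent (zero fruits but positive TP).
    """
    if isinstance(match, MatchResult):
        tp, fp, fn = match.tp, match.fp, match.fn
    else:
        tp, fp, fn = match
    if min(tp, fp, fn) < 0 or nfp < 0:
        raise ValueError("counts must be nonnegative")
    if nfp == 0 and tp > 0:
        raise ValueError(f"picture {picture_id!r}: tp={tp} but nfp=0")
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    accuracy = tp / nfp if nfp > 0 else math.nan
    return MetricsRow(picture_id=str(picture_id), tp=tp, fp=fp, fn=fn,
                      precision=precision, recall=recall, f1=f1,
                      nfp=nfp, accuracy=accuracy)


def metrics_table(rows: Sequence[MetricsRow], presented: bool = False
                  ) -> pd.DataFrame:
    """Assemble per-picture rows plus an ``Avg`` row (column-wise arithmetic
    mean of the unrounded values). With ``presented=True`` every cell is
    rounded to 2 decimals, half-up, for comparison against printed tables.
    """
    if not rows:
        raise ValueError("metrics_table needs at least one row")
    data = {
        "TP": [r.tp for r in rows], "FP": [r.fp for r in rows],
        "FN": [r.fn for r in rows], "P": [r.precision for r in rows],
        "R": [r.recall for r in rows], "F1": [r.f1 for r in rows],
        "Nfp": [r.nfp for r in rows], "A": [r.accuracy for r in rows],
    }
    df = pd.DataFrame(data, index=[r.picture_id for r in rows],
                      columns=TABLE_COLUMNS, dtype=float)
    df.loc["Avg"] = df.mean(axis=0, skipna=True)
    df.index.name = "Picture"
    if presented:
        df = df.map(round_half_up)
    return df


def mae(actual, forecast) -> float:
    """Mean absolute error ``(1/n) * sum |A_t - F_t|``."""
    a, f = _paired(actual, forecast)
    return float(np.mean(np.abs(a - f)))


def rmse(actual, forecast) -> float:
    """Root mean square error ``sqrt((1/n) * sum (A_t - F_t)^2)``."""
    a, f = _paired(actual, forecast)
    return float(np.sqrt(np.mean((a - f) ** 2)))


def _paired(actual, forecast) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if a.shape != f.shape or a.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if a.size == 0:
        raise ValueError("series must be nonempty")
    return a, f


def linear_fit(x, y) -> RegressionFit:
    """Ordinary least squares with intercept; R² = 1 - SSres/SStot.

    MAE/RMSE are computed between observed and fitted y. Requires n >= 3 and
    non-constant x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the fit is undefined")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=r2, mae=mae(y, fitted), rmse=rmse(y, fitted),
                         n=int(x.size))
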