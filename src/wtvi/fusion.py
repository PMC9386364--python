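"""Plot-level feature extraction, spectral-texture fusion, and k-fold CV.

A feature table holds one row per plot-date with columns ``plot_id``,
``stage``, ``LAI``, ``Ene``, ``VI_<name>`` and ``WTVI_<name>`` for each
registered index, where ``WTVI_<name> = VI_<name> * Ene``.

Model evaluation follows the k-fold scheme: a seeded shuffle partitions
the samples into k near-equal disjoint folds; each fold in turn is held
out, a simple linear model ``LAI = slope * feature + intercept`` is fit
on the remaining folds, and R^2, RMSE and rRMSE are scored on the
held-out fold. Reported aggregates are the plain arithmetic means of
the per-fold values (mean Coef^2, mean R^2, mean RMSE, mean rRMSE);
final coefficients come from a refit on all data.

Conventions: RMSE uses 1/n (not 1/(n-2)); rRMSE = 100 * RMSE / mean of
the observed LAI in the evaluated fold; held-out R^2 may be negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InputError
from .indices import VIImage
from .raster_io import PlotROI

__all__ = [
    "FitMetrics",
    "CVResult",
    "plot_vi",
    "fuse",
    "fit_linear",
    "kfold_evaluate",
    "kfold_split",
    "rank_indices",
    "feature_columns",
]


def plot_vi(vi_image: VIImage, roi: PlotROI) -> float:
    """Plot-level VI: mean of valid index pixels inside the ROI."""
    h, w = vi_image.values.shape
    roi.validate_against(h, w)
    sl = (slice(roi.row_min, roi.row_max), slice(roi.col_min, roi.col_max))
    valid = vi_image.valid_mask[sl]
    if not valid.any():
        raise DegenerateDataError(
            f"no valid {vi_image.name} pixels in ROI {roi.plot_id!r}"
        )
    return float(vi_image.values[sl][valid].mean())


def fuse(vi: float, ene: float) -> float:
    """Fused spectral-texture index: the product VI * Ene."""
    if not (math.isfinite(vi) and math.isfinite(ene)):
        raise InputError(f"non-finite fusion inputs vi={vi}, ene={ene}")
    return vi * ene


@dataclass(frozen=True)
class FitMetrics:
    slope: float
    intercept: float
    r2: float
    rmse: float
    rrmse: float


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xc = x - x.mean()
    sxx = float(np.dot(xc, xc))
    if sxx <= 0:
        raise DegenerateDataError("zero-variance feature")
    slope = float(np.dot(xc, y - y.mean()) / sxx)
    return slope, float(y.mean() - slope * x.mean())


def _score(y: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    resid = y - pred
    ss_res = float(np.dot(resid, resid))
    yc = y - y.mean()
    ss_tot = float(np.dot(yc, yc))
    if ss_tot <= 0:
        raise DegenerateDataError("constant response: R^2 undefined")
    rmse = math.sqrt(ss_res / len(y))
    if y.mean() == 0:
        raise DegenerateDataError("zero mean response: rRMSE undefined")
    return 1.0 - ss_res / ss_tot, rmse, 100.0 * rmse / float(y.mean())


def fit_linear(features, lai) -> FitMetrics:
    """OLS fit of ``lai = slope * feature + intercept`` with fit metrics.

    R^2 = 1 - SS_res/SS_tot; RMSE = sqrt(SS_res / n);
    rRMSE = 100 * RMSE / mean(lai). Requires n >= 3 and a
    non-constant feature.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(lai, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("features and lai must be equal-length 1D vectors")
    if len(x) < 3:
        raise DegenerateDataError(f"need n >= 3 samples, got {len(x)}")
    slope, intercept = _ols_line(x, y)
    r2, rmse, rrmse = _score(y, slope * x + intercept)
    return FitMetrics(slope, intercept, r2, rmse, rrmse)


def kfold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffle into k disjoint, exhaustive, near-equal folds.

    The first ``n % k`` folds receive one extra sample each.
    """
    if k < 2:
        raise InputError(f"k must be >= 2, got {k}")
    if k > n:
        raise InputError(f"k={k} exceeds sample count n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(order[start : start + size]))
        start += size
    return folds


@dataclass
class CVResult:
    """Cross-validated evaluation of one feature against measured LAI."""

    name: str
    k: int
    mean_coef2: float
    mean_r2: float
    mean_rmse: float
    mean_rrmse: float
    fold_coefs: list[float] = field(repr=False, default_factory=list)
    fold_r2: list[float] = field(repr=False, default_factory=list)
    fold_rmse: list[float] = field(repr=False, default_factory=list)
    fold_rrmse: list[float] = field(repr=False, default_factory=list)
    slope: float = float("nan")      # full-data refit
    intercept: float = float("nan")  # full-data refit

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "k": self.k,
            "mean_coef2": self.mean_coef2,
            "mean_r2": self.mean_r2,
            "mean_rmse": self.mean_rmse,
            "mean_rrmse": self.mean_rrmse,
            "slope": self.slope,
            "intercept": self.intercept,
            "fold_coefs": self.fold_coefs,
            "fold_r2": self.fold_r2,
            "fold_rmse": self.fold_rmse,
            "fold_rrmse": self.fold_rrmse,
        }


def kfold_evaluate(features, lai, k: int, seed: int, name: str = "") -> CVResult:
    """k-fold cross-validated linear model of LAI against one feature."""
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(lai, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("features and lai must be equal-length 1D vectors")
    folds = kfold_split(len(x), k, seed)
    coefs, r2s, rmses, rrmses = [], [], [], []
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(x)), test_idx, assume_unique=False)
        slope, intercept = _ols_line(x[train], y[train])
        r2, rmse, rrmse = _score(y[test_idx], slope * x[test_idx] + intercept)
        coefs.append(slope)
        r2s.append(r2)
        rmses.append(rmse)
        rrmses.append(rrmse)
    full = fit_linear(x, y)
    return CVResult(
        name=name,
        k=k,
        mean_coef2=float(np.mean([c**2 for c in coefs])),
        mean_r2=float(np.mean(r2s)),
        mean_rmse=float(np.mean(rmses)),
        mean_rrmse=float(np.mean(rrmses)),
        fold_coefs=coefs,
        fold_r2=r2s,
        fold_rmse=rmses,
        fold_rrmse=rrmses,
        slope=full.slope,
        intercept=full.intercept,
    )


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Evaluable feature columns of a feature table (VI_*, WTVI_*, Ene)."""
    cols = [c for c in table.columns if c.startswith(("VI_", "WTVI_"))]
    if "Ene" in table.columns:
        cols.append("Ene")
    return cols


def rank_indices(table: pd.DataFrame, k: int, seed: int) -> list[CVResult]:
    """One CVResult per feature column, best mean R^2 first.

    Ties break toward lower mean RMSE, then lexicographic name. The
    table must contain an ``LAI`` column and at least one feature
    column.
    """
    cols = feature_columns(table)
    if not cols:
        raise InputError("feature table has no VI_/WTVI_/Ene columns")
    if "LAI" not in table.columns:
        raise InputError("feature table has no LAI column")
    lai = table["LAI"].to_numpy(dtype=np.float64)
    results = [
        kfold_evaluate(table[c].to_numpy(dtype=np.float64), lai, k, seed, name=c)
        for c in cols
    ]
    return sorted(results, key=lambda r: (-r.mean_r2, r.mean_rmse, r.name))
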