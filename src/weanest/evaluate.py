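"""Point metrics, bootstrap confidence intervals and residual diagnostics.

Metrics are computed in years, after predictions have been inverse
robust-scaled.  RMSE penalizes large errors quadratically, MAE weighs all
errors equally, and R^2 is 1 - SSres/SStot about the mean of the reference
values.  Percentile bootstrap (resampling prediction/reference pairs with
replacement) provides seeded 95% confidence intervals.  Residuals
(reference - predicted) are summarized per tooth type or per maximum-age bin
with median, quartiles, Tukey whiskers and 1.5*IQR outliers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd


def _check_pair(y_true, y_pred, min_len: int = 2):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if y_true.size < min_len:
        raise ValueError(f"need at least {min_len} pairs")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("non-finite values in inputs")
    return y_true, y_pred


def rmse(y_true, y_pred) -> float:
    """Root mean squared error (years)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def mae(y_true, y_pred) -> float:
    """Mean absolute error (years)."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(y_true - y_pred)))


def r2(y_true, y_pred) -> float:
    """Coefficient of determination; NaN (with a warning) if y_true is constant."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R^2 undefined: zero variance in y_true", stacklevel=2)
        return float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    y_true,
    y_pred,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a paired metric (resampling pairs).

    Raises if the metric is undefined (non-finite) on more than 10% of
    resamples.
    """
    y_true, y_pred = _check_pair(y_true, y_pred, min_len=5)
    rng = np.random.default_rng(seed)
    n = y_true.size
    stats = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            stats[b] = metric(y_true[idx], y_pred[idx])
    bad = ~np.isfinite(stats)
    if bad.mean() > 0.10:
        raise ValueError(f"metric undefined on {bad.mean():.0%} of bootstrap resamples")
    stats = stats[~bad]
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass
class EvalReport:
    """Headline metrics with bootstrap CIs and a residual table."""

    rmse: float
    mae: float
    r2: float
    rmse_ci: tuple[float, float]
    mae_ci: tuple[float, float]
    r2_ci: tuple[float, float]
    n: int
    residuals: pd.DataFrame = field(repr=False, default=None)

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "n": self.n,
            "rmse": self.rmse,
            "rmse_ci": list(self.rmse_ci),
            "mae": self.mae,
            "mae_ci": list(self.mae_ci),
            "r2": self.r2,
            "r2_ci": list(self.r2_ci),
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d


def evaluate_predictions(
    df: pd.DataFrame,
    true_col: str = "y_true",
    pred_col: str = "y_pred",
    n_boot: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Full evaluation of a per-individual prediction table.

    ``df`` needs ``true_col`` and ``pred_col`` (years); ``sample_id``,
    ``tooth_type`` and ``max_age`` columns are carried into the residual table
    when present.
    """
    y_true = df[true_col].to_numpy(dtype=float)
    y_pred = df[pred_col].to_numpy(dtype=float)
    res = df.copy()
    res["residual"] = y_true - y_pred
    return EvalReport(
        rmse=rmse(y_true, y_pred),
        mae=mae(y_true, y_pred),
        r2=r2(y_true, y_pred),
        rmse_ci=bootstrap_ci(rmse, y_true, y_pred, n_boot=n_boot, seed=seed),
        mae_ci=bootstrap_ci(mae, y_true, y_pred, n_boot=n_boot, seed=seed + 1),
        r2_ci=bootstrap_ci(r2, y_true, y_pred, n_boot=n_boot, seed=seed + 2),
        n=len(df),
        residuals=res,
    )


def residuals_by_group(
    residuals: pd.DataFrame,
    grouping: str = "tooth_type",
    n_age_bins: int = 4,
) -> pd.DataFrame:
    """Box-plot backbone per group: median, quartiles, whiskers, outliers.

    ``grouping`` is ``"tooth_type"`` or ``"max_age_bin"`` (quantile bins of the
    ``max_age`` column).  Empty groups are omitted with a warning.
    """
    df = residuals.copy()
    if grouping == "tooth_type":
        key = "tooth_type"
    elif grouping == "max_age_bin":
        df["max_age_bin"] = pd.qcut(df["max_age"], q=n_age_bins, duplicates="drop").astype(str)
        key = "max_age_bin"
    else:
        raise ValueError("grouping must be 'tooth_type' or 'max_age_bin'")
    rows = []
    for name, grp in df.groupby(key, observed=True):
        r = grp["residual"].to_numpy(dtype=float)
        if r.size == 0:
            warnings.warn(f"empty group {name!r} omitted", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = r[(r >= lo_fence) & (r <= hi_fence)]
        outliers = r[(r < lo_fence) | (r > hi_fence)]
        rows.append(
            {
                "group": name,
                "n": int(r.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "whisker_lo": float(inside.min()) if inside.size else float("nan"),
                "whisker_hi": float(inside.max()) if inside.size else float("nan"),
                "n_outliers": int(outliers.size),
                "outliers": sorted(float(v) for v in outliers),
            }
        )
    return pd.DataFrame(rows)
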