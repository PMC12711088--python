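"""Temporal feature engineering for dentine isotope sequences.

Three derivative features are computed per isotope variable on the z-scaled
series, yielding the 9 numeric channels consumed by the sequence model, in the
fixed column order

    [d15N, d13C, age, delta_d15N, delta_d13C, roll_d15N, roll_d13C,
     slope_d15N, slope_d13C]

Consecutive differences capture the local direction and magnitude of isotopic
change, a centered 3-point rolling mean smooths analytical noise, and a
3-point local OLS slope against age measures the instantaneous rate of change.
Edge rules are explicit: the first difference is 0 ("no prior change"), the
rolling window shrinks at the two edges, and the slope window slides inward so
that a genuine regression is fit at every position.  Per-variable gaps (NaN in
one isotope) are handled by computing each feature over the present points of
that variable only and filling the missing positions with 0 in all of that
variable's channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import IndividualSeries

FEATURE_COLUMNS = (
    "d15N",
    "d13C",
    "age",
    "delta_d15N",
    "delta_d13C",
    "roll_d15N",
    "roll_d13C",
    "slope_d15N",
    "slope_d13C",
)

N_FEATURES = len(FEATURE_COLUMNS)


def consecutive_differences(values: np.ndarray) -> np.ndarray:
    """First differences of an age-ordered vector; out[0] = 0.

    Raises ``ValueError`` for vectors shorter than 2.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("consecutive_differences requires at least 2 values")
    out = np.empty_like(values)
    out[0] = 0.0
    out[1:] = values[1:] - values[:-1]
    return out


def rolling_mean3(values: np.ndarray) -> np.ndarray:
    """Centered 3-point rolling mean; the window shrinks to 2 points at the edges."""
    values = np.asarray(values, dtype=float)
    t = values.size
    if t == 0:
        raise ValueError("rolling_mean3 requires at least 1 value")
    if t == 1:
        return values.copy()
    out = np.empty(t)
    out[0] = (values[0] + values[1]) / 2.0
    out[-1] = (values[-2] + values[-1]) / 2.0
    if t > 2:
        out[1:-1] = (values[:-2] + values[1:-1] + values[2:]) / 3.0
    return out


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0.0:
        return 0.0
    return float(np.dot(xc, y - y.mean()) / denom)


def local_slope(values: np.ndarray, ages: np.ndarray, window: int = 3) -> np.ndarray:
    """Windowed OLS slope of ``values`` on ``ages`` centered at each position.

    At the edges the window slides inward to keep ``window`` points.  If the
    series is shorter than ``window``, a single global OLS slope is broadcast
    to all positions.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")
    t = values.size
    if t < window:
        return np.full(t, _ols_slope(ages, values))
    half = window // 2
    out = np.empty(t)
    for i in range(t):
        lo = min(max(i - half, 0), t - window)
        out[i] = _ols_slope(ages[lo : lo + window], values[lo : lo + window])
    return out


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-individual T x 9 engineered feature array (fixed column order)."""

    sample_id: str
    tooth_type: str
    ages: np.ndarray  # raw chronological ages, years
    channels: np.ndarray  # (T, 9), columns per FEATURE_COLUMNS

    def __post_init__(self):
        if self.channels.shape != (len(self.ages), N_FEATURES):
            raise ValueError(
                f"channels shape {self.channels.shape} != ({len(self.ages)}, {N_FEATURES})"
            )
        if not np.all(np.isfinite(self.channels)):
            raise ValueError(f"non-finite feature entries in {self.sample_id!r}")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])


def _variable_channels(values: np.ndarray, ages: np.ndarray) -> tuple[np.ndarray, ...]:
    """(base, delta, roll, slope) for one isotope, honouring NaN gaps.

    Features are computed over the present points only (with their true ages
    for the slope), then scattered back; positions where the base value is
    missing are 0 in all four channels.
    """
    t = values.size
    base = np.zeros(t)
    delta = np.zeros(t)
    roll = np.zeros(t)
    slope = np.zeros(t)
    present = np.isfinite(values)
    idx = np.flatnonzero(present)
    if idx.size == 0:
        return base, delta, roll, slope
    sub_v = values[idx]
    sub_a = ages[idx]
    base[idx] = sub_v
    if idx.size >= 2:
        delta[idx] = consecutive_differences(sub_v)
        slope[idx] = local_slope(sub_v, sub_a)
    roll[idx] = rolling_mean3(sub_v)
    return base, delta, roll, slope


def build_feature_matrix(series: IndividualSeries) -> FeatureMatrix:
    """Assemble the 9-channel feature matrix for one (z-scaled) series."""
    n15 = _variable_channels(series.d15n, series.ages)
    c13 = _variable_channels(series.d13c, series.ages)
    channels = np.column_stack(
        [
            n15[0],
            c13[0],
            series.ages,
            n15[1],
            c13[1],
            n15[2],
            c13[2],
            n15[3],
            c13[3],
        ]
    )
    return FeatureMatrix(
        sample_id=series.sample_id,
        tooth_type=series.tooth_type,
        ages=series.ages_raw.copy(),
        channels=channels,
    )
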