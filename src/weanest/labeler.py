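"""Regression-free elbow labelling of weaning completion age, plus robust scaling.

The supervision target is the age at the "elbow" of the declining δ¹⁵N
trajectory — the point where the breastfeeding-driven trophic enrichment gives
way to the post-weaning plateau.  The detector emulates the traditional
eye-balling of serial profiles without fitting a curve: both axes are min-max
normalized to [0, 1], a chord is drawn from the first to the last point, and
the elbow is the sample point with the maximum perpendicular distance to the
chord among points lying below it (the decline side).  Ties break toward the
earliest age.  Labelling uses δ¹⁵N only; δ¹³C enters the model as a feature
but not the target.

Elbow ages across the labelled set are then robust-scaled — centred by the
median and divided by the interquartile range — so the regressor trains on a
target insensitive to outlying weaning ages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import IndividualSeries

logger = logging.getLogger(__name__)

#: Minimum total δ¹⁵N range (per-mil) below which no decline is declared.
DEFAULT_MIN_RANGE = 0.3


class NoDeclineError(ValueError):
    """Raised when the δ¹⁵N trajectory carries no detectable decline."""


def estimate_elbow_age(
    ages: np.ndarray,
    d15n: np.ndarray,
    min_range: float = DEFAULT_MIN_RANGE,
) -> float:
    """Elbow age (years) of a δ¹⁵N trajectory by maximum chord distance.

    Parameters
    ----------
    ages, d15n:
        Age-ordered vectors; NaN δ¹⁵N entries are ignored.  At least 3 present
        points are required and ages must be strictly increasing.
    min_range:
        Total δ¹⁵N range (per-mil) below which :class:`NoDeclineError` is
        raised.

    Notes
    -----
    Min-max normalization of both axes makes the result invariant to affine
    rescaling of either variable.  If no point lies strictly below the chord
    (e.g. a convex rise-then-fall profile), the point of maximum absolute
    distance is used instead and a warning is logged.
    """
    ages = np.asarray(ages, dtype=float)
    d15n = np.asarray(d15n, dtype=float)
    present = np.isfinite(d15n)
    ages, d15n = ages[present], d15n[present]
    if ages.size < 3:
        raise ValueError("elbow estimation requires at least 3 d15N measurements")
    if np.any(np.diff(ages) <= 0):
        raise ValueError("ages must be strictly increasing")

    rng_n = float(d15n.max() - d15n.min())
    if rng_n < min_range:
        raise NoDeclineError(
            f"no isotopic decline detected: d15N range {rng_n:.3f} < {min_range} per-mil"
        )

    x = (ages - ages[0]) / (ages[-1] - ages[0])
    y = (d15n - d15n.min()) / rng_n

    # Signed area cross-product against the chord; dx > 0, so points below the
    # chord (decline side) have negative sign.
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    cross = dx * (y - y[0]) - dy * (x - x[0])
    dist = np.abs(cross) / np.hypot(dx, dy)

    below = cross < -1e-12
    if np.any(below):
        cand = np.where(below, dist, -np.inf)
    else:
        logger.warning("no point below the chord; falling back to maximum absolute distance")
        cand = dist
    best = cand.max()
    # Ties (within numerical noise) break toward the earliest age.
    i = int(np.flatnonzero(cand >= best - 1e-12)[0])
    return float(ages[i])


def estimate_onset_age(
    ages: np.ndarray,
    d15n: np.ndarray,
    threshold: float = DEFAULT_MIN_RANGE,
) -> float:
    """Age at which δ¹⁵N first drops more than ``threshold`` below its initial value.

    A convenience output for users wanting a weaning interval rather than a
    single completion age.  Returns the age of the last point still within
    ``threshold`` of the initial value (the onset-side bracket).
    """
    ages = np.asarray(ages, dtype=float)
    d15n = np.asarray(d15n, dtype=float)
    present = np.isfinite(d15n)
    ages, d15n = ages[present], d15n[present]
    if ages.size < 2:
        raise ValueError("onset estimation requires at least 2 d15N measurements")
    dropped = np.flatnonzero(d15n < d15n[0] - threshold)
    if dropped.size == 0:
        raise NoDeclineError("no isotopic decline detected for onset estimation")
    return float(ages[max(int(dropped[0]) - 1, 0)])


@dataclass(frozen=True)
class WeaningLabel:
    sample_id: str
    elbow_age: float  # years
    scaled_value: float | None = None


@dataclass(frozen=True)
class RobustScaleParams:
    """Median/IQR scaling of elbow ages; quartiles by linear interpolation."""

    median: float
    iqr: float

    def __post_init__(self):
        if self.iqr <= 0:
            raise ValueError("IQR is zero; cannot robust-scale labels")

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.median) / self.iqr

    def invert(self, z):
        return np.asarray(z, dtype=float) * self.iqr + self.median

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"median": self.median, "iqr": self.iqr}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RobustScaleParams":
        d = json.loads(Path(path).read_text())
        return cls(median=float(d["median"]), iqr=float(d["iqr"]))


def fit_robust_scale(elbow_ages: Sequence[float]) -> RobustScaleParams:
    """Fit median/IQR over the full labelled set (global fit, >= 4 individuals)."""
    x = np.asarray(elbow_ages, dtype=float)
    if x.size < 4:
        raise ValueError("robust scaling requires at least 4 labelled individuals")
    q25, q50, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return RobustScaleParams(median=float(q50), iqr=float(q75 - q25))


def label_individuals(
    series: Sequence[IndividualSeries],
    min_range: float = DEFAULT_MIN_RANGE,
) -> tuple[list[WeaningLabel], RobustScaleParams, list[tuple[str, str]]]:
    """Elbow-label every series and robust-scale the labels globally.

    Individuals whose trajectory yields no elbow (range below threshold) are
    excluded with a logged reason rather than aborting the run.

    Uses raw (unscaled) ages/δ¹⁵N: labels are in chronological years.
    """
    raw: list[tuple[str, float]] = []
    failures: list[tuple[str, str]] = []
    for s in series:
        try:
            raw.append((s.sample_id, estimate_elbow_age(s.ages_raw, s.d15n, min_range)))
        except (NoDeclineError, ValueError) as exc:
            failures.append((s.sample_id, str(exc)))
            logger.warning("could not label %s: %s", s.sample_id, exc)
    if not raw:
        raise NoDeclineError("no individual could be elbow-labelled")
    params = fit_robust_scale([a for _, a in raw])
    labels = [
        WeaningLabel(sample_id=sid, elbow_age=a, scaled_value=float(params.apply(a)))
        for sid, a in raw
    ]
    return labels, params, failures


def labels_to_frame(labels: Sequence[WeaningLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [l.sample_id for l in labels],
            "elbow_age": [l.elbow_age for l in labels],
            "scaled_value": [l.scaled_value for l in labels],
        }
    )
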