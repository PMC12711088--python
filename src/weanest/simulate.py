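"""Synthetic dentine isotope trajectories with known weaning schedules.

The generator is a curve-plus-noise model, not a physiological mixing model:
each individual has a breastmilk fraction S(t) that is 1 before weaning onset,
0 after completion, and declines linearly (or logistically, matched at the
1%/99% points) in between.  Isotope values are ``baseline + enrichment * S(t)``
— reflecting the ~2-3 per-mil trophic-level enrichment of a nursing infant's
δ¹⁵N over the maternal baseline and the ~1 per-mil shift in δ¹³C — plus
Gaussian measurement noise.

Increment ages emulate serial dentine sectioning, which preserves a dietary
record at sub-annual (six months or less) resolution: consecutive increments
are spaced 0.25-0.75 years apart, starting near the onset of the tooth's
formation window and truncated at its end.  Onset and duration draws are
truncated so that completion falls inside the sampled span: a tooth that never
records the post-weaning plateau carries no completion signal, and such
profiles are excluded from compiled training datasets in practice.  Deciduous
teeth may begin before birth (negative ages, in-utero formation).

Every draw is reproducible from a single seed, and the generated CSV is
byte-identical across re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IndividualSeries

#: Formation/sampling windows per tooth type, years (negative = in utero).
TOOTH_WINDOWS: dict[str, tuple[float, float]] = {
    "M1": (0.3, 9.0),
    "dM1": (-0.3, 2.5),
    "dM2": (0.0, 3.5),
}

#: Default tooth mix, matching the composition of the compiled training data.
DEFAULT_TOOTH_MIX: dict[str, int] = {"M1": 227, "dM1": 23, "dM2": 29}

#: Margin (years) kept between weaning completion and the last sampled age.
_WINDOW_MARGIN = 0.15
_MIN_DURATION = 0.5


@dataclass(frozen=True)
class SyntheticParams:
    """Realized generative parameters for one individual."""

    baseline_d15n: float  # per-mil, maternal/post-weaning level
    enrichment_d15n: float  # per-mil trophic enrichment while nursing
    baseline_d13c: float
    enrichment_d13c: float
    onset_age: float  # years
    completion_age: float  # years
    tooth_type: str
    n_increments: int
    noise_sd: float = 0.15  # per-mil
    decline_shape: str = "linear"  # or "logistic"

    def __post_init__(self):
        if self.completion_age <= self.onset_age:
            raise ValueError("completion_age must exceed onset_age")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.decline_shape not in ("linear", "logistic"):
            raise ValueError("decline_shape must be 'linear' or 'logistic'")


@dataclass(frozen=True)
class SyntheticIndividual:
    series: IndividualSeries
    params: SyntheticParams

    @property
    def onset_age(self) -> float:
        return self.params.onset_age

    @property
    def completion_age(self) -> float:
        return self.params.completion_age


def _breastmilk_fraction(t: np.ndarray, params: SyntheticParams) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    a, b = params.onset_age, params.completion_age
    if params.decline_shape == "linear":
        return np.clip((b - t) / (b - a), 0.0, 1.0)
    # Logistic matched to 0.99 at onset and 0.01 at completion, clamped to the
    # exact plateaus outside the transition window.
    mid = 0.5 * (a + b)
    k = 2.0 * np.log(99.0) / (b - a)
    s = 1.0 / (1.0 + np.exp(k * (t - mid)))
    return np.where(t <= a, 1.0, np.where(t >= b, 0.0, s))


def weaning_curve(t, params: SyntheticParams) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (d15N, d13C) at ages ``t`` for the given schedule."""
    s = _breastmilk_fraction(t, params)
    return (
        params.baseline_d15n + params.enrichment_d15n * s,
        params.baseline_d13c + params.enrichment_d13c * s,
    )


def _increment_ages(rng: np.random.Generator, tooth_type: str, n: int) -> np.ndarray:
    """Sub-annual serial-section ages: 0.25-0.75 y spacing inside the window.

    The first section starts just inside the formation window; if the raw span
    overruns the window it is compressed linearly onto it (finer increments in
    the short-forming deciduous teeth).
    """
    ws, we = TOOTH_WINDOWS[tooth_type]
    first = ws + rng.uniform(0.0, 0.2)
    gaps = rng.uniform(0.25, 0.75, size=n - 1)
    ages = first + np.concatenate([[0.0], np.cumsum(gaps)])
    if ages[-1] > we:
        ages = first + (ages - first) * (we - first) / (ages[-1] - first)
    # The penultimate section must be able to sit past a minimal weaning
    # schedule (onset >= 0.3, duration >= 0.5, margin), so the post-weaning
    # plateau is recorded by more than the profile's endpoint.
    min_penult = 0.3 + _MIN_DURATION + _WINDOW_MARGIN
    if ages[-2] < min_penult:
        ages = first + (ages - first) * (min_penult - first) / (ages[-2] - first)
        ages[-1] = min(ages[-1], we)
    return ages


def draw_params(
    rng: np.random.Generator,
    tooth_type: str,
    last_age: float,
    noise_sd: float = 0.15,
    decline_shape: str = "linear",
    n_increments: int = 8,
) -> SyntheticParams:
    """Draw one individual's generative parameters.

    Baselines ~ N(9.5, 1) / N(-19.5, 0.8); enrichments ~ U(2, 3) / U(0.5, 1.2);
    onset ~ U(0.3, 1.5) and duration ~ U(0.5, 2.5), both truncated so that
    completion precedes ``last_age`` (the penultimate sampled section) by a
    small margin: the post-weaning plateau must be recorded by at least the
    final two increments for the profile to carry a completion signal.
    """
    onset_hi = max(0.35, min(1.5, last_age - _WINDOW_MARGIN - _MIN_DURATION))
    onset = rng.uniform(0.3, onset_hi)
    dur_hi = max(_MIN_DURATION + 0.05, min(2.5, last_age - _WINDOW_MARGIN - onset))
    dur = rng.uniform(_MIN_DURATION, dur_hi)
    return SyntheticParams(
        baseline_d15n=rng.normal(9.5, 1.0),
        enrichment_d15n=rng.uniform(2.0, 3.0),
        baseline_d13c=rng.normal(-19.5, 0.8),
        enrichment_d13c=rng.uniform(0.5, 1.2),
        onset_age=onset,
        completion_age=onset + dur,
        tooth_type=tooth_type,
        n_increments=n_increments,
        noise_sd=noise_sd,
        decline_shape=decline_shape,
    )


def simulate_individual(
    sample_id: str,
    tooth_type: str,
    seed_or_rng: int | np.random.Generator,
    noise_sd: float = 0.15,
    decline_shape: str = "linear",
    params: SyntheticParams | None = None,
) -> SyntheticIndividual:
    """Simulate one individual's series; truth is recorded alongside."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    if params is None:
        n = int(rng.integers(4, 13))
        ages = _increment_ages(rng, tooth_type, n)
        params = draw_params(rng, tooth_type, last_age=float(ages[-2]),
                             noise_sd=noise_sd, decline_shape=decline_shape,
                             n_increments=n)
    else:
        ages = _increment_ages(rng, params.tooth_type, params.n_increments)
    d15n, d13c = weaning_curve(ages, params)
    if params.noise_sd > 0:
        d15n = d15n + rng.normal(0.0, params.noise_sd, size=ages.size)
        d13c = d13c + rng.normal(0.0, params.noise_sd, size=ages.size)
    series = IndividualSeries(
        sample_id=sample_id, tooth_type=params.tooth_type,
        ages=ages, d15n=d15n, d13c=d13c,
    )
    return SyntheticIndividual(series=series, params=params)


def _tooth_counts(n: int, tooth_mix: Mapping[str, int]) -> dict[str, int]:
    """Largest-remainder apportionment of ``n`` individuals to the mix."""
    total = sum(tooth_mix.values())
    exact = {k: n * v / total for k, v in tooth_mix.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(counts.values())
    for k in sorted(exact, key=lambda k: exact[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def simulate_dataset(
    n: int = 279,
    tooth_mix: Mapping[str, int] | None = None,
    seed: int = 0,
    noise_sd: float = 0.15,
    decline_shape: str = "linear",
) -> list[SyntheticIndividual]:
    """Simulate ``n`` individuals with the given tooth mix (default 227:23:29)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    tooth_mix = dict(tooth_mix or DEFAULT_TOOTH_MIX)
    counts = _tooth_counts(n, tooth_mix)
    rng = np.random.default_rng(seed)
    out: list[SyntheticIndividual] = []
    i = 0
    for tooth in DEFAULT_TOOTH_MIX:  # fixed tooth order for reproducibility
        for _ in range(counts.get(tooth, 0)):
            i += 1
            out.append(
                simulate_individual(
                    f"SIM_{i:04d}", tooth, rng,
                    noise_sd=noise_sd, decline_shape=decline_shape,
                )
            )
    return out


def dataset_to_frame(individuals: Sequence[SyntheticIndividual]) -> pd.DataFrame:
    return pd.concat([ind.series.to_frame() for ind in individuals], ignore_index=True)


def truth_frame(individuals: Sequence[SyntheticIndividual]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [ind.series.sample_id for ind in individuals],
            "onset_age": [ind.onset_age for ind in individuals],
            "completion_age": [ind.completion_age for ind in individuals],
        }
    )


def write_dataset_csv(
    individuals: Sequence[SyntheticIndividual],
    data_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write the long-format CSV (and optionally the truth CSV), byte-stable."""
    dataset_to_frame(individuals).to_csv(data_path, index=False, float_format="%.6f")
    if truth_path is not None:
        truth_frame(individuals).to_csv(truth_path, index=False, float_format="%.6f")
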