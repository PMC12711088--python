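"""Padded batch assembly: zero padding, validity masks, tooth-type one-hot channels.

Feature matrices of unequal length are right-padded with zeros to a common
maximum length ``t_max`` and a boolean mask marks the real timesteps; the
network's masking layer excludes pads from computation.  Tooth type is one-hot
encoded (M1 = [1,0,0], dM1 = [0,1,0], dM2 = [0,0,1]) and repeated across all
valid timesteps, giving 12 channels in total.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .features import FEATURE_COLUMNS, FeatureMatrix

TOOTH_ONE_HOT: dict[str, tuple[int, int, int]] = {
    "M1": (1, 0, 0),
    "dM1": (0, 1, 0),
    "dM2": (0, 0, 1),
}

CHANNEL_COLUMNS = FEATURE_COLUMNS + ("tooth_M1", "tooth_dM1", "tooth_dM2")
N_CHANNELS = len(CHANNEL_COLUMNS)  # 12


def one_hot_tooth(tooth_type: str) -> np.ndarray:
    """Exact one-hot mapping for the three tooth types."""
    try:
        return np.array(TOOTH_ONE_HOT[tooth_type], dtype=float)
    except KeyError:
        raise ValueError(
            f"unknown tooth_type {tooth_type!r}; expected one of {tuple(TOOTH_ONE_HOT)}"
        ) from None


@dataclass
class PaddedBatch:
    """N x t_max x 12 zero-padded tensor with validity mask.

    Invariants: entries at masked-out positions are exactly 0; the one-hot
    channels sum to 1 at every valid timestep and 0 at pads.
    """

    tensor: np.ndarray  # (N, t_max, 12)
    mask: np.ndarray  # (N, t_max) bool
    sample_ids: list[str]
    labels: np.ndarray | None = None  # (N,) robust-scaled, when supervised
    tooth_types: list[str] | None = None
    max_ages: np.ndarray | None = None  # (N,) years, for residual diagnostics

    def __post_init__(self):
        n, t, c = self.tensor.shape
        assert c == N_CHANNELS and self.mask.shape == (n, t)
        assert np.all(self.tensor[~self.mask] == 0.0), "padded positions must be zero"

    @property
    def n(self) -> int:
        return self.tensor.shape[0]

    @property
    def t_max(self) -> int:
        return self.tensor.shape[1]

    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    def subset(self, idx: Sequence[int]) -> "PaddedBatch":
        idx = np.asarray(idx, dtype=int)
        return PaddedBatch(
            tensor=self.tensor[idx],
            mask=self.mask[idx],
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            tooth_types=None if self.tooth_types is None else [self.tooth_types[i] for i in idx],
            max_ages=None if self.max_ages is None else self.max_ages[idx],
        )


def pad_and_mask(
    matrices: Sequence[FeatureMatrix],
    t_max: int | None = None,
    labels: Mapping[str, float] | None = None,
) -> PaddedBatch:
    """Right-pad feature matrices with zeros to ``t_max`` and attach masks.

    ``t_max`` defaults to the longest matrix in the batch.  A matrix longer
    than ``t_max`` raises (no silent truncation).  ``labels`` maps sample_id to
    the robust-scaled supervision value.
    """
    if not matrices:
        raise ValueError("empty batch")
    lengths = [len(m) for m in matrices]
    if t_max is None:
        t_max = max(lengths)
    too_long = [m.sample_id for m in matrices if len(m) > t_max]
    if too_long:
        raise ValueError(
            f"sequences longer than t_max={t_max}: {too_long}; retrain with a larger "
            "maximum length instead of truncating"
        )
    n = len(matrices)
    tensor = np.zeros((n, t_max, N_CHANNELS))
    mask = np.zeros((n, t_max), dtype=bool)
    for i, m in enumerate(matrices):
        t = len(m)
        tensor[i, :t, : len(FEATURE_COLUMNS)] = m.channels
        tensor[i, :t, len(FEATURE_COLUMNS) :] = one_hot_tooth(m.tooth_type)
        mask[i, :t] = True
    batch_labels = None
    if labels is not None:
        batch_labels = np.array([labels[m.sample_id] for m in matrices], dtype=float)
    return PaddedBatch(
        tensor=tensor,
        mask=mask,
        sample_ids=[m.sample_id for m in matrices],
        labels=batch_labels,
        tooth_types=[m.tooth_type for m in matrices],
        max_ages=np.array([m.max_age for m in matrices]),
    )


def split_individuals(
    sample_ids: Sequence[str], train_frac: float = 0.8, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Deterministic individual-level train/test split.

    All increments of one individual land on one side.  Train size is
    ``floor(train_frac * N)``; the remainder goes to test.
    """
    ids = list(sample_ids)
    if len(ids) < 5:
        raise ValueError("individual-level split requires at least 5 individuals")
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(train_frac * len(ids)))
    train = [ids[i] for i in sorted(perm[:n_train])]
    test = [ids[i] for i in sorted(perm[n_train:])]
    return train, test
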