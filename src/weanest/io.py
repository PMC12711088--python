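"""Reading, validation, filtering and z-score normalization of serial-isotope tables.

The expected input is a long-format CSV with one row per dentine increment and
columns ``sample_id``, ``age_at_increment`` (years), ``d15N`` (per-mil vs AIR),
``d13C`` (per-mil vs VPDB) and ``tooth_type`` (one of M1, dM1, dM2).  Rows are
grouped per individual and sorted by age; rows missing the age or missing both
isotope values are dropped (with a logged count).  A row missing only one of the
two isotopes is kept, the absent value carried as NaN — downstream feature
engineering treats it as a gap rather than imputing it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TOOTH_TYPES = ("M1", "dM1", "dM2")

REQUIRED_COLUMNS = ("sample_id", "age_at_increment", "d15N", "d13C", "tooth_type")

#: Sanity bounds for a single increment (configurable through ``load_dataset``).
DEFAULT_BOUNDS = {
    "age_at_increment": (-1.0, 25.0),
    "d15N": (-5.0, 25.0),
    "d13C": (-35.0, 0.0),
}


class ValidationError(ValueError):
    """Structured validation failure (missing column, unknown tooth type, ...)."""


@dataclass(frozen=True)
class IndividualSeries:
    """One individual's age-ordered increment measurements for a single tooth.

    ``ages`` is always in years and strictly increasing.  ``d15n``/``d13c`` may
    contain NaN where a single isotope was not measured.  ``ages_raw`` preserves
    the chronological ages (years) through z-scaling so that labels and metadata
    remain interpretable after normalization.
    """

    sample_id: str
    tooth_type: str
    ages: np.ndarray
    d15n: np.ndarray
    d13c: np.ndarray
    ages_raw: np.ndarray | None = None

    def __post_init__(self):
        if self.tooth_type not in TOOTH_TYPES:
            raise ValidationError(
                f"unknown tooth_type {self.tooth_type!r} for sample {self.sample_id!r}; "
                f"expected one of {TOOTH_TYPES}"
            )
        for name in ("ages", "d15n", "d13c"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.ages) == len(self.d15n) == len(self.d13c)):
            raise ValidationError(f"length mismatch in series {self.sample_id!r}")
        if np.any(np.diff(self.ages) <= 0):
            raise ValidationError(f"ages not strictly increasing in series {self.sample_id!r}")
        if self.ages_raw is None:
            object.__setattr__(self, "ages_raw", self.ages.copy())
        else:
            object.__setattr__(self, "ages_raw", np.asarray(self.ages_raw, dtype=float))

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def max_age(self) -> float:
        """Maximum age-at-increment in years (uses raw ages even after scaling)."""
        return float(self.ages_raw[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "age_at_increment": self.ages,
                "d15N": self.d15n,
                "d13C": self.d13c,
                "tooth_type": self.tooth_type,
            }
        )


@dataclass
class LoadReport:
    """Bookkeeping from :func:`load_dataset`; conserves row counts."""

    n_rows_in: int = 0
    n_rows_kept: int = 0
    n_dropped_missing_age: int = 0
    n_dropped_missing_both: int = 0
    n_dropped_out_of_bounds: int = 0
    n_duplicate_ages_merged: int = 0
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_rows_dropped(self) -> int:
        return (
            self.n_dropped_missing_age
            + self.n_dropped_missing_both
            + self.n_dropped_out_of_bounds
        )


def _resolve_columns(df: pd.DataFrame, aliases: Mapping[str, str] | None) -> pd.DataFrame:
    """Rename alias columns to canonical names and check all required ones exist."""
    if aliases:
        df = df.rename(columns={v: k for k, v in aliases.items()})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} missing from input")
    return df


def load_dataset(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
) -> tuple[list[IndividualSeries], LoadReport]:
    """Read a long-format increment CSV into per-individual series.

    Parameters
    ----------
    path:
        CSV file (RFC 4180, UTF-8, '.' decimal separator).
    aliases:
        Optional mapping ``canonical name -> column name in the file`` for
        inputs using e.g. ``age_at_formation`` instead of ``age_at_increment``.
    bounds:
        Per-variable ``(lo, hi)`` sanity bounds; defaults to
        :data:`DEFAULT_BOUNDS`.  Out-of-bounds rows are dropped with a warning.

    Returns
    -------
    (series, report):
        Series grouped by ``sample_id`` and sorted by age, plus a
        :class:`LoadReport` with drop counts (rows in = rows kept + dropped).
    """
    df = pd.read_csv(path)
    df = _resolve_columns(df, aliases)
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    report = LoadReport(n_rows_in=len(df))

    for col in ("age_at_increment", "d15N", "d13C"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["sample_id"] = df["sample_id"].astype(str)
    df["tooth_type"] = df["tooth_type"].astype(str).str.strip()

    bad_tooth = sorted(set(df.loc[~df["tooth_type"].isin(TOOTH_TYPES), "sample_id"]))
    if bad_tooth:
        raise ValidationError(
            f"unknown tooth_type for sample_ids: {', '.join(bad_tooth)}; "
            f"expected one of {TOOTH_TYPES}"
        )

    missing_age = df["age_at_increment"].isna()
    report.n_dropped_missing_age = int(missing_age.sum())
    df = df[~missing_age]

    missing_both = df["d15N"].isna() & df["d13C"].isna()
    report.n_dropped_missing_both = int(missing_both.sum())
    df = df[~missing_both]

    in_bounds = pd.Series(True, index=df.index)
    for col, (lo, hi) in bounds.items():
        vals = df[col]
        in_bounds &= vals.isna() | ((vals >= lo) & (vals <= hi))
    report.n_dropped_out_of_bounds = int((~in_bounds).sum())
    df = df[in_bounds]

    if report.n_rows_dropped:
        logger.warning(
            "load_dataset: dropped %d rows (%d missing age, %d missing both isotopes, "
            "%d out of bounds)",
            report.n_rows_dropped,
            report.n_dropped_missing_age,
            report.n_dropped_missing_both,
            report.n_dropped_out_of_bounds,
        )

    series: list[IndividualSeries] = []
    for sample_id, grp in df.groupby("sample_id", sort=True):
        teeth = grp["tooth_type"].unique()
        if len(teeth) > 1:
            raise ValidationError(
                f"sample {sample_id!r} has conflicting tooth types: {sorted(teeth)}"
            )
        grp = grp.sort_values("age_at_increment", kind="stable")
        # Duplicate ages within an individual: average the isotope values so the
        # sequence model sees one measurement per timestep.
        if grp["age_at_increment"].duplicated().any():
            n_before = len(grp)
            grp = (
                grp.groupby("age_at_increment", as_index=False)
                .agg({"d15N": "mean", "d13C": "mean"})
                .sort_values("age_at_increment", kind="stable")
            )
            merged = n_before - len(grp)
            report.n_duplicate_ages_merged += merged
            logger.info("sample %s: averaged %d duplicate-age increments", sample_id, merged)
        series.append(
            IndividualSeries(
                sample_id=str(sample_id),
                tooth_type=str(teeth[0]),
                ages=grp["age_at_increment"].to_numpy(),
                d15n=grp["d15N"].to_numpy(),
                d13c=grp["d13C"].to_numpy(),
            )
        )

    report.n_rows_kept = int(sum(len(s) for s in series)) + report.n_duplicate_ages_merged
    assert report.n_rows_in == report.n_rows_kept + report.n_rows_dropped
    return series, report


def filter_individuals(
    series: Iterable[IndividualSeries], min_len: int = 3
) -> tuple[list[IndividualSeries], list[tuple[str, str]]]:
    """Keep individuals with at least ``min_len`` increments.

    Returns the retained series and an exclusion log of ``(sample_id, reason)``.
    Raises :class:`ValidationError` if nothing survives.
    """
    kept: list[IndividualSeries] = []
    excluded: list[tuple[str, str]] = []
    for s in series:
        if len(s) >= min_len:
            kept.append(s)
        else:
            excluded.append((s.sample_id, f"fewer than {min_len} measurements ({len(s)})"))
    if not kept:
        raise ValidationError("no individuals survive filtering")
    for sample_id, reason in excluded:
        logger.info("excluded %s: %s", sample_id, reason)
    return kept, excluded


_ZVARS = ("d15N", "d13C", "age_at_increment")


@dataclass(frozen=True)
class ZScaleParams:
    """Per-variable mean/sd for z-scoring d15N, d13C and age (population sd)."""

    mean: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self):
        for var in _ZVARS:
            if self.sd[var] <= 0:
                raise ValidationError(f"variable {var!r} is constant (sd = 0); cannot z-scale")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"mean": self.mean, "sd": self.sd}, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ZScaleParams":
        d = json.loads(Path(path).read_text())
        return cls(mean={k: float(v) for k, v in d["mean"].items()},
                   sd={k: float(v) for k, v in d["sd"].items()})


def fit_zscale(train_series: Sequence[IndividualSeries]) -> ZScaleParams:
    """Fit z-score parameters on the training individuals only (NaN-aware).

    Uses the population convention (divide by n), matching the usual
    StandardScaler semantics.
    """
    pooled = {
        "d15N": np.concatenate([s.d15n for s in train_series]),
        "d13C": np.concatenate([s.d13c for s in train_series]),
        "age_at_increment": np.concatenate([s.ages for s in train_series]),
    }
    mean, sd = {}, {}
    for var, vals in pooled.items():
        mean[var] = float(np.nanmean(vals))
        sd[var] = float(np.nanstd(vals))  # ddof=0
    return ZScaleParams(mean=mean, sd=sd)


def apply_zscale(
    series: Sequence[IndividualSeries], params: ZScaleParams
) -> list[IndividualSeries]:
    """Return new series with d15N/d13C/age z-scored; raw ages kept in ``ages_raw``."""
    out = []
    for s in series:
        out.append(
            replace(
                s,
                ages=(s.ages - params.mean["age_at_increment"]) / params.sd["age_at_increment"],
                d15n=(s.d15n - params.mean["d15N"]) / params.sd["d15N"],
                d13c=(s.d13c - params.mean["d13C"]) / params.sd["d13C"],
                ages_raw=s.ages_raw.copy(),
            )
        )
    return out


def invert_zscale(
    series: Sequence[IndividualSeries], params: ZScaleParams
) -> list[IndividualSeries]:
    """Inverse of :func:`apply_zscale` (round-trips within 1e-9)."""
    out = []
    for s in series:
        out.append(
            replace(
                s,
                ages=s.ages * params.sd["age_at_increment"] + params.mean["age_at_increment"],
                d15n=s.d15n * params.sd["d15N"] + params.mean["d15N"],
                d13c=s.d13c * params.sd["d13C"] + params.mean["d13C"],
                ages_raw=s.ages_raw.copy(),
            )
        )
    return out


def write_series_csv(series: Sequence[IndividualSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(path, index=False)
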