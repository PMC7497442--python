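"""Actigraphy feature extraction: per-day 24-hour biometric profiles.

Raw wrist-actigraphy recordings (one activity count per minute) are turned
into per-day feature vectors of 24 hourly mean activity levels (``h1``
covers 00:00-00:59, ..., ``h24`` covers 23:00-23:59).  Hours with no
recorded minutes receive the sentinel value -1, the first calendar day of
each recording is discarded (recordings typically start mid-day), and the
resulting corpus is min-max normalized per feature into [0, 1].  These
normalized profiles are the behavioural signatures a user-identification
model is trained on, and the search space the impersonation attack
operates in.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

N_HOURS = 24
MISSING = -1.0

__all__ = [
    "MISSING",
    "N_HOURS",
    "DailyProfile",
    "FeatureMatrix",
    "NormalizationStats",
    "UserRecording",
    "extract_daily_profiles",
    "normalize",
    "read_actigraphy_csv",
    "read_feature_table",
    "user_correlation_matrix",
    "write_actigraphy_csv",
    "write_feature_table",
]


class FormatError(ValueError):
    """Raised for malformed actigraphy or feature-table files."""


@dataclass
class UserRecording:
    """One user's minute-resolution activity-count time series.

    ``samples`` holds columns ``timestamp`` (datetime64), ``date`` (the
    calendar date of each sample) and ``activity`` (non-negative int),
    sorted by strictly increasing timestamp.
    """

    user_id: str
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        ts = self.samples["timestamp"]
        if len(ts) and not ts.is_monotonic_increasing:
            raise FormatError(f"{self.user_id}: timestamps are not increasing")
        if len(ts) > 1 and ts.duplicated().any():
            raise FormatError(f"{self.user_id}: duplicate timestamps")
        if (self.samples["activity"] < 0).any():
            row = int(np.flatnonzero(self.samples["activity"] < 0)[0])
            raise FormatError(f"{self.user_id}: negative activity count at row {row}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class DailyProfile:
    """Hourly mean activity counts for one (user, calendar day)."""

    user_id: str
    date: object  # datetime.date
    hours: np.ndarray  # 24 values, each >= 0 or exactly -1

    def __post_init__(self) -> None:
        self.hours = np.asarray(self.hours, dtype=float)
        if self.hours.shape != (N_HOURS,):
            raise ValueError("a daily profile has exactly 24 hourly values")
        bad = (self.hours < 0) & (self.hours != MISSING)
        if bad.any():
            raise ValueError("hourly means must be >= 0 or the -1 sentinel")


@dataclass
class NormalizationStats:
    """Per-feature min/max used for [0,1] scaling; reusable on new data."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != (N_HOURS,) or self.maximum.shape != (N_HOURS,):
            raise ValueError("stats must cover exactly 24 features")
        if (self.maximum < self.minimum).any():
            raise ValueError("per-feature max must be >= min")

    def transform(self, raw: np.ndarray) -> np.ndarray:
        """Scale raw hourly values into [0,1]; degenerate features map to 0.

        Values outside the fitted range (possible when projecting new data
        through training-corpus stats) are clipped into [0,1].
        """
        raw = np.asarray(raw, dtype=float)
        span = self.maximum - self.minimum
        safe = np.where(span > 0, span, 1.0)
        scaled = (raw - self.minimum) / safe
        scaled = np.where(span > 0, scaled, 0.0)
        return np.clip(scaled, 0.0, 1.0)

    def to_dict(self) -> dict:
        return {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(np.asarray(d["minimum"]), np.asarray(d["maximum"]))


@dataclass
class FeatureMatrix:
    """Normalized per-day biometric profiles with user labels.

    ``X`` is an (n_rows, 24) float array with every value in [0, 1]; row i
    belongs to ``user_ids[i]`` on ``dates[i]``.  ``stats`` retains the
    min-max used so new raw profiles can be projected into the same space.
    """

    user_ids: np.ndarray
    dates: np.ndarray
    X: np.ndarray
    stats: NormalizationStats = field(repr=False)

    def __post_init__(self) -> None:
        self.user_ids = np.asarray(self.user_ids, dtype=object)
        self.dates = np.asarray(self.dates, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != N_HOURS:
            raise ValueError("feature matrix must be (n, 24)")
        if len(self.user_ids) != len(self.X) or len(self.dates) != len(self.X):
            raise ValueError("labels and rows must align")
        if (self.X < 0).any() or (self.X > 1).any():
            raise ValueError("normalized features must lie in [0, 1]")

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def users(self) -> list[str]:
        """Distinct user ids in sorted order."""
        return sorted(set(self.user_ids))

    def rows_for(self, user_id: str) -> np.ndarray:
        return self.X[self.user_ids == user_id]


def read_actigraphy_csv(path: str | Path) -> UserRecording:
    """Read one user's recording from a ``timestamp,date,activity`` CSV.

    The user id is the file name stem (e.g. ``control10.csv`` ->
    ``control10``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"timestamp", "date", "activity"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise FormatError(f"{path.name}: missing columns {sorted(missing_cols)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
        df["activity"] = pd.to_numeric(df["activity"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: malformed value ({exc})") from exc
    bad = df.index[df["activity"] < 0]
    if len(bad):
        raise FormatError(f"{path.name}: negative activity count at row {bad[0]}")
    df["date"] = df["timestamp"].dt.date
    return UserRecording(user_id=path.stem, samples=df[["timestamp", "date", "activity"]])


def write_actigraphy_csv(recording: UserRecording, directory: str | Path) -> Path:
    """Write a recording in the same per-user CSV dialect; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / f"{recording.user_id}.csv"
    df = recording.samples.copy()
    df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%d %H:%M:%S")
    df["date"] = df["date"].astype(str)
    df.to_csv(out, index=False)
    return out


def extract_daily_profiles(recording: UserRecording) -> list[DailyProfile]:
    """Compute per-day hourly-mean profiles, dropping the first calendar day.

    Each hour bin averages only the minutes actually recorded in it; an
    hour with no samples gets the -1 sentinel.  First-day exclusion is
    unconditional.  A recording spanning fewer than two calendar days
    yields an empty list (with a warning).
    """
    df = recording.samples
    if df.empty:
        raise ValueError(f"{recording.user_id}: empty recording")
    days = sorted(df["date"].unique())
    if len(days) < 2:
        warnings.warn(
            f"{recording.user_id}: recording spans a single day; "
            "no usable profiles after first-day exclusion",
            stacklevel=2,
        )
        return []
    hours = df["timestamp"].dt.hour
    profiles: list[DailyProfile] = []
    for day in days[1:]:
        mask = df["date"] == day
        means = df.loc[mask, "activity"].groupby(hours[mask]).mean()
        h = np.full(N_HOURS, MISSING)
        h[means.index.to_numpy()] = means.to_numpy()
        profiles.append(DailyProfile(recording.user_id, day, h))
    return profiles


def normalize(
    profiles: Sequence[DailyProfile],
    stats: NormalizationStats | None = None,
) -> FeatureMatrix:
    """Min-max scale profiles into [0,1] per feature.

    The -1 sentinel participates in the scaling as an ordinary value, so
    "hour missing" becomes the minimum of any feature that ever has a
    missing hour.  When ``stats`` is given (e.g. fitted on a training
    corpus) it is applied instead of refitting; values outside the fitted
    range are clipped.
    """
    if not profiles:
        raise ValueError("need at least one profile to normalize")
    raw = np.stack([p.hours for p in profiles])
    if stats is None:
        stats = NormalizationStats(raw.min(axis=0), raw.max(axis=0))
    return FeatureMatrix(
        user_ids=np.array([p.user_id for p in profiles], dtype=object),
        dates=np.array([p.date for p in profiles], dtype=object),
        X=stats.transform(raw),
        stats=stats,
    )


def user_correlation_matrix(matrix: FeatureMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation of users' mean 24-hour profiles.

    Each user is summarized by the mean of their daily feature vectors;
    entry (i, j) is the correlation between those two 24-vectors.  A user
    whose mean profile is constant has undefined correlations, reported
    as NaN.
    """
    users = matrix.users
    if len(users) < 2:
        raise ValueError("need at least two users")
    means = pd.DataFrame(
        {u: matrix.rows_for(u).mean(axis=0) for u in users}
    )
    return means.corr(method="pearson")


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> Path:
    """Write the feature table as CSV with a JSON stats sidecar."""
    path = Path(path)
    cols = {f"h{i + 1}": matrix.X[:, i] for i in range(N_HOURS)}
    df = pd.DataFrame({"user_id": matrix.user_ids, "date": matrix.dates, **cols})
    df.to_csv(path, index=False, float_format="%.10g")
    path.with_suffix(".stats.json").write_text(json.dumps(matrix.stats.to_dict()))
    return path


def read_feature_table(path: str | Path) -> FeatureMatrix:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["user_id", "date"] + [f"h{i + 1}" for i in range(N_HOURS)]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path.name}: expected columns {expected[:3]}...h24, got {list(df.columns)[:4]}..."
        )
    stats_path = path.with_suffix(".stats.json")
    if not stats_path.exists():
        raise FormatError(f"missing stats sidecar {stats_path.name}")
    stats = NormalizationStats.from_dict(json.loads(stats_path.read_text()))
    return FeatureMatrix(
        user_ids=df["user_id"].to_numpy(dtype=object),
        dates=df["date"].to_numpy(dtype=object),
        X=df[expected[2:]].to_numpy(dtype=float),
        stats=stats,
    )
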