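"""Multivariate dynamic time warping over paired RT/ET series.

The distance between two cows is dependent (single-alignment) multivariate
DTW: one warping path is shared by the two behaviour dimensions, the local
cost of matching hour i of cow A to hour j of cow B is the squared Euclidean
distance between the (RT, ET) 2-vectors, and the reported distance is the
square root of the accumulated cost at the end of the optimal path.  With an
unbounded window this is the classical O(n*m) dynamic programme; a
Sakoe-Chiba band (``window_radius``) is available for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BehaviorSeries",
    "DTWConfig",
    "DistanceMatrix",
    "UnusableCowError",
    "DTWWindowError",
    "preprocess_series",
    "dtw_distance",
    "accumulated_cost_matrix",
    "pairwise_distances",
    "DTWDistance",
]

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


class UnusableCowError(ValueError):
    """A cow's series is too short/gappy to enter the distance matrix."""

    def __init__(self, cow_id: str, message: str):
        self.cow_id = cow_id
        super().__init__(f"cow {cow_id!r}: {message}")


class DTWWindowError(ValueError):
    """The Sakoe-Chiba radius cannot cover the series length difference."""


@dataclass
class BehaviorSeries:
    """One cow's ordered hourly (RT, ET) observations.

    ``values`` is an (n, 2) float array in seconds per hour (unless the
    series has been z-normalised); ``timestamps`` are strictly increasing.
    """

    cow_id: str
    timestamps: np.ndarray
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.timestamps = np.asarray(self.timestamps)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be an (n, 2) array of (rt_s, et_s)")
        if len(self.values) < 2:
            raise UnusableCowError(self.cow_id, "series shorter than 2 hours")
        if len(self.timestamps) != len(self.values):
            raise ValueError("timestamps and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if len(self.timestamps) > 1 and not np.all(
                self.timestamps[1:] > self.timestamps[:-1]):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DTWConfig:
    """``window_radius=None`` means an unbounded warping window;
    ``normalize=True`` z-scores each behaviour dimension per cow before
    alignment.  The local cost is fixed to squared Euclidean distance."""

    window_radius: int | None = None
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.window_radius is not None and self.window_radius < 0:
            raise ValueError("window_radius must be >= 0 or None")


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise DTW distances."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix must be finite")
        if np.any(self.values < 0):
            raise ValueError("distances must be nonnegative")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        # %.12g keeps 12 significant digits, enough for lossless round-trips
        df.to_csv(path, float_format="%.12g", index_label="cow_id")

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        values = df.to_numpy(dtype=np.float64)
        values = 0.5 * (values + values.T)  # undo last-digit rounding asymmetry
        np.fill_diagonal(values, 0.0)
        return cls(tuple(df.index.astype(str)), values)


@njit(cache=True)
def _dtw_table(x, y, radius):  # pragma: no cover - exercised via wrappers
    n = x.shape[0]
    m = y.shape[0]
    d = x.shape[1]
    acc = np.full((n, m), np.inf)
    for i in range(n):
        if radius < 0:
            lo, hi = 0, m
        else:
            lo = i - radius
            if lo < 0:
                lo = 0
            hi = i + radius + 1
            if hi > m:
                hi = m
        for j in range(lo, hi):
            c = 0.0
            for k in range(d):
                dv = x[i, k] - y[j, k]
                c += dv * dv
            if i == 0 and j == 0:
                acc[0, 0] = c
            else:
                best = np.inf
                if i > 0 and acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if j > 0 and acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                if i > 0 and j > 0 and acc[i - 1, j - 1] < best:
                    best = acc[i - 1, j - 1]
                acc[i, j] = c + best
    return acc


def _znorm(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (values - mu) / sd


def _prepare(series: BehaviorSeries, config: DTWConfig) -> np.ndarray:
    v = series.values
    if config.normalize and not series.normalized:
        v = _znorm(v)
    return np.ascontiguousarray(v)


def _check_pair(a: BehaviorSeries, b: BehaviorSeries, config: DTWConfig) -> None:
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cannot align an empty series")
    if a.values.shape[1] != b.values.shape[1]:
        raise ValueError("series dimensionality differs")
    if config.window_radius is not None:
        if config.window_radius < abs(len(a) - len(b)):
            raise DTWWindowError(
                f"window_radius={config.window_radius} cannot span the "
                f"length difference |{len(a)} - {len(b)}|")


def accumulated_cost_matrix(a: BehaviorSeries, b: BehaviorSeries,
                            config: DTWConfig | None = None) -> np.ndarray:
    """Full |a| x |b| accumulated-cost table; the square root of its terminal
    cell is the DTW distance."""
    config = config or DTWConfig()
    _check_pair(a, b, config)
    radius = -1 if config.window_radius is None else int(config.window_radius)
    return _dtw_table(_prepare(a, config), _prepare(b, config), radius)


def dtw_distance(a: BehaviorSeries, b: BehaviorSeries,
                 config: DTWConfig | None = None) -> float:
    """Dependent multivariate DTW distance between two cows' (RT, ET) series."""
    acc = accumulated_cost_matrix(a, b, config)
    return float(np.sqrt(acc[-1, -1]))


def pairwise_distances(series: list[BehaviorSeries],
                       config: DTWConfig | None = None) -> DistanceMatrix:
    """All-pairs DTW distances; each unordered pair is computed once."""
    config = config or DTWConfig()
    if len(series) < 2:
        raise ValueError("need at least 2 series")
    ids = [s.cow_id for s in series]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cow ids in series list")
    prepared = [_prepare(s, config) for s in series]
    radius = -1 if config.window_radius is None else int(config.window_radius)
    n = len(series)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _check_pair(series[i], series[j], config)
            acc = _dtw_table(prepared[i], prepared[j], radius)
            out[i, j] = out[j, i] = np.sqrt(acc[-1, -1])
    return DistanceMatrix(tuple(ids), out)


def preprocess_series(rows: pd.DataFrame, max_gap_hours: int = 3,
                      normalize: bool = False,
                      cow_id: str | None = None) -> BehaviorSeries:
    """Turn one cow's raw hourly rows into a clean :class:`BehaviorSeries`.

    Gaps of at most ``max_gap_hours`` consecutive missing hours are filled by
    linear interpolation per dimension; any day touched by a longer gap is
    dropped whole.  The multi-day record is kept as one concatenated hourly
    sequence.
    """
    if cow_id is None:
        ids = rows["cow_id"].unique()
        if len(ids) != 1:
            raise ValueError("rows must belong to a single cow")
        cow_id = str(ids[0])
    if len(rows) == 0:
        raise UnusableCowError(cow_id, "no sensor rows")

    ts = pd.to_datetime(rows["date"]) + pd.to_timedelta(rows["hour"], unit="h")
    df = pd.DataFrame({"rt_s": rows["rt_s"].to_numpy(float),
                       "et_s": rows["et_s"].to_numpy(float)},
                      index=ts).sort_index()
    df = df[~df.index.duplicated(keep="first")]
    full = df.reindex(pd.date_range(df.index[0], df.index[-1], freq="h"))

    missing = full["rt_s"].isna() | full["et_s"].isna()
    if missing.any():
        # Label runs of consecutive missing hours, measure each run's length.
        run_id = (missing != missing.shift()).cumsum()
        run_len = missing.groupby(run_id).transform("sum")
        long_gap = missing & (run_len > max_gap_hours)
        bad_dates = set(full.index[long_gap].normalize())
        keep = ~full.index.normalize().isin(bad_dates)
        full = full[keep]
        full = full.interpolate(method="linear", limit_area="inside")
        full = full.dropna()

    values = full[["rt_s", "et_s"]].to_numpy(float)
    if len(values) < 2:
        raise UnusableCowError(cow_id, "fewer than 2 usable hours after gap filtering")
    values = np.clip(values, 0.0, 3600.0)
    normalized = False
    if normalize:
        values = _znorm(values)
        normalized = True
    return BehaviorSeries(cow_id, full.index.to_numpy(), values,
                          normalized=normalized)


class DTWDistance:
    """sklearn-style transformer computing the pairwise DTW distance matrix.

    ``fit_transform(X)`` accepts a list of :class:`BehaviorSeries` (or an
    (n_series, n_time, 2) array) and returns the (n, n) distance matrix; the
    labelled :class:`DistanceMatrix` is stored as ``distance_matrix_``.
    """

    def __init__(self, window_radius: int | None = None, normalize: bool = False):
        self.window_radius = window_radius
        self.normalize = normalize

    def get_params(self, deep: bool = True) -> dict:
        return {"window_radius": self.window_radius, "normalize": self.normalize}

    def set_params(self, **params) -> "DTWDistance":
        for k, v in params.items():
            if k not in ("window_radius", "normalize"):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _as_series(self, X) -> list[BehaviorSeries]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            n = X.shape[0]
            ts = np.arange(X.shape[1])
            return [BehaviorSeries(f"series_{i}", ts, X[i]) for i in range(n)]
        return list(X)

    def fit(self, X, y=None) -> "DTWDistance":
        config = DTWConfig(self.window_radius, self.normalize)
        self.distance_matrix_ = pairwise_distances(self._as_series(X), config)
        return self

    def transform(self, X=None) -> np.ndarray:
        if not hasattr(self, "distance_matrix_"):
            raise RuntimeError("DTWDistance is not fitted")
        if X is not None:
            warnings.warn("DTWDistance.transform returns the fitted pairwise "
                          "matrix; out-of-sample series are not supported")
        return self.distance_matrix_.values

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform()
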