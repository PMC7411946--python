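"""Smoothing of raw 5 Hz RSS streams and folding into observation windows.

Raw advertisements arrive at a nominal 0.2 s period per tag.  Because a cow is
stationary most of the time, smoothing aims to suppress second-scale RSS
fluctuations: a centered moving mean or median over a time window, or a
constant-velocity Kalman filter on the RSS level.  After smoothing, streams
are folded into non-overlapping 5 s windows — the time step of the hidden
Markov model downstream — by averaging per station.

All filters operate on one ``(tag, station)`` stream at a time; windows are
time-based (seconds), not sample-count based, so irregular reception gaps are
handled naturally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

NOMINAL_DT = 0.2  # s between advertisements at the 5 Hz send rate
DEFAULT_FOLD_S = 5.0
#: Default pipeline smoother: moving mean over a 10 s window.
DEFAULT_FILTER = ("mean", 10.0)


@dataclass(frozen=True)
class RssSeries:
    """One (tag, station) RSS stream: strictly increasing timestamps (s),
    values (dB)."""

    timestamps: np.ndarray
    values: np.ndarray
    nominal_dt: float = NOMINAL_DT

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("timestamps and values must be equal-length 1-D")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.timestamps.size


@dataclass(frozen=True)
class KalmanSpec:
    """Constant-velocity Kalman filter on the RSS level.

    State is ``[rss, slope]`` with transition ``F = [[1, dt], [0, 1]]``,
    observation ``H = [1, 0]``, process noise ``Q = q * I``, measurement
    noise variance ``r`` (default 1).
    """

    q: float = 1e-5
    dt: float = NOMINAL_DT
    r: float = 1.0

    def __post_init__(self) -> None:
        if self.q <= 0 or self.dt <= 0 or self.r <= 0:
            raise ValueError("q, dt and r must all be > 0")


def _window_bounds(t: np.ndarray, window: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.searchsorted(t, t - window / 2.0, side="left")
    hi = np.searchsorted(t, t + window / 2.0, side="right")
    return lo, hi


def mean_filter(series: RssSeries, window: float) -> RssSeries:
    """Centered moving average over all samples within ±window/2 seconds.

    Windows truncate at the series edges; output timestamps are unchanged.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(series) == 0:
        return series
    t, v = series.timestamps, series.values
    lo, hi = _window_bounds(t, window)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return RssSeries(t, out, series.nominal_dt)


def median_filter(series: RssSeries, window: float) -> RssSeries:
    """Centered moving median over all samples within ±window/2 seconds."""
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(series) == 0:
        return series
    t, v = series.timestamps, series.values
    lo, hi = _window_bounds(t, window)
    out = np.array([np.median(v[a:b]) for a, b in zip(lo, hi)])
    return RssSeries(t, out, series.nominal_dt)


def kalman_filter(series: RssSeries, spec: KalmanSpec = KalmanSpec()) -> RssSeries:
    """Linear Kalman recursion over the stream; returns the filtered level.

    Initialisation: state ``[first observation, 0]``, covariance identity.
    """
    if len(series) == 0:
        return series
    v = series.values
    if not np.all(np.isfinite(v)):
        raise ValueError("RSS values must be finite")
    F = np.array([[1.0, spec.dt], [0.0, 1.0]])
    Q = spec.q * np.eye(2)
    H = np.array([1.0, 0.0])
    x = np.array([v[0], 0.0])
    P = np.eye(2)
    out = np.empty_like(v)
    for i, z in enumerate(v):
        x = F @ x
        P = F @ P @ F.T + Q
        s = H @ P @ H + spec.r
        k = (P @ H) / s
        x = x + k * (z - H @ x)
        P = (np.eye(2) - np.outer(k, H)) @ P
        out[i] = x[0]
    return RssSeries(series.timestamps, out, series.nominal_dt)


_FILTERS = {"mean": mean_filter, "median": median_filter, "kalman": kalman_filter}


def filter_log(
    records: pd.DataFrame,
    method: str | None = "mean",
    window: float = 10.0,
    q: float = 1e-5,
    r: float = 1.0,
) -> pd.DataFrame:
    """Apply a smoother to every (tag, station) stream of an RSS log.

    ``records`` needs columns ``timestamp``, ``tag_id``, ``station_id``,
    ``rss_db``.  ``method=None`` returns the input unchanged.
    """
    if method is None:
        return records
    if method not in _FILTERS:
        raise ValueError(f"unknown filter method {method!r}")
    parts = []
    for _, grp in records.groupby(["tag_id", "station_id"], sort=False):
        grp = grp.sort_values("timestamp")
        series = RssSeries(grp["timestamp"].to_numpy(), grp["rss_db"].to_numpy())
        if method == "kalman":
            filtered = kalman_filter(series, KalmanSpec(q=q, r=r))
        else:
            filtered = _FILTERS[method](series, window)
        grp = grp.copy()
        grp["rss_db"] = filtered.values
        parts.append(grp)
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values("timestamp", kind="stable", ignore_index=True)


class RssSmoother(TransformerMixin, BaseEstimator):
    """Transformer wrapper over :func:`filter_log` for pipeline composition."""

    def __init__(self, method: str | None = "mean", window: float = 10.0,
                 q: float = 1e-5, r: float = 1.0):
        self.method = method
        self.window = window
        self.q = q
        self.r = r

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return filter_log(X, self.method, self.window, self.q, self.r)


@dataclass
class ObservationWindow:
    """One folded interval for one tag: per-station mean RSS over the
    stations actually heard during [t_start, t_end)."""

    t_start: float
    t_end: float
    tag_id: str
    rss_by_station: dict = field(default_factory=dict)

    @property
    def heard(self) -> set:
        return set(self.rss_by_station)


def fold_windows(
    records: pd.DataFrame, fold: float = DEFAULT_FOLD_S, t0: float | None = None
) -> dict[str, list[ObservationWindow]]:
    """Fold an RSS log into aligned, non-overlapping windows per tag.

    Windows are ``[t0 + k*fold, t0 + (k+1)*fold)`` where ``t0`` defaults to
    the first timestamp of the batch rounded down to a whole fold interval.
    Per window and station the RSS is averaged; stations with no sample in a
    window are absent from that window's heard-set.  Every tag's window list
    is contiguous from its first to its last occupied window (intermediate
    windows with no reception appear with an empty heard-set) so downstream
    decoding can bridge silent stretches through the transition model.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    out: dict[str, list[ObservationWindow]] = {}
    if len(records) == 0:
        return out
    if t0 is None:
        t0 = np.floor(records["timestamp"].min() / fold) * fold
    df = records.copy()
    df["_win"] = np.floor((df["timestamp"] - t0) / fold).astype(int)
    grouped = df.groupby(["tag_id", "_win", "station_id"])["rss_db"].mean()
    for tag, tag_grp in grouped.groupby(level=0):
        wins = tag_grp.index.get_level_values(1)
        windows = []
        for w in range(int(wins.min()), int(wins.max()) + 1):
            obs = ObservationWindow(
                t_start=t0 + w * fold, t_end=t0 + (w + 1) * fold, tag_id=str(tag)
            )
            if w in wins:
                sub = tag_grp.xs(w, level=1)
                obs.rss_by_station = {
                    str(s): float(val)
                    for (t, s), val in sub.items()
                }
            windows.append(obs)
        out[str(tag)] = windows
    return out
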