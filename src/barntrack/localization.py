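"""Grid lookup-table localization with hidden-Markov trajectory smoothing.

For each 5 s observation window the measured per-station RSS vector is
compared against the precomputed model RSS at every mapping point ``k``:

    Err_k = sum over heard stations i of
            (RSS_mes,i - N_mes - (RSS_map[k,i] - N_pm,k))^2,

where ``N_mes`` is the mean measured RSS over the heard stations and
``N_pm,k`` the mean model RSS over the same stations at point ``k``.  The
two shifting factors make the comparison use *relative* signal levels, which
cancels constant per-tag and per-station offsets — the dominant nuisance in
a herd of cheap tags.  The unshifted variant omits both means and compares
absolute levels.

Point probabilities are the reciprocal localization errors,
``P_k ∝ 1 / Err_k``, and the most probable trajectory over the whole
recording is decoded with the Viterbi algorithm under the barn-structure
transition matrix, so the track can never jump farther than the per-step
limit or cross a wall.  Stations are excluded from the sums in windows where
they heard nothing, and the model mean ``N_pm,k`` is taken over the same
heard subset; this subset matching is what makes the shifted error exactly
invariant to a constant offset on all heard stations.  Windows heard by
fewer than ``min_stations`` receivers are decoded from the transition prior
alone (uniform emission).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .barn_map import BarnMap, build_rss_lookup, build_transition_matrix
from .filtering import DEFAULT_FOLD_S, ObservationWindow, filter_log, fold_windows
from .propagation import DEFAULT_MODEL, PathLossModel

EMISSION_EPS = 1e-9  # floor on Err before taking the reciprocal
PROB_FLOOR = 1e-300  # floor on emission probabilities in the log domain
DEFAULT_MIN_STATIONS = 3  # below this a 2-D position is underdetermined


@dataclass
class ErrorSurface:
    """Localization error at every mapping point for one window."""

    errs: np.ndarray
    n_stations_used: int

    def __post_init__(self) -> None:
        self.errs = np.asarray(self.errs, dtype=float)
        if np.any(self.errs < 0):
            raise ValueError("localization errors must be >= 0")


@dataclass
class Track:
    """Decoded trajectory: mapping-point index per window, for one tag."""

    tag_id: str
    t_starts: np.ndarray
    points: np.ndarray
    fold: float = DEFAULT_FOLD_S

    def __len__(self) -> int:
        return len(self.points)

    def coords(self, barn_map: BarnMap) -> np.ndarray:
        """(W, 2) decoded coordinates in metres."""
        return barn_map.coords[self.points]

    def to_frame(self, barn_map: BarnMap) -> pd.DataFrame:
        xy = self.coords(barn_map)
        return pd.DataFrame(
            {
                "t_start": self.t_starts,
                "tag_id": self.tag_id,
                "point_index": self.points,
                "x": xy[:, 0],
                "y": xy[:, 1],
            }
        )


def error_surface(
    obs: ObservationWindow,
    barn_map: BarnMap,
    shifted: bool = True,
    min_stations: int = DEFAULT_MIN_STATIONS,
) -> ErrorSurface:
    """Localization error of one window at every mapping point.

    Raises ``ValueError`` when fewer than ``min_stations`` stations were
    heard (the window is unlocatable from RSS alone).
    """
    if barn_map.rss_map_ is None:
        raise ValueError("barn map has no RSS lookup table; call build() first")
    ids = barn_map.station_ids
    heard = [s for s in ids if s in obs.rss_by_station]
    if len(heard) < min_stations:
        raise ValueError(
            f"unlocatable window at t={obs.t_start}: heard {len(heard)} "
            f"stations, need {min_stations}"
        )
    idx = [ids.index(s) for s in heard]
    mes = np.array([obs.rss_by_station[s] for s in heard])
    sub = barn_map.rss_map_[:, idx]
    if shifted:
        mes = mes - mes.mean()
        sub = sub - sub.mean(axis=1, keepdims=True)
    errs = ((mes[None, :] - sub) ** 2).sum(axis=1)
    return ErrorSurface(errs=np.maximum(errs, 0.0), n_stations_used=len(heard))


def best_point(surface: ErrorSurface) -> int:
    """Index of the minimum-error mapping point; ties go to the lowest index."""
    return int(np.argmin(surface.errs))


def emission_probabilities(
    surface: ErrorSurface, eps: float = EMISSION_EPS
) -> np.ndarray:
    """Point probabilities ``P_k ∝ 1/Err_k``, normalised to sum to one."""
    p = 1.0 / np.maximum(surface.errs, eps)
    return p / p.sum()


def viterbi_decode(
    emissions: np.ndarray, tm: np.ndarray, prior: np.ndarray | None = None
) -> np.ndarray:
    """Most probable hidden-state path of the HMM (log-domain Viterbi).

    ``emissions`` is (T, K); rows that sum to zero are treated as
    uninformative (uniform).  Transitions with probability zero are
    structurally impossible (log weight −inf), so the decoded path can never
    traverse them.  Ties are broken toward the lowest state index.
    """
    em = np.asarray(emissions, dtype=float)
    if em.ndim != 2 or em.shape[0] < 1:
        raise ValueError("emissions must be a (T, K) array with T >= 1")
    t_steps, k = em.shape
    if tm.shape != (k, k):
        raise ValueError("transition matrix shape does not match emissions")
    em = em.copy()
    dead = em.sum(axis=1) <= 0
    em[dead] = 1.0 / k
    log_em = np.log(np.maximum(em, PROB_FLOOR))
    with np.errstate(divide="ignore"):
        log_tm = np.log(tm)
    if prior is None:
        log_prior = np.full(k, -np.log(k))
    else:
        with np.errstate(divide="ignore"):
            log_prior = np.log(np.asarray(prior, dtype=float))
    scores = log_prior + log_em[0]
    back = np.empty((t_steps, k), dtype=np.intp)
    for t in range(1, t_steps):
        cand = scores[:, None] + log_tm
        ptr = np.argmax(cand, axis=0)
        back[t] = ptr
        scores = cand[ptr, np.arange(k)] + log_em[t]
    path = np.empty(t_steps, dtype=np.intp)
    path[-1] = int(np.argmax(scores))
    for t in range(t_steps - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def _emissions_for_windows(
    windows: list[ObservationWindow],
    station_ids: list[str],
    rss_map: np.ndarray,
    shifted: bool,
    min_stations: int,
    eps: float = EMISSION_EPS,
) -> np.ndarray:
    """(W, K) emission matrix; unlocatable windows get uniform rows.

    Windows sharing a heard-station pattern are processed together so the
    per-point sums reduce to one matrix product per pattern.
    """
    k = rss_map.shape[0]
    w = len(windows)
    out = np.full((w, k), 1.0 / k)
    id_index = {s: i for i, s in enumerate(station_ids)}
    patterns: dict[frozenset, list[int]] = {}
    for wi, obs in enumerate(windows):
        heard = frozenset(s for s in obs.rss_by_station if s in id_index)
        if len(heard) >= min_stations:
            patterns.setdefault(heard, []).append(wi)
    for heard, rows in patterns.items():
        idx = sorted(id_index[s] for s in heard)
        ids = [station_ids[i] for i in idx]
        mes = np.array(
            [[windows[wi].rss_by_station[s] for s in ids] for wi in rows]
        )
        sub = rss_map[:, idx]
        if shifted:
            mes = mes - mes.mean(axis=1, keepdims=True)
            sub = sub - sub.mean(axis=1, keepdims=True)
        # ||m - M_k||^2 expanded: one matmul for the cross term
        errs = (
            (mes**2).sum(axis=1)[:, None]
            - 2.0 * mes @ sub.T
            + (sub**2).sum(axis=1)[None, :]
        )
        errs = np.maximum(errs, 0.0)
        p = 1.0 / np.maximum(errs, eps)
        out[rows] = p / p.sum(axis=1, keepdims=True)
    return out


class GridLocalizer(BaseEstimator):
    """Lookup-table localizer with Viterbi trajectory smoothing.

    ``fit`` precomputes the RSS lookup table and the transition matrix from
    the barn map and path-loss model; ``predict`` takes a raw RSS log
    (DataFrame with columns ``timestamp, tag_id, station_id, rss_db``) and
    returns one decoded :class:`Track` per tag.

    Parameters
    ----------
    barn_map : BarnMap
        Barn geometry with stations and obstacles.
    model : PathLossModel
        Path-loss model used to fill the lookup table.
    shifted : bool
        Use the shift-invariant error function (default); ``False`` compares
        absolute RSS levels.
    min_stations : int
        Minimum heard stations for a window to contribute RSS evidence.
    filter_method : str or None
        RSS smoother applied before folding (``mean``/``median``/``kalman``
        or None for raw).
    filter_window : float
        Smoother time window in seconds (mean/median).
    kalman_q : float
        Process-noise scale when ``filter_method="kalman"``.
    fold : float
        Observation-window length in seconds.

    Attributes
    ----------
    rss_map_ : (K, S) ndarray
        Model RSS per mapping point and station.
    tm_ : (K, K) ndarray
        Row-stochastic transition matrix.
    """

    def __init__(
        self,
        barn_map: BarnMap,
        model: PathLossModel = DEFAULT_MODEL,
        shifted: bool = True,
        min_stations: int = DEFAULT_MIN_STATIONS,
        filter_method: str | None = "mean",
        filter_window: float = 10.0,
        kalman_q: float = 1e-5,
        fold: float = DEFAULT_FOLD_S,
    ):
        self.barn_map = barn_map
        self.model = model
        self.shifted = shifted
        self.min_stations = min_stations
        self.filter_method = filter_method
        self.filter_window = filter_window
        self.kalman_q = kalman_q
        self.fold = fold

    def fit(self, X=None, y=None):
        self.rss_map_ = build_rss_lookup(
            self.barn_map.points,
            self.barn_map.stations,
            self.model,
            self.barn_map.tag_height,
        )
        self.tm_ = build_transition_matrix(
            self.barn_map.points, self.barn_map.obstacles, self.barn_map.transition
        )
        return self

    def _check_fitted(self):
        if not hasattr(self, "rss_map_"):
            raise ValueError("GridLocalizer is not fitted; call fit() first")

    def decode_windows(self, windows: list[ObservationWindow]) -> Track:
        """Decode one tag's window sequence into a track."""
        self._check_fitted()
        if not windows:
            raise ValueError("no observation windows to decode")
        em = _emissions_for_windows(
            windows,
            self.barn_map.station_ids,
            self.rss_map_,
            self.shifted,
            self.min_stations,
        )
        path = viterbi_decode(em, self.tm_)
        return Track(
            tag_id=windows[0].tag_id,
            t_starts=np.array([w.t_start for w in windows]),
            points=path,
            fold=self.fold,
        )

    def predict(self, X: pd.DataFrame) -> dict[str, Track]:
        """Filter, fold and decode an RSS log; one track per tag.

        Tags whose every window is unlocatable still produce a track (decoded
        from the transition prior alone); tags with no records at all are
        absent from the result.
        """
        self._check_fitted()
        filtered = filter_log(
            X, self.filter_method, self.filter_window, q=self.kalman_q
        )
        per_tag = fold_windows(filtered, fold=self.fold)
        tracks: dict[str, Track] = {}
        for tag, windows in per_tag.items():
            locatable = sum(
                1
                for w in windows
                if len(w.rss_by_station) >= self.min_stations
            )
            if locatable == 0:
                import warnings

                warnings.warn(
                    f"tag {tag}: no locatable windows; track decoded from "
                    "the movement prior only",
                    stacklevel=2,
                )
            tracks[tag] = self.decode_windows(windows)
        return tracks


def localize(
    records: pd.DataFrame,
    barn_map: BarnMap,
    model: PathLossModel = DEFAULT_MODEL,
    shifted: bool = True,
    filter_method: str | None = "mean",
    filter_window: float = 10.0,
    min_stations: int = DEFAULT_MIN_STATIONS,
    fold: float = DEFAULT_FOLD_S,
) -> dict[str, Track]:
    """End-to-end pipeline: smooth, fold, localize and Viterbi-decode.

    Thin wrapper over :class:`GridLocalizer`.
    """
    loc = GridLocalizer(
        barn_map=barn_map,
        model=model,
        shifted=shifted,
        min_stations=min_stations,
        filter_method=filter_method,
        filter_window=filter_window,
        fold=fold,
    ).fit()
    return loc.predict(records)
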