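"""Accuracy metrics against reference locations, occupancy and zone maps.

Localization accuracy is evaluated per reference event: the decoded mapping
point occupying the majority of the 5 s windows inside the event interval is
compared with the reference location by plane Euclidean distance.  Summaries
report per-tag and pooled mean ± STD (sample STD, n−1 denominator) and the
empirical cumulative error curve.  Occupancy maps give the relative
frequency of decoded presence per mapping point; zone distributions coarsen
them over labelled barn regions (feeding, cubicles, waiting yard, ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .barn_map import BarnMap
from .localization import Track


@dataclass
class AccuracySummary:
    """Per-tag and pooled localization accuracy (metres)."""

    per_tag: pd.DataFrame  # index tag_id; columns mean_m, std_m, n_events
    mean_m: float
    std_m: float
    curve_errors: np.ndarray  # sorted error grid
    curve_fractions: np.ndarray  # fraction of events with error <= grid value


def localization_errors(
    track: Track | dict[str, Track],
    refs: pd.DataFrame,
    barn_map: BarnMap,
) -> pd.DataFrame:
    """Per-event localization error in metres.

    ``refs`` needs columns ``t_start, t_end, tag_id, x, y``.  For each event
    the decoded point is the majority vote over the track windows starting
    inside the event interval (ties to the lowest point index); events with
    no decoded windows are skipped with a warning.
    """
    tracks = track if isinstance(track, dict) else {track.tag_id: track}
    coords = barn_map.coords
    rows = []
    for ev in refs.itertuples(index=False):
        trk = tracks.get(str(ev.tag_id))
        if trk is None:
            warnings.warn(f"no track for tag {ev.tag_id}; event skipped",
                          stacklevel=2)
            continue
        sel = (trk.t_starts >= ev.t_start) & (trk.t_starts < ev.t_end)
        if not sel.any():
            warnings.warn(
                f"tag {ev.tag_id}: no decoded windows in "
                f"[{ev.t_start}, {ev.t_end}); event skipped",
                stacklevel=2,
            )
            continue
        pts, counts = np.unique(trk.points[sel], return_counts=True)
        winner = int(pts[np.argmax(counts)])  # first max = lowest index
        err = float(np.hypot(coords[winner, 0] - ev.x, coords[winner, 1] - ev.y))
        rows.append(
            {
                "tag_id": str(ev.tag_id),
                "t_start": ev.t_start,
                "t_end": ev.t_end,
                "point_index": winner,
                "error_m": err,
            }
        )
    return pd.DataFrame(
        rows, columns=["tag_id", "t_start", "t_end", "point_index", "error_m"]
    )


def accuracy_summary(errors: pd.DataFrame) -> AccuracySummary:
    """Mean ± STD per tag and pooled, plus the cumulative error curve.

    STDs use the sample convention (n−1); a single event yields STD 0.
    """
    if len(errors) == 0:
        raise ValueError("no localization errors to summarise")
    e = errors["error_m"].to_numpy(dtype=float)
    per_tag = errors.groupby("tag_id")["error_m"].agg(
        mean_m="mean", std_m=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
        n_events="count",
    )
    pooled_std = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    order = np.sort(e)
    fractions = np.arange(1, e.size + 1) / e.size
    return AccuracySummary(
        per_tag=per_tag,
        mean_m=float(e.mean()),
        std_m=pooled_std,
        curve_errors=order,
        curve_fractions=fractions,
    )


def occupancy_map(track: Track | dict[str, Track], barn_map: BarnMap) -> np.ndarray:
    """Relative frequency of decoded presence per mapping point (sums to 1)."""
    tracks = track if isinstance(track, dict) else {track.tag_id: track}
    k = len(barn_map.points)
    counts = np.zeros(k)
    total = 0
    for trk in tracks.values():
        counts += np.bincount(trk.points, minlength=k)
        total += len(trk)
    if total == 0:
        raise ValueError("empty track")
    return counts / total


def zone_time_distribution(
    track: Track | dict[str, Track], barn_map: BarnMap
) -> dict[str, float]:
    """Fraction of time per zone label; points without a zone fall into
    ``"unassigned"``.  Exact coarsening of :func:`occupancy_map`."""
    occ = occupancy_map(track, barn_map)
    out: dict[str, float] = {}
    for p, f in zip(barn_map.points, occ):
        if f == 0:
            continue
        label = p.zone if p.zone is not None else "unassigned"
        out[label] = out.get(label, 0.0) + float(f)
    return out


def plot_cumulative(summary: AccuracySummary, path: str) -> None:
    """Cumulative percentage of location error (accuracy curve figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.step(summary.curve_errors, 100 * summary.curve_fractions, where="post")
    ax.set_xlabel("location error (m)")
    ax.set_ylabel("cumulative percentage (%)")
    ax.set_ylim(0, 100)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_occupancy(occ: np.ndarray, barn_map: BarnMap, path: str) -> None:
    """Scatter heat map of relative presence frequency over the barn."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = barn_map.coords
    fig, ax = plt.subplots(figsize=(4, 8))
    sc = ax.scatter(coords[:, 0], coords[:, 1], c=occ, s=30, cmap="viridis")
    for st in barn_map.stations:
        ax.plot(st.x, st.y, "r^", ms=8)
    fig.colorbar(sc, ax=ax, label="relative frequency")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
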