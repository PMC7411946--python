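"""File formats, run configuration and the end-to-end pipeline runner.

RSS logs and tracks are plain CSV (the stations' native output format); the
barn map is YAML because of its nested geometry.  Timestamps are stored as
epoch seconds (floats); ISO-8601 strings are accepted on input.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .barn_map import BarnMap
from .evaluate import (
    accuracy_summary,
    localization_errors,
    occupancy_map,
    plot_cumulative,
    plot_occupancy,
    zone_time_distribution,
)
from .localization import Track, localize
from .propagation import DEFAULT_MODEL, PathLossModel

log = logging.getLogger("barntrack")

RSS_COLUMNS = ["timestamp", "tag_id", "station_id", "rss_db"]
TRACK_COLUMNS = ["t_start", "tag_id", "point_index", "x", "y"]
REF_COLUMNS = ["t_start", "t_end", "tag_id", "x", "y"]


class FormatError(ValueError):
    """Raised when a file is missing required structure."""


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    """Epoch seconds from numeric or ISO-8601 values; NaN where unparseable."""
    num = pd.to_numeric(raw, errors="coerce")
    bad = num.isna() & raw.notna()
    if bad.any():
        iso = pd.to_datetime(raw[bad], errors="coerce", utc=True, format="ISO8601")
        ok = iso.notna()
        num.loc[ok[ok].index] = iso[ok].astype("int64") / 1e9
    return num


def read_rss_log(path) -> pd.DataFrame:
    """Read and validate an RSS log CSV; returns time-sorted records.

    Required columns: ``timestamp, tag_id, station_id, rss_db``.  Rows with
    unparseable timestamps or RSS values are dropped with a warning that
    lists their line numbers (1-based, header = line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in RSS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    ts = _parse_timestamps(df["timestamp"])
    rss = pd.to_numeric(df["rss_db"], errors="coerce")
    bad = ts.isna() | rss.isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        warnings.warn(
            f"{path}: dropped {bad.sum()} malformed row(s) at line(s) {lines}",
            stacklevel=2,
        )
        df = df[~bad]
        ts, rss = ts[~bad], rss[~bad]
    out = df.copy()
    out["timestamp"] = ts.astype(float)
    out["rss_db"] = rss.astype(float)
    out["tag_id"] = out["tag_id"].astype(str)
    out["station_id"] = out["station_id"].astype(str)
    return out.sort_values("timestamp", kind="stable", ignore_index=True)


def write_rss_log(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.4f")


def read_map_config(path) -> BarnMap:
    """Load and validate a barn map from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: map config must be a mapping")
    try:
        return BarnMap.from_dict(cfg)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: invalid map config ({exc})") from exc


def write_map_config(barn_map: BarnMap, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(barn_map.to_dict(), fh, sort_keys=False)


def synthetic_barn() -> BarnMap:
    """The packaged synthetic barn: a 9.8 × 39 m usable area with feeding
    alley, cubicle rows, waiting yard and milking-robot corner, of the same
    general geometry as a small free-stall research barn."""
    ref = resources.files("barntrack") / "data" / "barn_synthetic.yaml"
    with resources.as_file(ref) as p:
        return read_map_config(p)


def write_tracks(tracks: dict[str, Track], barn_map: BarnMap, path) -> None:
    frames = [t.to_frame(barn_map) for t in tracks.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_tracks(path, fold: float = 5.0) -> dict[str, Track]:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    out = {}
    for tag, grp in df.groupby("tag_id"):
        grp = grp.sort_values("t_start")
        out[str(tag)] = Track(
            tag_id=str(tag),
            t_starts=grp["t_start"].to_numpy(dtype=float),
            points=grp["point_index"].to_numpy(dtype=np.intp),
            fold=fold,
        )
    return out


def read_reference(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REF_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["tag_id"] = df["tag_id"].astype(str)
    return df


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    map_path: str
    rss_path: str
    track_path: str = "track.csv"
    report_path: str | None = None
    ref_path: str | None = None
    plots_dir: str | None = None
    filter_method: str | None = "mean"
    filter_window: float = 10.0
    fold: float = 5.0
    shifted: bool = True
    min_stations: int = 3
    model: PathLossModel = field(default_factory=lambda: DEFAULT_MODEL)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "model"}
        d["model"] = {"n": self.model.n, "a0": self.model.a0}
        return d


def run_pipeline(config: RunConfig) -> dict:
    """Filter → fold → localize → (optionally) evaluate; writes artifacts.

    Returns the report dict.  Deterministic: identical config and inputs
    yield identical artifacts.
    """
    log.info("barntrack %s: pipeline start, config=%s", __version__,
             json.dumps(config.to_dict()))
    try:
        barn_map = read_map_config(config.map_path)
    except Exception as exc:
        raise RuntimeError(f"[map] {exc}") from exc
    try:
        records = read_rss_log(config.rss_path)
    except Exception as exc:
        raise RuntimeError(f"[rss] {exc}") from exc
    try:
        tracks = localize(
            records,
            barn_map,
            model=config.model,
            shifted=config.shifted,
            filter_method=config.filter_method,
            filter_window=config.filter_window,
            min_stations=config.min_stations,
            fold=config.fold,
        )
        write_tracks(tracks, barn_map, config.track_path)
    except Exception as exc:
        raise RuntimeError(f"[localize] {exc}") from exc

    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "n_tags": len(tracks),
        "n_windows": {t: len(trk) for t, trk in tracks.items()},
    }
    occ = occupancy_map(tracks, barn_map)
    report["zone_time_distribution"] = zone_time_distribution(tracks, barn_map)

    if config.ref_path is not None:
        try:
            refs = read_reference(config.ref_path)
            errors = localization_errors(tracks, refs, barn_map)
            summary = accuracy_summary(errors)
        except Exception as exc:
            raise RuntimeError(f"[evaluate] {exc}") from exc
        report["accuracy"] = {
            "mean_m": summary.mean_m,
            "std_m": summary.std_m,
            "per_tag": {
                t: {
                    "mean_m": float(r["mean_m"]),
                    "std_m": float(r["std_m"]),
                    "n_events": int(r["n_events"]),
                }
                for t, r in summary.per_tag.iterrows()
            },
            "cumulative": {
                "error_m": summary.curve_errors.tolist(),
                "fraction": summary.curve_fractions.tolist(),
            },
        }
        if config.plots_dir is not None:
            out = Path(config.plots_dir)
            out.mkdir(parents=True, exist_ok=True)
            plot_cumulative(summary, str(out / "cumulative_error.png"))
            plot_occupancy(occ, barn_map, str(out / "occupancy.png"))
    elif config.plots_dir is not None:
        out = Path(config.plots_dir)
        out.mkdir(parents=True, exist_ok=True)
        plot_occupancy(occ, barn_map, str(out / "occupancy.png"))

    if config.report_path is not None:
        with open(config.report_path, "w") as fh:
            json.dump(report, fh, indent=2)
    log.info("pipeline done: %d tag(s)", len(tracks))
    return report
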