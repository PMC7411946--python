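"""Barn geometry: mapping-point grid, RSS lookup table and transition matrix.

Localization is discrete: the barn floor is covered by mapping points on a
regular grid (about 1 m pitch; 0.5 m in the small waiting yard), each of
which is a hidden state of the trajectory HMM.  Two precomputed structures
live on the map:

* ``rss_map`` — model RSS at every mapping point for every receiving
  station, from the log-distance path-loss model and 3-D distances with the
  tag carried at a fixed collar height;
* ``tm`` — a row-stochastic transition matrix over mapping points.  A move
  is possible within 3 m per time step and only if the straight passage
  between the two points crosses no obstacle; its unnormalised weight is
  ``1 / (1 + dist)``, staying in place has weight 1, and each row is then
  normalised to sum to one.

Obstacles are 2-D in the floor plane: open polylines (``wall``) block
passages, closed polygons (``block``) additionally exclude the grid points
they cover.  A passage that merely touches an obstacle counts as blocked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Point, Polygon
from shapely.strtree import STRtree

from .propagation import PathLossModel

TAG_HEIGHT_M = 1.5  # collar height of the tag above the floor
MIN_DISTANCE_M = 0.1  # clamp to avoid the log singularity at zero range


@dataclass(frozen=True)
class Station:
    """A receiving station at a fixed 3-D position (metres, barn frame)."""

    id: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError(f"station {self.id}: height z must be > 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class MapPoint:
    """One predefined location point of the localization grid."""

    index: int
    x: float
    y: float
    zone: str | None = None


@dataclass(frozen=True)
class Obstacle:
    """A 2-D barn structure: ``wall`` (open polyline, blocks passage) or
    ``block`` (closed polygon, blocks passage and excludes interior grid
    points)."""

    kind: str
    points: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("wall", "block"):
            raise ValueError(f"unknown obstacle kind {self.kind!r}")
        pts = tuple((float(x), float(y)) for x, y in self.points)
        need = 3 if self.kind == "block" else 2
        if len(pts) < need:
            raise ValueError(f"{self.kind} obstacle needs >= {need} vertices")
        object.__setattr__(self, "points", pts)

    def geometry(self):
        if self.kind == "block":
            return Polygon(self.points)
        return LineString(self.points)


@dataclass(frozen=True)
class Zone:
    """A labelled floor region used for occupancy aggregation."""

    label: str
    polygon: tuple

    def geometry(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class TransitionSpec:
    """Rules of the movement chain between mapping points."""

    max_step: float = 3.0  # m per decoding time step
    stay_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")

    def weight(self, dist: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + dist)


def build_grid(
    extents: tuple[float, float, float, float],
    resolution: float,
    obstacles: list[Obstacle] = (),
    zones: list[Zone] = (),
) -> list[MapPoint]:
    """Regular grid of mapping points over ``(xmin, xmax, ymin, ymax)``.

    Boundary points are included; points covered by a ``block`` obstacle are
    excluded.  Indices are assigned row-major (y-major, then x), so the same
    configuration always yields identical indexing.
    """
    xmin, xmax, ymin, ymax = map(float, extents)
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if resolution > (xmax - xmin) or resolution > (ymax - ymin):
        raise ValueError("resolution exceeds the barn extents")
    xs = np.round(np.arange(xmin, xmax + resolution / 2, resolution), 9)
    ys = np.round(np.arange(ymin, ymax + resolution / 2, resolution), 9)
    blocks = [o.geometry() for o in obstacles if o.kind == "block"]
    zone_geoms = [(z.label, z.geometry()) for z in zones]
    points: list[MapPoint] = []
    k = 0
    for y in ys:
        for x in xs:
            p = Point(x, y)
            if any(g.covers(p) for g in blocks):
                continue
            label = next(
                (lbl for lbl, g in zone_geoms if g.covers(p)), None
            )
            points.append(MapPoint(index=k, x=float(x), y=float(y), zone=label))
            k += 1
    return points


def passage_clear(
    i: MapPoint | tuple, j: MapPoint | tuple, obstacles: list[Obstacle]
) -> bool:
    """True iff the straight segment between two points crosses no obstacle.

    Touching an obstacle (even at a single endpoint) counts as blocked.
    """
    xi, yi = (i.x, i.y) if isinstance(i, MapPoint) else i
    xj, yj = (j.x, j.y) if isinstance(j, MapPoint) else j
    seg = LineString([(xi, yi), (xj, yj)])
    return not any(seg.intersects(o.geometry()) for o in obstacles)


def build_rss_lookup(
    points: list[MapPoint],
    stations: list[Station],
    model: PathLossModel,
    tag_height: float = TAG_HEIGHT_M,
) -> np.ndarray:
    """Model RSS at every mapping point for every station (K x S, dB).

    Distances are 3-D Euclidean between ``(x_k, y_k, tag_height)`` and the
    station position, clamped below at 0.1 m.
    """
    if not stations:
        raise ValueError("at least one station is required")
    pts = np.array([[p.x, p.y, tag_height] for p in points])
    sta = np.array([s.position for s in stations])
    dist = np.linalg.norm(pts[:, None, :] - sta[None, :, :], axis=2)
    dist = np.maximum(dist, MIN_DISTANCE_M)
    return np.asarray(model.predict(dist))


def build_transition_matrix(
    points: list[MapPoint],
    obstacles: list[Obstacle] = (),
    spec: TransitionSpec = TransitionSpec(),
) -> np.ndarray:
    """Row-stochastic movement matrix over mapping points.

    Unnormalised weights: diagonal ``stay_weight``; zero beyond ``max_step``
    or across an obstacle; else ``1/(1+dist)``.  Rows are then normalised.
    An isolated point keeps probability 1 of staying put.
    """
    if not points:
        raise ValueError("at least one mapping point is required")
    coords = np.array([[p.x, p.y] for p in points])
    k = len(points)
    tm = np.zeros((k, k))
    np.fill_diagonal(tm, spec.stay_weight)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=spec.max_step, output_type="ndarray")
    if pairs.size:
        geoms = [o.geometry() for o in obstacles]
        if geoms:
            obstree = STRtree(geoms)
            clear = np.empty(len(pairs), dtype=bool)
            for m, (a, b) in enumerate(pairs):
                seg = LineString([coords[a], coords[b]])
                cand = obstree.query(seg)
                clear[m] = not any(
                    seg.intersects(geoms[c]) for c in np.atleast_1d(cand)
                )
        else:
            clear = np.ones(len(pairs), dtype=bool)
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        w = spec.weight(d)
        a, b = pairs[clear, 0], pairs[clear, 1]
        tm[a, b] = w[clear]
        tm[b, a] = w[clear]
    tm /= tm.sum(axis=1, keepdims=True)
    return tm


@dataclass
class BarnMap:
    """Barn description plus the precomputed localization structures.

    ``build(model)`` populates the grid, the RSS lookup table ``rss_map_``
    and the transition matrix ``tm_`` for a given path-loss model.
    """

    extents: tuple[float, float, float, float]
    resolution: float
    stations: list[Station]
    obstacles: list[Obstacle] = field(default_factory=list)
    zones: list[Zone] = field(default_factory=list)
    tag_height: float = TAG_HEIGHT_M
    transition: TransitionSpec = field(default_factory=TransitionSpec)

    points: list[MapPoint] = field(default_factory=list, repr=False)
    rss_map_: np.ndarray | None = field(default=None, repr=False)
    tm_: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.extents
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("degenerate extents")
        for s in self.stations:
            if not (xmin <= s.x <= xmax and ymin <= s.y <= ymax):
                raise ValueError(
                    f"station {s.id} at ({s.x}, {s.y}) lies outside the extents"
                )
        if not self.points:
            self.points = build_grid(
                self.extents, self.resolution, self.obstacles, self.zones
            )

    @property
    def station_ids(self) -> list[str]:
        return [s.id for s in self.stations]

    @property
    def coords(self) -> np.ndarray:
        """(K, 2) array of mapping-point coordinates."""
        return np.array([[p.x, p.y] for p in self.points])

    def build(self, model: PathLossModel) -> "BarnMap":
        self.rss_map_ = build_rss_lookup(
            self.points, self.stations, model, self.tag_height
        )
        self.tm_ = build_transition_matrix(
            self.points, self.obstacles, self.transition
        )
        return self

    # ---- config dict (used by the YAML reader/writer in barntrack.io) ----

    def to_dict(self) -> dict:
        xmin, xmax, ymin, ymax = self.extents
        return {
            "extents": {"xmin": xmin, "xmax": xmax, "ymin": ymin, "ymax": ymax},
            "resolution": self.resolution,
            "tag_height": self.tag_height,
            "max_step": self.transition.max_step,
            "stations": [
                {"id": s.id, "x": s.x, "y": s.y, "z": s.z} for s in self.stations
            ],
            "obstacles": [
                {"kind": o.kind, "points": [list(p) for p in o.points]}
                for o in self.obstacles
            ],
            "zones": [
                {"label": z.label, "polygon": [list(p) for p in z.polygon]}
                for z in self.zones
            ],
        }

    @classmethod
    def from_dict(cls, cfg: dict) -> "BarnMap":
        ext = cfg["extents"]
        extents = (ext["xmin"], ext["xmax"], ext["ymin"], ext["ymax"])
        stations = [
            Station(id=str(s["id"]), x=float(s["x"]), y=float(s["y"]), z=float(s["z"]))
            for s in cfg["stations"]
        ]
        obstacles = [
            Obstacle(kind=o["kind"], points=tuple(map(tuple, o["points"])))
            for o in cfg.get("obstacles", [])
        ]
        zones = [
            Zone(label=z["label"], polygon=tuple(map(tuple, z["polygon"])))
            for z in cfg.get("zones", [])
        ]
        return cls(
            extents=extents,
            resolution=float(cfg["resolution"]),
            stations=stations,
            obstacles=obstacles,
            zones=zones,
            tag_height=float(cfg.get("tag_height", TAG_HEIGHT_M)),
            transition=TransitionSpec(max_step=float(cfg.get("max_step", 3.0))),
        )


def station_grid(
    extents: tuple[float, float, float, float],
    spacing: float,
    z: float = 4.0,
    margin: float | None = None,
) -> list[Station]:
    """Evenly spaced station layout over the extents, ``spacing`` metres
    between neighbours, mounted at height ``z``.  Convenience for
    station-density studies."""
    xmin, xmax, ymin, ymax = extents
    if margin is None:
        margin = spacing / 2.0
    xs = np.arange(xmin + margin, xmax - margin + 1e-9, spacing)
    ys = np.arange(ymin + margin, ymax - margin + 1e-9, spacing)
    if xs.size == 0:
        xs = np.array([(xmin + xmax) / 2.0])
    if ys.size == 0:
        ys = np.array([(ymin + ymax) / 2.0])
    stations = []
    i = 0
    for y in ys:
        for x in xs:
            stations.append(Station(id=f"s{i:02d}", x=float(x), y=float(y), z=z))
            i += 1
    return stations
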