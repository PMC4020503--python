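"""Spatial substrate for areal scans: regions, centroids, distances, adjacency.

Regions are represented by their centroids only.  Coordinates are either
planar (projected, e.g. km) or latitude/longitude; the mode is always
declared explicitly and never inferred.  Adjacency is an undirected graph
over region ids, built from the centroids by Delaunay triangulation or
symmetrized k-nearest-neighbor links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable

import numpy as np
from scipy.spatial import Delaunay, QhullError

__all__ = [
    "RegionMap",
    "DistanceMatrix",
    "read_coordinates",
    "write_coordinates",
    "build_adjacency",
    "distances",
    "exclude_regions",
    "EARTH_RADIUS_KM",
]

#: Mean Earth radius used for great-circle distances (km).
EARTH_RADIUS_KM = 6371.0

PLANAR = "planar"
LATLONG = "latlong"
_MODES = (PLANAR, LATLONG)


def _norm_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class RegionMap:
    """Regions with centroids and (optionally) an adjacency graph.

    Parameters
    ----------
    region_ids
        Unique label per region, in a fixed order used by all aligned arrays.
    coords
        ``(n, 2)`` array of centroid coordinates.  In ``latlong`` mode the
        columns are (latitude, longitude) in decimal degrees.
    mode
        ``"planar"`` or ``"latlong"``.
    adjacency
        Unordered region-id pairs; stored normalized (sorted within pair).
    """

    region_ids: tuple[str, ...]
    coords: np.ndarray
    mode: str = PLANAR
    adjacency: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        ids = tuple(str(r) for r in self.region_ids)
        object.__setattr__(self, "region_ids", ids)
        if len(set(ids)) != len(ids):
            dupes = sorted({r for r in ids if ids.count(r) > 1})
            raise ValueError(f"duplicate region ids: {dupes}")
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(ids), 2):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(ids)} regions"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite centroid coordinates")
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        if self.mode not in _MODES:
            raise ValueError(f"coordinate mode must be one of {_MODES}")
        known = set(ids)
        edges = set()
        for pair in self.adjacency:
            a, b = pair
            if a == b:
                raise ValueError(f"self-adjacency for region {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"adjacency references unknown region in {pair}")
            edges.add(_norm_pair(a, b))
        object.__setattr__(self, "adjacency", frozenset(edges))

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region {region_id!r}") from None

    def neighbors(self, region_id: str) -> tuple[str, ...]:
        """Adjacent region ids, sorted."""
        if region_id not in self.region_ids:
            raise KeyError(f"unknown region {region_id!r}")
        out = set()
        for a, b in self.adjacency:
            if a == region_id:
                out.add(b)
            elif b == region_id:
                out.add(a)
        return tuple(sorted(out))

    def neighbor_sets(self) -> dict[str, set[str]]:
        """Adjacency as a dict of neighbor sets (fast repeated lookup)."""
        out: dict[str, set[str]] = {r: set() for r in self.region_ids}
        for a, b in self.adjacency:
            out[a].add(b)
            out[b].add(a)
        return out

    def is_connected(self) -> bool:
        """True when the adjacency graph is connected (BFS)."""
        if self.n_regions == 0:
            return True
        nbrs = self.neighbor_sets()
        seen = {self.region_ids[0]}
        stack = [self.region_ids[0]]
        while stack:
            for v in nbrs[stack.pop()]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_regions


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise centroid distances; symmetric with a zero diagonal."""

    region_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.region_ids)
        if vals.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("distances must be finite and nonnegative")
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def between(self, a: str, b: str) -> float:
        i = self.region_ids.index(a)
        j = self.region_ids.index(b)
        return float(self.values[i, j])


def _open_source(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_coordinates(source, mode: str = PLANAR) -> RegionMap:
    """Read a whitespace-delimited coordinates file: ``id x y`` per line.

    Blank lines and lines starting with ``#`` are ignored.  In ``latlong``
    mode the two coordinate columns are latitude then longitude.

    Raises
    ------
    ValueError
        On a malformed line (with its line number) or a duplicate region id.
    """
    if mode not in _MODES:
        raise ValueError(f"coordinate mode must be one of {_MODES}")
    stream, close = _open_source(source)
    ids: list[str] = []
    xy: list[tuple[float, float]] = []
    seen: set[str] = set()
    try:
        for lineno, raw in enumerate(stream, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"line {lineno}: expected 'id x y', got {len(parts)} fields"
                )
            rid, xs, ys = parts
            try:
                x, y = float(xs), float(ys)
            except ValueError:
                raise ValueError(f"line {lineno}: non-numeric coordinate") from None
            if rid in seen:
                raise ValueError(f"line {lineno}: duplicate region id {rid!r}")
            seen.add(rid)
            ids.append(rid)
            xy.append((x, y))
    finally:
        if close:
            stream.close()
    return RegionMap(tuple(ids), np.array(xy, dtype=float).reshape(-1, 2), mode=mode)


def write_coordinates(region_map: RegionMap, dest) -> None:
    """Write the coordinates file read back by :func:`read_coordinates`.

    Uses ``repr`` formatting so a write/read round trip reproduces every
    coordinate bit-exactly.
    """
    stream, close = (open(dest, "w", encoding="utf-8"), True) if isinstance(
        dest, (str, Path)
    ) else (dest, False)
    try:
        for rid, (x, y) in zip(region_map.region_ids, region_map.coords):
            stream.write(f"{rid} {float(x)!r} {float(y)!r}\n")
    finally:
        if close:
            stream.close()


def distances(region_map: RegionMap) -> DistanceMatrix:
    """Pairwise centroid distances.

    Planar mode: Euclidean distance in the coordinate units.  Lat/long mode:
    great-circle distance (spherical law of cosines, mean Earth radius
    6371.0 km), in kilometres.
    """
    c = region_map.coords
    if region_map.mode == PLANAR:
        diff = c[:, None, :] - c[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    else:
        lat = np.radians(c[:, 0])
        lon = np.radians(c[:, 1])
        cosang = np.sin(lat)[:, None] * np.sin(lat)[None, :] + np.cos(lat)[
            :, None
        ] * np.cos(lat)[None, :] * np.cos(lon[:, None] - lon[None, :])
        d = EARTH_RADIUS_KM * np.arccos(np.clip(cosang, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against rounding
    return DistanceMatrix(region_map.region_ids, d)


def build_adjacency(
    region_map: RegionMap, method: str = "delaunay", *, k: int | None = None
) -> RegionMap:
    """Return a copy of *region_map* with adjacency derived from centroids.

    ``delaunay`` links regions sharing a Delaunay edge (points are processed
    in lexicographic region-id order so co-circular tie-breaking is
    reproducible).  ``knn`` takes the union of each region's directed links
    to its ``k`` nearest neighbors and symmetrizes it; distance ties are
    broken by lexicographic region id.
    """
    n = region_map.n_regions
    if method == "delaunay":
        if n < 3:
            raise ValueError("delaunay adjacency needs at least 3 regions")
        order = sorted(range(n), key=lambda i: region_map.region_ids[i])
        pts = region_map.coords[order]
        try:
            tri = Delaunay(pts)
        except QhullError as exc:
            raise ValueError(
                "degenerate geometry (collinear centroids?) for delaunay adjacency"
            ) from exc
        edges: set[tuple[str, str]] = set()
        for simplex in tri.simplices:
            for i in range(3):
                a = region_map.region_ids[order[simplex[i]]]
                b = region_map.region_ids[order[simplex[(i + 1) % 3]]]
                edges.add(_norm_pair(a, b))
        return replace(region_map, adjacency=frozenset(edges))
    if method == "knn":
        if k is None or k < 1:
            raise ValueError("knn adjacency requires k >= 1")
        if k >= n:
            raise ValueError(f"k={k} must be smaller than the region count {n}")
        dm = distances(region_map).values
        ids = region_map.region_ids
        edges = set()
        for i in range(n):
            ranked = sorted(
                (j for j in range(n) if j != i), key=lambda j: (dm[i, j], ids[j])
            )
            for j in ranked[:k]:
                edges.add(_norm_pair(ids[i], ids[j]))
        return replace(region_map, adjacency=frozenset(edges))
    raise ValueError(f"unknown adjacency method {method!r}")


def exclude_regions(region_map: RegionMap, excluded: Iterable[str]) -> RegionMap:
    """Drop regions (and incident adjacency) before any analysis.

    Unknown ids raise so configuration typos cannot silently keep a region.
    """
    excl = set(excluded)
    if not excl:
        return region_map
    unknown = excl - set(region_map.region_ids)
    if unknown:
        raise KeyError(f"cannot exclude unknown regions: {sorted(unknown)}")
    keep = [i for i, r in enumerate(region_map.region_ids) if r not in excl]
    ids = tuple(region_map.region_ids[i] for i in keep)
    coords = region_map.coords[keep]
    adj = frozenset(
        p for p in region_map.adjacency if p[0] not in excl and p[1] not in excl
    )
    return RegionMap(ids, coords, mode=region_map.mode, adjacency=adj)


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two lat/long points, in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    cosang = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return EARTH_RADIUS_KM * math.acos(min(1.0, max(-1.0, cosang)))
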