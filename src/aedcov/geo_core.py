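"""Coordinate handling and distance computation in metres.

Two coordinate modes are supported:

``geographic``
    WGS84 longitude/latitude in decimal degrees; distances are great-circle
    (haversine) on a sphere of mean radius 6,371,000 m.
``planar``
    x/y in metres; distances are Euclidean.

All points participating in one computation must share a mode.  Distances
are two-dimensional throughout (building height is ignored).  The
brute-force pairwise scan is the contractual definition of every
nearest/within query; vectorised numpy code is used for speed but must
agree with it exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

GEOGRAPHIC = "geographic"
PLANAR = "planar"


class GeoModeError(ValueError):
    """Raised when points with different coordinate modes are combined."""


class NoTargetsError(ValueError):
    """Raised when a nearest-neighbour query is made against no targets."""


@dataclass(frozen=True)
class GeoPoint:
    """A point location: (lon, lat) degrees or (x, y) metres.

    Parameters
    ----------
    lon : float
        Longitude in decimal degrees east (geographic) or x in metres (planar).
    lat : float
        Latitude in decimal degrees north (geographic) or y in metres (planar).
    mode : str
        Either ``"geographic"`` (default) or ``"planar"``.
    """

    lon: float
    lat: float
    mode: str = GEOGRAPHIC

    def __post_init__(self) -> None:
        if self.mode not in (GEOGRAPHIC, PLANAR):
            raise ValueError(f"unknown coordinate mode: {self.mode!r}")
        if not (math.isfinite(self.lon) and math.isfinite(self.lat)):
            raise ValueError(f"non-finite coordinates: ({self.lon}, {self.lat})")
        if self.mode == GEOGRAPHIC:
            if not -180.0 <= self.lon <= 180.0:
                raise ValueError(f"longitude {self.lon} outside [-180, 180]")
            if not -90.0 <= self.lat <= 90.0:
                raise ValueError(f"latitude {self.lat} outside [-90, 90]")


def _check_same_mode(points: Iterable[GeoPoint]) -> str:
    mode = None
    for p in points:
        if mode is None:
            mode = p.mode
        elif p.mode != mode:
            raise GeoModeError(
                f"mixed coordinate modes in one computation: {mode!r} vs {p.mode!r}"
            )
    if mode is None:
        raise ValueError("no points given")
    return mode


def _haversine_m(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres; accepts scalars or numpy arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float)) for v in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def distance_m(a: GeoPoint, b: GeoPoint) -> float:
    """Straight-line distance between two points, in metres.

    Geographic mode uses the haversine great-circle distance with mean
    Earth radius 6,371,000 m; planar mode uses Euclidean distance.

    Raises
    ------
    GeoModeError
        If ``a`` and ``b`` do not share a coordinate mode.
    """
    mode = _check_same_mode((a, b))
    if mode == PLANAR:
        return math.hypot(a.lon - b.lon, a.lat - b.lat)
    return float(_haversine_m(a.lon, a.lat, b.lon, b.lat))


def _coords(points: Sequence[GeoPoint]) -> np.ndarray:
    return np.array([(p.lon, p.lat) for p in points], dtype=float).reshape(-1, 2)


def distances_to(p: GeoPoint, targets: Sequence[GeoPoint]) -> np.ndarray:
    """Vector of distances from ``p`` to each target, in metres."""
    mode = _check_same_mode([p, *targets])
    t = _coords(targets)
    if mode == PLANAR:
        return np.hypot(t[:, 0] - p.lon, t[:, 1] - p.lat)
    return _haversine_m(p.lon, p.lat, t[:, 0], t[:, 1])


def distance_matrix(sources: Sequence[GeoPoint], targets: Sequence[GeoPoint]) -> np.ndarray:
    """Dense (n_sources, n_targets) matrix of distances in metres."""
    mode = _check_same_mode([*sources, *targets])
    s = _coords(sources)
    t = _coords(targets)
    if mode == PLANAR:
        return np.hypot(
            s[:, 0][:, None] - t[:, 0][None, :],
            s[:, 1][:, None] - t[:, 1][None, :],
        )
    return _haversine_m(
        s[:, 0][:, None], s[:, 1][:, None], t[:, 0][None, :], t[:, 1][None, :]
    )


def nearest_target(p: GeoPoint, targets: Sequence[GeoPoint]) -> tuple[int, float]:
    """Index and distance (m) of the nearest target.

    Ties are broken deterministically by the lowest target index.

    Raises
    ------
    NoTargetsError
        If ``targets`` is empty ("no AEDs registered" is an explicit error,
        never an infinite distance).
    """
    if len(targets) == 0:
        raise NoTargetsError("no targets registered: nearest distance is undefined")
    d = distances_to(p, targets)
    idx = int(np.argmin(d))  # argmin returns the first minimum -> lowest index
    return idx, float(d[idx])


def points_within(p: GeoPoint, targets: Sequence[GeoPoint], r: float) -> set[int]:
    """Indices of targets strictly within ``r`` metres of ``p``.

    The boundary is strict: a target at exactly ``r`` is excluded.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if len(targets) == 0:
        return set()
    d = distances_to(p, targets)
    return set(np.flatnonzero(d < r).tolist())
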