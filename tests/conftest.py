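"""Shared fixtures and brute-force oracles.

The scalar pairwise scan (python loop over ``distance_m``) is the
contractual definition of every nearest/within query; vectorised
implementations are tested for exact agreement with it.
"""

from __future__ import annotations

import numpy as np
import pytest

from aedcov.coverage import CoverageResult, NearestAed
from aedcov.geo_core import GEOGRAPHIC, PLANAR, GeoPoint, distance_m
from aedcov.records import AedRecord, OhcaRecord


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_nearest(p: GeoPoint, targets) -> tuple[int, float]:
    best_i, best_d = 0, distance_m(p, targets[0])
    for i, t in enumerate(targets[1:], start=1):
        d = distance_m(p, t)
        if d < best_d:
            best_i, best_d = i, d
    return best_i, best_d


def brute_within(p: GeoPoint, targets, r: float) -> set[int]:
    return {i for i, t in enumerate(targets) if distance_m(p, t) < r}


def brute_disk_counts(candidates, points, r: float) -> dict[int, int]:
    return {
        i: sum(1 for q in points if distance_m(c, q) < r)
        for i, c in enumerate(candidates)
    }


# ---------------------------------------------------------------------------
# random instance helpers


def random_points(rng: np.random.Generator, n: int, mode: str = PLANAR):
    if mode == PLANAR:
        xy = rng.uniform(0, 5000, size=(n, 2))
        return [GeoPoint(float(x), float(y), PLANAR) for x, y in xy]
    lon = rng.uniform(6.0, 7.0, size=n)
    lat = rng.uniform(46.0, 47.0, size=n)
    return [GeoPoint(float(a), float(b), GEOGRAPHIC) for a, b in zip(lon, lat)]


def make_ohcas(points, stratum="urban", location_type="home", prefix="o"):
    return [
        OhcaRecord(id=f"{prefix}{i:04d}", point=p, stratum=stratum,
                   location_type=location_type)
        for i, p in enumerate(points)
    ]


def make_aeds(points, ownership="public", available=True, prefix="a"):
    return [
        AedRecord(id=f"{prefix}{i:04d}", point=p, ownership=ownership,
                  available_24_7=available)
        for i, p in enumerate(points)
    ]


def counts_coverage(label_counts: dict[str, tuple[int, int]], group_field: str,
                    radius_m: float = 100.0):
    """Fabricate (ohcas, CoverageResult) realising given (covered, total) counts.

    ``group_field`` is "stratum" or "location_type"; covered events sit at
    50 m from their nearest AED, uncovered at 150 m.
    """
    ohcas, per = [], {}
    i = 0
    for label, (n_cov, n_tot) in label_counts.items():
        for j in range(n_tot):
            oid = f"o{i:05d}"
            i += 1
            kw = {"stratum": "urban", "location_type": "home", group_field: label}
            ohcas.append(OhcaRecord(id=oid, point=GeoPoint(0, 0, PLANAR), **kw))
            covered = j < n_cov
            per[oid] = NearestAed("a0", 50.0 if covered else 150.0, covered)
    result = CoverageResult(
        per_ohca=per,
        n_total=len(per),
        n_covered=sum(1 for v in per.values() if v.covered),
        radius_m=radius_m,
    )
    return ohcas, result


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
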