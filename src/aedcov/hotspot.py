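"""Uncovered-OHCA hotspot detection and greedy AED placement.

A hotspot is a location with at least ``k`` (default 5) uncovered OHCAs
strictly within the coverage radius and no AED strictly within that
radius.  Detection and placement are combined in a deterministic greedy
loop: repeatedly place an AED at the candidate covering the most
still-uncovered OHCAs, stopping when the best candidate would cover fewer
than ``k``.  Placed AEDs immediately suppress candidates within the
radius, so no two proposals fall in one disk.

Candidate sites default to the uncovered OHCA locations themselves
(``ohca_points``); a regular ``grid`` over the OHCA bounding box is also
supported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geo_core
from .coverage import CoverageResult, compute_coverage, eligible_aeds, DEFAULT_RADIUS_M
from .geo_core import GeoPoint, PLANAR
from .records import AedRecord, OhcaRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_OHCA = 5


@dataclass(frozen=True)
class Hotspot:
    """A proposed AED site with the uncovered OHCAs it would newly cover."""

    center: GeoPoint
    member_ohca_ids: frozenset[str]

    @property
    def n_members(self) -> int:
        return len(self.member_ohca_ids)


@dataclass
class PlacementPlan:
    """Ordered greedy placements; newly-covered sets are pairwise disjoint."""

    placements: list[Hotspot] = field(default_factory=list)
    radius_m: float = DEFAULT_RADIUS_M
    min_ohca: int = DEFAULT_MIN_OHCA

    @property
    def total_newly_covered(self) -> int:
        return sum(p.n_members for p in self.placements)

    def all_newly_covered_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for p in self.placements:
            out |= p.member_ohca_ids
        return frozenset(out)


def uncovered_density(
    ohcas: Sequence[OhcaRecord],
    coverage: CoverageResult,
    candidates: Sequence[GeoPoint],
    r: float = DEFAULT_RADIUS_M,
) -> dict[int, int]:
    """Number of uncovered OHCAs strictly within ``r`` of each candidate.

    Keys are candidate indices; an empty candidate list yields an empty map.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if not candidates:
        return {}
    unc_pts = [o.point for o in ohcas if not coverage.per_ohca[o.id].covered]
    if not unc_pts:
        return {i: 0 for i in range(len(candidates))}
    d = geo_core.distance_matrix(list(candidates), unc_pts)
    counts = (d < r).sum(axis=1)
    return {i: int(c) for i, c in enumerate(counts)}


def _grid_candidates(points: Sequence[GeoPoint], spacing_m: float) -> list[GeoPoint]:
    """Regular grid spanning the bounding box of ``points`` at ~spacing_m."""
    if spacing_m <= 0:
        raise ValueError("grid spacing must be positive")
    xs = [p.lon for p in points]
    ys = [p.lat for p in points]
    mode = points[0].mode
    if mode == PLANAR:
        dx = dy = spacing_m
    else:
        # degree steps equivalent to spacing_m at the box's mid-latitude
        mid_lat = (min(ys) + max(ys)) / 2.0
        m_per_deg = 2 * math.pi * geo_core.EARTH_RADIUS_M / 360.0
        dy = spacing_m / m_per_deg
        dx = spacing_m / (m_per_deg * max(math.cos(math.radians(mid_lat)), 1e-9))
    gx = np.arange(min(xs), max(xs) + dx, dx)
    gy = np.arange(min(ys), max(ys) + dy, dy)
    return [GeoPoint(float(x), float(y), mode) for y in gy for x in gx]


def find_hotspots_greedy(
    ohcas: Sequence[OhcaRecord],
    aeds: Sequence[AedRecord],
    r: float = DEFAULT_RADIUS_M,
    k: int = DEFAULT_MIN_OHCA,
    candidate_mode: str = "ohca_points",
    grid_spacing_m: float | None = None,
) -> PlacementPlan:
    """Greedy maximal-coverage AED placement over uncovered-OHCA hotspots.

    Each iteration picks the live candidate covering the most uncovered
    OHCAs (ties: smallest mean distance to its members, then lowest
    candidate index), stops when the best count drops below ``k``, and
    otherwise places an AED there, marking its members covered and
    suppressing candidates within ``r``.  Deterministic for fixed inputs;
    an empty plan is a valid result.
    """
    if candidate_mode not in ("ohca_points", "grid"):
        raise ValueError(f"unknown candidate_mode: {candidate_mode!r}")
    if k < 1:
        raise ValueError("k must be >= 1")
    plan = PlacementPlan(radius_m=r, min_ohca=k)
    usable = eligible_aeds(aeds)
    cov = compute_coverage(ohcas, usable, radius_m=r)
    unc = [o for o in ohcas if not cov.per_ohca[o.id].covered]
    if not unc:
        return plan

    if candidate_mode == "ohca_points":
        candidates = [o.point for o in unc]
    else:
        spacing = grid_spacing_m if grid_spacing_m is not None else r / 2.0
        candidates = _grid_candidates([o.point for o in unc], spacing)
    if not candidates:
        return plan

    unc_pts = [o.point for o in unc]
    dmat = geo_core.distance_matrix(candidates, unc_pts)  # candidates x uncovered
    cover_sets = [set(np.flatnonzero(dmat[i] < r).tolist()) for i in range(len(candidates))]

    alive = np.ones(len(candidates), dtype=bool)
    if usable:
        d_aed = geo_core.distance_matrix(candidates, [a.point for a in usable])
        alive &= ~(d_aed < r).any(axis=1)  # no existing AED strictly within r

    remaining: set[int] = set(range(len(unc)))
    while True:
        best_i = -1
        best_cnt = -1
        best_mean = math.inf
        for i in range(len(candidates)):
            if not alive[i]:
                continue
            members = cover_sets[i] & remaining
            cnt = len(members)
            if cnt < k or cnt < best_cnt:
                continue
            mean_d = float(np.mean(dmat[i, sorted(members)])) if members else math.inf
            if cnt > best_cnt or (cnt == best_cnt and mean_d < best_mean - 1e-12):
                best_i, best_cnt, best_mean = i, cnt, mean_d
        if best_i < 0:
            break
        members = cover_sets[best_i] & remaining
        center = candidates[best_i]
        plan.placements.append(
            Hotspot(center=center, member_ohca_ids=frozenset(unc[j].id for j in members))
        )
        logger.debug(
            "placement %d at (%.1f, %.1f): %d newly covered",
            len(plan.placements), center.lon, center.lat, len(members),
        )
        remaining -= members
        # a placed AED suppresses every candidate within r, itself included
        dists = geo_core.distances_to(center, candidates)
        alive &= ~(dists < r)
        if not remaining:
            break
    logger.info(
        "greedy placement: %d placements, %d newly covered OHCAs",
        len(plan.placements), plan.total_newly_covered,
    )
    return plan


def apply_placements(aeds: Sequence[AedRecord], plan: PlacementPlan) -> list[AedRecord]:
    """Original AEDs plus one public 24/7 AED per placement (proposed-001, ...)."""
    out = list(aeds)
    for i, p in enumerate(plan.placements, start=1):
        out.append(
            AedRecord(
                id=f"proposed-{i:03d}",
                point=p.center,
                ownership="public",
                available_24_7=True,
            )
        )
    return out
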