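"""AED overlay detection and coverage-preserving relocation.

An *overlay* is a location with more than one AED strictly within the
coverage radius — redundant density.  ``find_relocatable`` computes an
ordered set of AEDs (public by default) that can all be removed while
leaving the covered-OHCA *set* — not just the count — exactly unchanged.
The greedy deletion rechecks removability after every removal, so mutual
backups are never both removed, and a final joint verification recomputes
coverage without the removed AEDs and asserts set equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import geo_core
from .coverage import DEFAULT_RADIUS_M, compute_coverage, eligible_aeds
from .geo_core import GeoPoint
from .records import AedRecord, OhcaRecord

logger = logging.getLogger(__name__)


@dataclass
class RelocationPlan:
    """Ordered removable AEDs with per-removal justification.

    ``per_removal`` maps each removed AED id to the OHCA ids it covered,
    all of which remain covered by surviving AEDs; ``backups`` maps it to
    the surviving AED ids that provide that backup.
    """

    removable_aed_ids: list[str] = field(default_factory=list)
    per_removal: dict[str, frozenset[str]] = field(default_factory=dict)
    backups: dict[str, frozenset[str]] = field(default_factory=dict)
    radius_m: float = DEFAULT_RADIUS_M

    @property
    def n_removable(self) -> int:
        return len(self.removable_aed_ids)


def aed_density(
    aeds: Sequence[AedRecord],
    candidates: Sequence[GeoPoint],
    r: float = DEFAULT_RADIUS_M,
) -> dict[int, int]:
    """Number of AEDs strictly within ``r`` of each candidate point.

    An overlay is flagged wherever the count exceeds 1.
    """
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    if not candidates:
        return {}
    if not aeds:
        return {i: 0 for i in range(len(candidates))}
    d = geo_core.distance_matrix(list(candidates), [a.point for a in aeds])
    counts = (d < r).sum(axis=1)
    return {i: int(c) for i, c in enumerate(counts)}


def find_relocatable(
    ohcas: Sequence[OhcaRecord],
    aeds: Sequence[AedRecord],
    r: float = DEFAULT_RADIUS_M,
    restrict_to: str = "public",
) -> RelocationPlan:
    """Greedy maximal set of AEDs removable with zero loss of OHCA coverage.

    Repeatedly scans surviving eligible AEDs in deterministic order
    (descending count of redundantly covered OHCAs, ties by ascending id)
    and removes one whose covered OHCAs are all also covered by another
    surviving AED; an AED covering zero OHCAs is trivially removable.
    Stops when no AED is removable, then verifies jointly that the
    recomputed covered set equals the original.
    """
    if restrict_to not in ("public", "all"):
        raise ValueError(f"unknown restrict_to: {restrict_to!r}")
    plan = RelocationPlan(radius_m=r)
    usable = eligible_aeds(aeds)
    if not usable:
        return plan

    ohca_pts = [o.point for o in ohcas]
    # cover_sets[i]: indices of OHCAs strictly within r of AED i
    if ohca_pts:
        dmat = geo_core.distance_matrix([a.point for a in usable], ohca_pts)
        cover_sets = [set(np.flatnonzero(dmat[i] < r).tolist()) for i in range(len(usable))]
    else:
        cover_sets = [set() for _ in usable]

    surviving = set(range(len(usable)))
    eligible_idx = {
        i for i, a in enumerate(usable) if restrict_to == "all" or a.ownership == "public"
    }
    # per-OHCA count of surviving AEDs covering it
    n_cover = np.zeros(len(ohcas), dtype=int)
    for i in surviving:
        for j in cover_sets[i]:
            n_cover[j] += 1

    while True:
        candidates = []
        for i in surviving & eligible_idx:
            redundant = sum(1 for j in cover_sets[i] if n_cover[j] >= 2)
            candidates.append((-redundant, usable[i].id, i))
        candidates.sort()
        removed = None
        for _, _, i in candidates:
            if all(n_cover[j] >= 2 for j in cover_sets[i]):
                removed = i
                break
        if removed is None:
            break
        surviving.discard(removed)
        for j in cover_sets[removed]:
            n_cover[j] -= 1
        aed = usable[removed]
        plan.removable_aed_ids.append(aed.id)
        plan.per_removal[aed.id] = frozenset(ohcas[j].id for j in cover_sets[removed])
        backup_ids = {
            usable[i].id
            for i in surviving
            if cover_sets[i] & cover_sets[removed]
        }
        plan.backups[aed.id] = frozenset(backup_ids)
        logger.debug(
            "removing AED %s (covered %d OHCAs, %d backups survive)",
            aed.id, len(cover_sets[removed]), len(backup_ids),
        )

    _verify_plan(ohcas, usable, plan, r)
    logger.info("relocation: %d AEDs removable with zero coverage loss", plan.n_removable)
    return plan


def _verify_plan(
    ohcas: Sequence[OhcaRecord],
    usable: Sequence[AedRecord],
    plan: RelocationPlan,
    r: float,
) -> None:
    """Joint check: removing every listed AED leaves the covered set identical."""
    removed = set(plan.removable_aed_ids)
    before = compute_coverage(ohcas, usable, radius_m=r).covered_ids()
    after = compute_coverage(
        ohcas, [a for a in usable if a.id not in removed], radius_m=r
    ).covered_ids()
    if before != after:
        raise AssertionError(
            "relocation plan verification failed: covered-OHCA set changed"
        )


def apply_relocation(aeds: Sequence[AedRecord], plan: RelocationPlan) -> list[AedRecord]:
    """AED list with the plan's removable AEDs deleted."""
    removed = set(plan.removable_aed_ids)
    return [a for a in aeds if a.id not in removed]
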