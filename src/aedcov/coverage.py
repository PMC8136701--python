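"""Per-OHCA coverage determination and stratified summary statistics.

An OHCA is *covered* when its nearest AED lies strictly within the
coverage radius (default 100 m).  Only AEDs available 24/7 participate.
Summaries report, per group and in total: event count, covered count,
coverage rate (%), and median / interquartile range of the nearest-AED
distance.  Percentiles use linear interpolation between order statistics;
rates and distances are rounded to one decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from . import geo_core
from .records import AedRecord, OhcaRecord, LOCATION_TYPES, STRATA

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_M = 100.0


class NearestAed(NamedTuple):
    """Nearest-AED lookup result for one OHCA."""

    aed_id: str | None
    distance_m: float | None
    covered: bool


@dataclass
class CoverageResult:
    """Per-OHCA nearest-AED distances plus aggregate covered counts."""

    per_ohca: dict[str, NearestAed]
    n_total: int
    n_covered: int
    radius_m: float = DEFAULT_RADIUS_M

    def covered_ids(self) -> frozenset[str]:
        return frozenset(oid for oid, rec in self.per_ohca.items() if rec.covered)


@dataclass(frozen=True)
class SummaryRow:
    label: str
    n_ohca: int
    n_covered: int
    coverage_rate_pct: float
    median_distance_m: float | None
    iqr_low_m: float | None
    iqr_high_m: float | None


@dataclass
class StratifiedSummary:
    """Rows of a coverage table: one per group value plus a Total row."""

    group_by: str
    rows: list[SummaryRow] = field(default_factory=list)

    def row(self, label: str) -> SummaryRow:
        for r in self.rows:
            if r.label == label:
                return r
        raise KeyError(label)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rows]


@dataclass(frozen=True)
class DeltaRow:
    label: str
    n_ohca: int
    n_covered: int
    n_covered_delta: int
    coverage_rate_pct: float
    coverage_rate_delta: float
    median_distance_m: float | None
    median_delta_m: float | None
    iqr_low_m: float | None
    iqr_low_delta_m: float | None
    iqr_high_m: float | None
    iqr_high_delta_m: float | None


@dataclass
class DeltaTable:
    group_by: str
    rows: list[DeltaRow] = field(default_factory=list)


def coverage_rate_pct(n_covered: int, n_total: int) -> float:
    """Coverage rate as a percentage rounded to one decimal."""
    if n_total == 0:
        return 0.0
    return round(100.0 * n_covered / n_total, 1)


def eligible_aeds(aeds: Sequence[AedRecord]) -> list[AedRecord]:
    """AEDs that participate in coverage: those available 24/7."""
    kept = [a for a in aeds if a.available_24_7]
    dropped = len(aeds) - len(kept)
    if dropped:
        logger.info("dropping %d AEDs not available 24/7", dropped)
    return kept


def compute_coverage(
    ohcas: Sequence[OhcaRecord],
    aeds: Sequence[AedRecord],
    radius_m: float = DEFAULT_RADIUS_M,
) -> CoverageResult:
    """Nearest-AED distance and covered flag for every OHCA.

    With no eligible AED, every OHCA gets a ``None`` distance and is
    uncovered (a warning is logged); an empty OHCA list yields an empty
    result.
    """
    if radius_m <= 0:
        raise ValueError(f"radius_m must be positive, got {radius_m}")
    usable = eligible_aeds(aeds)
    per_ohca: dict[str, NearestAed] = {}
    if not usable:
        if ohcas:
            logger.warning("no AEDs registered: all %d OHCAs uncovered", len(ohcas))
        for o in ohcas:
            per_ohca[o.id] = NearestAed(None, None, False)
        return CoverageResult(per_ohca, n_total=len(ohcas), n_covered=0, radius_m=radius_m)

    points = [a.point for a in usable]
    for o in ohcas:
        idx, dist = geo_core.nearest_target(o.point, points)
        per_ohca[o.id] = NearestAed(usable[idx].id, dist, dist < radius_m)
    n_covered = sum(1 for rec in per_ohca.values() if rec.covered)
    return CoverageResult(per_ohca, n_total=len(ohcas), n_covered=n_covered, radius_m=radius_m)


def _quantiles(distances: list[float]) -> tuple[float | None, float | None, float | None]:
    if not distances:
        return None, None, None
    q25, med, q75 = np.percentile(np.asarray(distances, dtype=float), [25, 50, 75])
    return round(float(med), 1), round(float(q25), 1), round(float(q75), 1)


_GROUP_ORDERS = {"stratum": list(STRATA), "location_type": list(LOCATION_TYPES)}


def _group_label(ohca: OhcaRecord, group_by: str) -> str:
    return getattr(ohca, group_by)


def summarize(
    coverage: CoverageResult,
    ohcas: Sequence[OhcaRecord],
    group_by: str = "none",
) -> StratifiedSummary:
    """Build the coverage table for ``group_by`` in {stratum, location_type, none}.

    Every OHCA id in ``coverage`` must appear in ``ohcas``.  Groups with
    zero OHCAs are omitted (and logged).  A ``Total`` row aggregates all
    records.
    """
    if group_by not in ("stratum", "location_type", "none"):
        raise ValueError(f"unknown group_by: {group_by!r}")
    by_id = {o.id: o for o in ohcas}
    missing = [oid for oid in coverage.per_ohca if oid not in by_id]
    if missing:
        raise ValueError(f"coverage references unknown OHCA ids: {missing[:5]}")

    summary = StratifiedSummary(group_by=group_by)
    if group_by != "none":
        for label in _GROUP_ORDERS[group_by]:
            ids = [oid for oid in coverage.per_ohca if _group_label(by_id[oid], group_by) == label]
            if not ids:
                logger.info("summary group %r has zero OHCAs; row omitted", label)
                continue
            summary.rows.append(_make_row(label, ids, coverage))
    all_ids = list(coverage.per_ohca)
    summary.rows.append(_make_row("Total", all_ids, coverage))
    return summary


def _make_row(label: str, ids: list[str], coverage: CoverageResult) -> SummaryRow:
    n = len(ids)
    n_cov = sum(1 for oid in ids if coverage.per_ohca[oid].covered)
    dists = [coverage.per_ohca[oid].distance_m for oid in ids]
    dists = [d for d in dists if d is not None]
    med, q25, q75 = _quantiles(dists)
    return SummaryRow(
        label=label,
        n_ohca=n,
        n_covered=n_cov,
        coverage_rate_pct=coverage_rate_pct(n_cov, n),
        median_distance_m=med,
        iqr_low_m=q25,
        iqr_high_m=q75,
    )


def _delta(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return round(b - a, 1)


def coverage_delta(before: StratifiedSummary, after: StratifiedSummary) -> DeltaTable:
    """Per-row differences between two summaries with identical groupings."""
    if before.group_by != after.group_by or before.labels != after.labels:
        raise ValueError(
            f"mismatched groupings: {before.group_by}/{before.labels} "
            f"vs {after.group_by}/{after.labels}"
        )
    table = DeltaTable(group_by=before.group_by)
    for b, a in zip(before.rows, after.rows):
        table.rows.append(
            DeltaRow(
                label=a.label,
                n_ohca=a.n_ohca,
                n_covered=a.n_covered,
                n_covered_delta=a.n_covered - b.n_covered,
                coverage_rate_pct=a.coverage_rate_pct,
                coverage_rate_delta=round(a.coverage_rate_pct - b.coverage_rate_pct, 1),
                median_distance_m=a.median_distance_m,
                median_delta_m=_delta(b.median_distance_m, a.median_distance_m),
                iqr_low_m=a.iqr_low_m,
                iqr_low_delta_m=_delta(b.iqr_low_m, a.iqr_low_m),
                iqr_high_m=a.iqr_high_m,
                iqr_high_delta_m=_delta(b.iqr_high_m, a.iqr_high_m),
            )
        )
    return table
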