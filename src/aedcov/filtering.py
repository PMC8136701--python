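"""Inclusion/exclusion filtering of raw OHCA records with flowchart accounting.

Exclusion rules, applied in a fixed order so each excluded record is
attributed to exactly one rule:

1. ``traumatic``            — cause is traumatic
2. ``highway``              — event occurred on a highway
3. ``healthcare_facility``  — event occurred in a healthcare facility
4. ``incomplete_address``   — address could not be fully resolved
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .records import OhcaRecord

logger = logging.getLogger(__name__)

EXCLUSION_RULES = ("traumatic", "highway", "healthcare_facility", "incomplete_address")


@dataclass
class FilterReport:
    """Accounting of a filtering pass: eligible = included + Σ excluded."""

    n_eligible: int
    n_included: int
    n_excluded_by_rule: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(self.n_excluded_by_rule.values())

    def check(self) -> None:
        if self.n_included + self.n_excluded != self.n_eligible:
            raise AssertionError("filter report does not reconcile")


def _first_matching_rule(rec: OhcaRecord) -> str | None:
    if rec.cause == "traumatic":
        return "traumatic"
    if rec.setting == "highway":
        return "highway"
    if rec.setting == "healthcare_facility":
        return "healthcare_facility"
    if not rec.address_complete:
        return "incomplete_address"
    return None


def apply_inclusion_filters(
    records: list[OhcaRecord],
) -> tuple[list[OhcaRecord], FilterReport]:
    """Split records into included and excluded, with per-rule counts.

    A record is excluded iff its cause is traumatic, it occurred on a
    highway or in a healthcare facility, or its address is incomplete.
    Attribution is to the first matching rule in ``EXCLUSION_RULES`` order.
    Filtering is idempotent.
    """
    included: list[OhcaRecord] = []
    counts = {rule: 0 for rule in EXCLUSION_RULES}
    for rec in records:
        rule = _first_matching_rule(rec)
        if rule is None:
            included.append(rec)
        else:
            counts[rule] += 1
    report = FilterReport(
        n_eligible=len(records),
        n_included=len(included),
        n_excluded_by_rule=counts,
    )
    report.check()
    logger.info(
        "filtering: %d eligible, %d included, %d excluded (%s)",
        report.n_eligible,
        report.n_included,
        report.n_excluded,
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return included, report
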