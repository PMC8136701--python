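"""Record types shared across the pipeline: OHCA events and AED devices."""

from __future__ import annotations

from dataclasses import dataclass

from .geo_core import GeoPoint

STRATA = ("urban", "intermediate", "rural")
LOCATION_TYPES = ("home", "public")
CAUSES = ("cardiac", "respiratory", "other", "traumatic")
SETTINGS = ("none", "highway", "healthcare_facility")
OWNERSHIPS = ("public", "private")


@dataclass(frozen=True)
class OhcaRecord:
    """An out-of-hospital cardiac arrest event.

    ``setting`` flags circumstances that trigger exclusion (highway,
    healthcare facility); ``address_complete`` is False when the original
    address could not be fully resolved.
    """

    id: str
    point: GeoPoint
    stratum: str
    location_type: str
    cause: str = "cardiac"
    setting: str = "none"
    address_complete: bool = True

    def __post_init__(self) -> None:
        if self.stratum is not None and self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r} for OHCA {self.id}")
        if self.location_type is not None and self.location_type not in LOCATION_TYPES:
            raise ValueError(
                f"unknown location_type {self.location_type!r} for OHCA {self.id}"
            )
        if self.cause not in CAUSES:
            raise ValueError(f"unknown cause {self.cause!r} for OHCA {self.id}")
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r} for OHCA {self.id}")


@dataclass(frozen=True)
class AedRecord:
    """A fixed automated external defibrillator site."""

    id: str
    point: GeoPoint
    ownership: str = "public"
    available_24_7: bool = True

    def __post_init__(self) -> None:
        if self.ownership not in OWNERSHIPS:
            raise ValueError(f"unknown ownership {self.ownership!r} for AED {self.id}")


def check_unique_ids(records) -> None:
    """Raise ValueError if any id repeats within a dataset."""
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id: {rec.id!r}")
        seen.add(rec.id)
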