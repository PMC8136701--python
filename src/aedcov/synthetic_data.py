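"""Seeded synthetic OHCA/AED scenario generation with ground-truth labels.

Scenarios carry the statistical structure the downstream analysis assumes:
clustered OHCA incidence (a parent-offspring cluster process per stratum
band, most events at home), sparse background AEDs, plus *planted*
structures with known labels — hotspot clusters (>= k uncovered OHCAs
inside one coverage disk, no AED nearby) and AED overlays (>= 2 AEDs in
one disk).  Everything is reproducible from the spec's seed.

Planar metres are the default coordinate mode (exact geometry, trivial
oracles); geographic mode lays the same pattern around a reference
longitude/latitude for end-to-end haversine testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geo_core import EARTH_RADIUS_M, GEOGRAPHIC, PLANAR, GeoPoint
from .records import AedRecord, OhcaRecord, STRATA

_M_PER_DEG = 2 * math.pi * EARTH_RADIUS_M / 360.0


@dataclass(frozen=True)
class ClusterProcess:
    """Parent-offspring clustering parameters for one stratum band."""

    n_parents: int = 8
    dispersion_m: float = 250.0
    offspring_mean: float = 20.0


@dataclass(frozen=True)
class PlantedHotspot:
    """A cluster of OHCAs to plant inside one coverage disk, far from AEDs."""

    center: tuple[float, float]
    n_points: int = 5
    spread_m: float = 40.0


@dataclass(frozen=True)
class PlantedOverlay:
    """A group of AEDs to plant inside one coverage disk."""

    center: tuple[float, float]
    n_aeds: int = 2
    spread_m: float = 40.0


# marginal rates shaped like the study region: ~79.3% at home,
# urban-dominant strata mix ~ 1399:486:340
DEFAULT_P_HOME = 0.793
DEFAULT_STRATA_MIX = {"urban": 1399 / 2225, "intermediate": 486 / 2225, "rural": 340 / 2225}
DEFAULT_EXCLUSION_RATES = {
    "traumatic": 0.08,
    "highway": 0.02,
    "healthcare_facility": 0.10,
    "incomplete_address": 0.05,
}


@dataclass
class ScenarioSpec:
    """Full parameterisation of one synthetic scenario."""

    seed: int = 0
    region: tuple[float, float, float, float] = (0.0, 0.0, 10_000.0, 10_000.0)
    mode: str = PLANAR
    ref_lon: float = 6.63   # used only in geographic mode
    ref_lat: float = 46.52
    n_ohca: int = 200
    p_home: float = DEFAULT_P_HOME
    strata_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STRATA_MIX))
    cluster_process: dict[str, ClusterProcess] = field(
        default_factory=lambda: {s: ClusterProcess() for s in STRATA}
    )
    n_background_aeds: int = 30
    aed_p_public: float = 0.6
    aed_p_24_7: float = 1.0
    planted_hotspots: list[PlantedHotspot] = field(default_factory=list)
    planted_overlays: list[PlantedOverlay] = field(default_factory=list)
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES)
    )
    radius_m: float = 100.0

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.region
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("region must have positive extent")
        for name, p in [("p_home", self.p_home), ("aed_p_public", self.aed_p_public),
                        ("aed_p_24_7", self.aed_p_24_7), *self.exclusion_rates.items()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {name}={p} outside [0, 1]")
        if abs(sum(self.strata_mix.values()) - 1.0) > 1e-9:
            raise ValueError("strata_mix must sum to 1")
        if self.n_ohca < 0 or self.n_background_aeds < 0:
            raise ValueError("counts must be non-negative")
        for h in self.planted_hotspots:
            if h.n_points < 1 or not 0 < h.spread_m < self.radius_m:
                raise ValueError(f"invalid planted hotspot: {h}")
        for o in self.planted_overlays:
            if o.n_aeds < 2 or not 0 < o.spread_m < self.radius_m:
                raise ValueError(f"invalid planted overlay: {o}")
        self._check_separation()

    def _check_separation(self) -> None:
        """Hotspot centres must be >= 2r + eps from each other, from overlay
        centres, and inside the region with margin for their spread."""
        r = self.radius_m
        min_sep = 2 * r + 1.0
        xmin, ymin, xmax, ymax = self.region
        centers = [h.center for h in self.planted_hotspots]
        for h in self.planted_hotspots:
            cx, cy = h.center
            if not (xmin + h.spread_m <= cx <= xmax - h.spread_m
                    and ymin + h.spread_m <= cy <= ymax - h.spread_m):
                raise ValueError(f"planted hotspot at {h.center} does not fit region")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if math.dist(centers[i], centers[j]) < min_sep:
                    raise ValueError(
                        f"planted hotspots {centers[i]} and {centers[j]} closer than {min_sep} m"
                    )
            for o in self.planted_overlays:
                if math.dist(centers[i], o.center) < min_sep:
                    raise ValueError(
                        f"planted hotspot {centers[i]} within {min_sep} m of overlay {o.center}"
                    )
        if (xmax - xmin) * (ymax - ymin) < len(centers) * min_sep ** 2:
            raise ValueError("region too small for the requested planted hotspots")


@dataclass
class ScenarioTruth:
    """Ground-truth labels for every generated record."""

    hotspot_membership: dict[str, int | None] = field(default_factory=dict)
    overlay_membership: dict[str, int | None] = field(default_factory=dict)
    exclusion_label: dict[str, str | None] = field(default_factory=dict)


def _to_point(x: float, y: float, spec: ScenarioSpec) -> GeoPoint:
    if spec.mode == PLANAR:
        return GeoPoint(x, y, PLANAR)
    lon = spec.ref_lon + x / (_M_PER_DEG * math.cos(math.radians(spec.ref_lat)))
    lat = spec.ref_lat + y / _M_PER_DEG
    return GeoPoint(lon, lat, GEOGRAPHIC)


def _strata_bands(spec: ScenarioSpec) -> dict[str, tuple[float, float]]:
    """Vertical bands of the region, one per stratum, width ~ strata_mix."""
    xmin, _, xmax, _ = spec.region
    width = xmax - xmin
    bands = {}
    x0 = xmin
    for s in STRATA:
        w = width * spec.strata_mix[s]
        bands[s] = (x0, x0 + w)
        x0 += w
    return bands


def _stratum_of(x: float, bands: dict[str, tuple[float, float]]) -> str:
    for s in STRATA:
        lo, hi = bands[s]
        if lo <= x < hi:
            return s
    return STRATA[-1]


def _draw_exclusion_marks(rng: np.random.Generator, rates: dict[str, float]):
    """Independent draws of (cause, setting, address_complete); returns the
    first-matching exclusion rule (or None) alongside the marks."""
    cause = "traumatic" if rng.random() < rates.get("traumatic", 0.0) else "cardiac"
    setting = "none"
    if rng.random() < rates.get("highway", 0.0):
        setting = "highway"
    elif rng.random() < rates.get("healthcare_facility", 0.0):
        setting = "healthcare_facility"
    complete = rng.random() >= rates.get("incomplete_address", 0.0)
    if cause == "traumatic":
        label = "traumatic"
    elif setting in ("highway", "healthcare_facility"):
        label = setting
    elif not complete:
        label = "incomplete_address"
    else:
        label = None
    return cause, setting, complete, label


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[list[OhcaRecord], list[AedRecord], ScenarioTruth]:
    """Generate one scenario; fully reproducible from ``spec.seed``.

    OHCAs come from the per-stratum parent-offspring process plus the
    planted hotspot clusters; AEDs are uniform background (kept >= 2r + 1 m
    away from planted hotspot centres so planted members stay uncovered)
    plus the planted overlay groups.  Raises ValueError when the planting
    constraints are infeasible in the given region.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    xmin, ymin, xmax, ymax = spec.region
    bands = _strata_bands(spec)
    r = spec.radius_m
    keepout = [h.center for h in spec.planted_hotspots]
    min_sep = 2 * r + 1.0

    truth = ScenarioTruth()
    ohcas: list[OhcaRecord] = []
    oid = 0

    # background OHCAs: stratified parent-offspring clusters
    n_per = rng.multinomial(spec.n_ohca, [spec.strata_mix[s] for s in STRATA])
    for s, n_s in zip(STRATA, n_per):
        if n_s == 0:
            continue
        lo, hi = bands[s]
        proc = spec.cluster_process[s]
        n_parents = max(1, proc.n_parents)
        px = rng.uniform(lo, hi, size=n_parents)
        py = rng.uniform(ymin, ymax, size=n_parents)
        parent_idx = rng.integers(0, n_parents, size=n_s)
        dx, dy = rng.normal(0.0, proc.dispersion_m, size=(2, n_s))
        xs = np.clip(px[parent_idx] + dx, xmin, xmax - 1e-9)
        ys = np.clip(py[parent_idx] + dy, ymin, ymax - 1e-9)
        for x, y in zip(xs, ys):
            oid += 1
            cause, setting, complete, label = _draw_exclusion_marks(rng, spec.exclusion_rates)
            rec = OhcaRecord(
                id=f"ohca-{oid:05d}",
                point=_to_point(float(x), float(y), spec),
                stratum=_stratum_of(float(x), bands),
                location_type="home" if rng.random() < spec.p_home else "public",
                cause=cause,
                setting=setting,
                address_complete=complete,
            )
            ohcas.append(rec)
            truth.hotspot_membership[rec.id] = None
            truth.exclusion_label[rec.id] = label

    # planted hotspot clusters: always includable, always labelled
    for h_idx, h in enumerate(spec.planted_hotspots):
        cx, cy = h.center
        theta = rng.uniform(0, 2 * math.pi, size=h.n_points)
        rho = rng.uniform(0, h.spread_m, size=h.n_points)
        for t, d in zip(theta, rho):
            oid += 1
            x = cx + d * math.cos(t)
            y = cy + d * math.sin(t)
            rec = OhcaRecord(
                id=f"ohca-{oid:05d}",
                point=_to_point(x, y, spec),
                stratum=_stratum_of(x, bands),
                location_type="home" if rng.random() < spec.p_home else "public",
                cause="cardiac",
                setting="none",
                address_complete=True,
            )
            ohcas.append(rec)
            truth.hotspot_membership[rec.id] = h_idx
            truth.exclusion_label[rec.id] = None

    aeds: list[AedRecord] = []
    aid = 0

    # background AEDs: uniform, rejected near planted hotspot centres
    max_tries = 1000 * max(1, spec.n_background_aeds)
    tries = 0
    while len(aeds) < spec.n_background_aeds:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                "cannot place background AEDs: region too crowded by planted "
                "hotspot keep-out zones"
            )
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if any(math.dist((x, y), c) < min_sep for c in keepout):
            continue
        aid += 1
        rec = AedRecord(
            id=f"aed-{aid:04d}",
            point=_to_point(x, y, spec),
            ownership="public" if rng.random() < spec.aed_p_public else "private",
            available_24_7=bool(rng.random() < spec.aed_p_24_7),
        )
        aeds.append(rec)
        truth.overlay_membership[rec.id] = None

    # planted overlay AED groups
    for o_idx, o in enumerate(spec.planted_overlays):
        cx, cy = o.center
        if any(math.dist((cx, cy), c) < min_sep for c in keepout):
            raise ValueError(f"planted overlay at {o.center} inside a hotspot keep-out zone")
        theta = rng.uniform(0, 2 * math.pi, size=o.n_aeds)
        rho = rng.uniform(0, o.spread_m, size=o.n_aeds)
        for t, d in zip(theta, rho):
            aid += 1
            rec = AedRecord(
                id=f"aed-{aid:04d}",
                point=_to_point(cx + d * math.cos(t), cy + d * math.sin(t), spec),
                ownership="public",
                available_24_7=True,
            )
            aeds.append(rec)
            truth.overlay_membership[rec.id] = o_idx

    return ohcas, aeds, truth


def scenario_to_files(
    ohcas: list[OhcaRecord], aeds: list[AedRecord], path: str | Path
) -> dict[str, Path]:
    """Write a scenario as CSV and GeoJSON under ``path``; returns the files.

    Round-trip guarantee: reading the files back reproduces the records
    with coordinates to 7 decimal places.
    """
    from . import io_report  # deferred: io_report imports record types from here

    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "ohca_csv": out / "ohca.csv",
        "aed_csv": out / "aed.csv",
        "ohca_geojson": out / "ohca.geojson",
        "aed_geojson": out / "aed.geojson",
    }
    io_report.write_points_csv(ohcas, files["ohca_csv"], kind="ohca")
    io_report.write_points_csv(aeds, files["aed_csv"], kind="aed")
    io_report.write_points_geojson(ohcas, files["ohca_geojson"], kind="ohca")
    io_report.write_points_geojson(aeds, files["aed_geojson"], kind="aed")
    return files


def vaud_like_spec(seed: int = 0, n_ohca: int = 600, n_background_aeds: int = 150) -> ScenarioSpec:
    """A preset scenario shaped like the study region's marginals."""
    return ScenarioSpec(
        seed=seed,
        region=(0.0, 0.0, 20_000.0, 20_000.0),
        n_ohca=n_ohca,
        n_background_aeds=n_background_aeds,
        planted_hotspots=[
            PlantedHotspot(center=(2_000.0, 18_000.0), n_points=7, spread_m=40.0),
            PlantedHotspot(center=(4_000.0, 18_000.0), n_points=6, spread_m=40.0),
            PlantedHotspot(center=(6_000.0, 18_000.0), n_points=5, spread_m=40.0),
        ],
        planted_overlays=[
            PlantedOverlay(center=(10_000.0, 2_000.0), n_aeds=3, spread_m=50.0),
            PlantedOverlay(center=(15_000.0, 2_000.0), n_aeds=2, spread_m=40.0),
        ],
    )
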