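"""Readers/writers (CSV + GeoJSON), run configuration, and report assembly.

CSV files are RFC-4180 with named columns; GeoJSON follows RFC 7946 with
coordinates in (lon, lat) order.  Every number in the rendered text report
is re-derivable from the machine-readable frames this module emits — the
renderer does no arithmetic of its own beyond string formatting.  Decimal
separators are always points.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .coverage import DeltaTable, StratifiedSummary
from .filtering import EXCLUSION_RULES, FilterReport
from .geo_core import GEOGRAPHIC, PLANAR, GeoPoint
from .hotspot import PlacementPlan
from .overlay import RelocationPlan
from .records import (
    AedRecord,
    CAUSES,
    LOCATION_TYPES,
    OWNERSHIPS,
    OhcaRecord,
    SETTINGS,
    STRATA,
)

logger = logging.getLogger(__name__)

COORD_DECIMALS = 7

_OHCA_REQUIRED = ("id", "lon", "lat", "stratum", "location_type")
_AED_REQUIRED = ("id", "lon", "lat", "ownership")


@dataclass
class RunConfig:
    """Analysis parameters with the study defaults (r = 100 m, k = 5)."""

    radius_m: float = 100.0
    hotspot_min_ohca: int = 5
    candidate_mode: str = "ohca_points"
    grid_spacing_m: float | None = None
    public_only_relocation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")
        if self.hotspot_min_ohca < 1:
            raise ValueError("hotspot_min_ohca must be >= 1")
        if self.candidate_mode not in ("ohca_points", "grid"):
            raise ValueError(f"unknown candidate_mode {self.candidate_mode!r}")


# ---------------------------------------------------------------------------
# point readers / writers


def _fmt_coord(v: float) -> str:
    return f"{v:.{COORD_DECIMALS}f}"


def write_points_csv(records: Sequence, path: str | Path, kind: str) -> None:
    rows = []
    for rec in records:
        base = {
            "id": rec.id,
            "lon": _fmt_coord(rec.point.lon),
            "lat": _fmt_coord(rec.point.lat),
            "mode": rec.point.mode,
        }
        if kind == "ohca":
            base.update(
                stratum=rec.stratum,
                location_type=rec.location_type,
                cause=rec.cause,
                setting=rec.setting,
                address_complete=rec.address_complete,
            )
        elif kind == "aed":
            base.update(ownership=rec.ownership, available_24_7=rec.available_24_7)
        else:
            raise ValueError(f"unknown kind {kind!r}")
        rows.append(base)
    columns = (
        ["id", "lon", "lat", "mode", "stratum", "location_type", "cause",
         "setting", "address_complete"]
        if kind == "ohca"
        else ["id", "lon", "lat", "mode", "ownership", "available_24_7"]
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def _point_properties(rec, kind: str) -> dict:
    if kind == "ohca":
        return {
            "id": rec.id,
            "mode": rec.point.mode,
            "stratum": rec.stratum,
            "location_type": rec.location_type,
            "cause": rec.cause,
            "setting": rec.setting,
            "address_complete": rec.address_complete,
        }
    return {
        "id": rec.id,
        "mode": rec.point.mode,
        "ownership": rec.ownership,
        "available_24_7": rec.available_24_7,
    }


def write_points_geojson(records: Sequence, path: str | Path, kind: str) -> None:
    if kind not in ("ohca", "aed"):
        raise ValueError(f"unknown kind {kind!r}")
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [
                    round(rec.point.lon, COORD_DECIMALS),
                    round(rec.point.lat, COORD_DECIMALS),
                ],
            },
            "properties": _point_properties(rec, kind),
        }
        for rec in records
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1) + "\n"
    )


def _parse_bool(v) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {v!r}")


def _build_record(kind: str, props: dict, lon: float, lat: float):
    mode = props.get("mode", GEOGRAPHIC)
    if mode not in (GEOGRAPHIC, PLANAR):
        raise ValueError(f"unknown mode {mode!r}")
    if not (math.isfinite(lon) and math.isfinite(lat)):
        raise ValueError(f"non-finite coordinate ({lon}, {lat})")
    point = GeoPoint(float(lon), float(lat), mode)
    if kind == "ohca":
        return OhcaRecord(
            id=str(props["id"]),
            point=point,
            stratum=str(props["stratum"]),
            location_type=str(props["location_type"]),
            cause=str(props.get("cause", "cardiac")),
            setting=str(props.get("setting", "none")),
            address_complete=_parse_bool(props.get("address_complete", True)),
        )
    return AedRecord(
        id=str(props["id"]),
        point=point,
        ownership=str(props["ownership"]),
        available_24_7=_parse_bool(props.get("available_24_7", True)),
    )


def read_points_detailed(
    path: str | Path, kind: str
) -> tuple[list, list[tuple[int, str]]]:
    """Read OHCA or AED points; returns (records, rejections).

    Rejections are (line-or-feature number, message) pairs for malformed
    rows; a missing required column is fatal.  CSV and GeoJSON are
    dispatched on file extension.
    """
    if kind not in ("ohca", "aed"):
        raise ValueError(f"unknown kind {kind!r}")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".geojson", ".json"):
        return _read_geojson(path, kind)
    if suffix == ".csv":
        return _read_csv(path, kind)
    raise ValueError(f"unsupported file type {suffix!r} for {path}")


def read_points(path: str | Path, kind: str) -> list:
    """Like :func:`read_points_detailed` but logs rejections and returns records."""
    records, rejections = read_points_detailed(path, kind)
    for lineno, msg in rejections:
        logger.warning("%s line %d rejected: %s", path, lineno, msg)
    return records


def _read_csv(path: Path, kind: str) -> tuple[list, list[tuple[int, str]]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = _OHCA_REQUIRED if kind == "ohca" else _AED_REQUIRED
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    records, rejections = [], []
    for idx, row in df.iterrows():
        lineno = int(idx) + 2  # header is line 1
        try:
            lon = float(row["lon"])
            lat = float(row["lat"])
            records.append(_build_record(kind, row.to_dict(), lon, lat))
        except (ValueError, KeyError) as exc:
            rejections.append((lineno, str(exc)))
    return records, rejections


def _read_geojson(path: Path, kind: str) -> tuple[list, list[tuple[int, str]]]:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    records, rejections = [], []
    for i, feat in enumerate(doc.get("features", []), start=1):
        try:
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise ValueError(f"geometry type {geom.get('type')!r}, expected Point")
            lon, lat = geom["coordinates"][:2]
            props = feat.get("properties") or {}
            required = _OHCA_REQUIRED if kind == "ohca" else _AED_REQUIRED
            for fieldname in required:
                if fieldname in ("lon", "lat"):
                    continue
                if fieldname not in props:
                    raise ValueError(f"missing property {fieldname!r}")
            records.append(_build_record(kind, props, float(lon), float(lat)))
        except (ValueError, KeyError, TypeError, IndexError) as exc:
            rejections.append((i, str(exc)))
    return records, rejections


# ---------------------------------------------------------------------------
# tabular frames


def summary_to_frame(summary: StratifiedSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.label,
                "OHCA": r.n_ohca,
                "OHCA covered": r.n_covered,
                "Coverage rate": r.coverage_rate_pct,
                "Median distance OHCA-nearest AED (meters)": r.median_distance_m,
                "IQR low": r.iqr_low_m,
                "IQR high": r.iqr_high_m,
            }
            for r in summary.rows
        ]
    )


def delta_to_frame(delta: DeltaTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.label,
                "OHCA": r.n_ohca,
                "OHCA covered": r.n_covered,
                "OHCA covered delta": r.n_covered_delta,
                "Coverage rate": r.coverage_rate_pct,
                "Coverage rate delta": r.coverage_rate_delta,
                "Median distance OHCA-nearest AED (meters)": r.median_distance_m,
                "Median delta": r.median_delta_m,
                "IQR low": r.iqr_low_m,
                "IQR low delta": r.iqr_low_delta_m,
                "IQR high": r.iqr_high_m,
                "IQR high delta": r.iqr_high_delta_m,
            }
            for r in delta.rows
        ]
    )


def placements_to_frame(plan: PlacementPlan) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": i,
                "lon": round(p.center.lon, COORD_DECIMALS),
                "lat": round(p.center.lat, COORD_DECIMALS),
                "n_newly_covered": p.n_members,
                "newly_covered_ohca_ids": ";".join(sorted(p.member_ohca_ids)),
            }
            for i, p in enumerate(plan.placements, start=1)
        ],
        columns=["rank", "lon", "lat", "n_newly_covered", "newly_covered_ohca_ids"],
    )


def placements_to_geojson(plan: PlacementPlan, path: str | Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [
                    round(p.center.lon, COORD_DECIMALS),
                    round(p.center.lat, COORD_DECIMALS),
                ],
            },
            "properties": {
                "rank": i,
                "n_newly_covered": p.n_members,
                "newly_covered_ohca_ids": sorted(p.member_ohca_ids),
            },
        }
        for i, p in enumerate(plan.placements, start=1)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1) + "\n"
    )


def relocation_to_frame(plan: RelocationPlan) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "aed_id": aid,
                "n_ohcas_backed_up": len(plan.per_removal[aid]),
                "backup_aed_ids": ";".join(sorted(plan.backups[aid])),
            }
            for aid in plan.removable_aed_ids
        ],
        columns=["aed_id", "n_ohcas_backed_up", "backup_aed_ids"],
    )


def filter_report_to_frame(report: FilterReport) -> pd.DataFrame:
    rows = [{"stage": "eligible", "count": report.n_eligible}]
    rows += [
        {"stage": f"excluded: {rule}", "count": report.n_excluded_by_rule.get(rule, 0)}
        for rule in EXCLUSION_RULES
    ]
    rows.append({"stage": "included", "count": report.n_included})
    return pd.DataFrame(rows, columns=["stage", "count"])


# ---------------------------------------------------------------------------
# text rendering


def _fmt_opt(v, unit: str = "") -> str:
    return "-" if v is None else f"{v:.1f}{unit}"


def _fmt_delta(v, unit: str = "") -> str:
    if v is None:
        return ""
    return f" ({v:+.1f}{unit})" if isinstance(v, float) else f" ({v:+d}{unit})"


def render_summary_text(summary: StratifiedSummary, title: str) -> str:
    lines = [title, "-" * len(title)]
    header = f"{'group':<14}{'OHCA':>7}{'covered':>9}{'rate':>8}{'median':>9}  IQR"
    lines.append(header)
    for r in summary.rows:
        lines.append(
            f"{r.label:<14}{r.n_ohca:>7}{r.n_covered:>9}"
            f"{r.coverage_rate_pct:>7.1f}%{_fmt_opt(r.median_distance_m):>9}"
            f"  ({_fmt_opt(r.iqr_low_m)}; {_fmt_opt(r.iqr_high_m)})"
        )
    return "\n".join(lines)


def render_delta_text(delta: DeltaTable, title: str) -> str:
    lines = [title, "-" * len(title)]
    for r in delta.rows:
        lines.append(
            f"{r.label:<14}{r.n_ohca:>7}"
            f"  covered {r.n_covered}{_fmt_delta(r.n_covered_delta)}"
            f"  rate {r.coverage_rate_pct:.1f}%{_fmt_delta(r.coverage_rate_delta)}"
            f"  median {_fmt_opt(r.median_distance_m)}{_fmt_delta(r.median_delta_m)}"
            f"  IQR ({_fmt_opt(r.iqr_low_m)}{_fmt_delta(r.iqr_low_delta_m)};"
            f" {_fmt_opt(r.iqr_high_m)}{_fmt_delta(r.iqr_high_delta_m)})"
        )
    return "\n".join(lines)


@dataclass
class Report:
    """Assembled analysis report: plain text plus machine-readable frames."""

    text: str
    frames: dict[str, pd.DataFrame]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"report": out / "report.txt"}
        paths["report"].write_text(self.text + "\n")
        for name, frame in self.frames.items():
            paths[name] = out / f"{name}.csv"
            frame.to_csv(paths[name], index=False)
        return paths


def build_report(
    before: StratifiedSummary,
    after: StratifiedSummary | None = None,
    delta: DeltaTable | None = None,
    placement_plan: PlacementPlan | None = None,
    relocation_plan: RelocationPlan | None = None,
    filter_report: FilterReport | None = None,
) -> Report:
    """Assemble the before / after coverage report with optional plan listings."""
    frames: dict[str, pd.DataFrame] = {"summary_before": summary_to_frame(before)}
    parts: list[str] = []
    if filter_report is not None:
        frames["filter_report"] = filter_report_to_frame(filter_report)
        parts.append(
            "Inclusion filtering\n-------------------\n"
            + "\n".join(
                f"{row.stage:<30}{row.count:>7}"
                for row in frames["filter_report"].itertuples()
            )
        )
    parts.append(render_summary_text(before, "Actual situation"))
    if after is not None:
        frames["summary_after"] = summary_to_frame(after)
        if delta is not None:
            frames["delta"] = delta_to_frame(delta)
            parts.append(render_delta_text(delta, "Situation with AEDs on proposed locations"))
        else:
            parts.append(render_summary_text(after, "Situation with AEDs on proposed locations"))
    if placement_plan is not None:
        frames["placements"] = placements_to_frame(placement_plan)
        parts.append(
            f"Proposed AED placements: {len(placement_plan.placements)} "
            f"(newly covering {placement_plan.total_newly_covered} OHCAs)"
        )
    if relocation_plan is not None:
        frames["relocations"] = relocation_to_frame(relocation_plan)
        parts.append(
            f"Relocatable AEDs (zero coverage loss): {relocation_plan.n_removable}"
        )
    return Report(text="\n\n".join(parts), frames=frames)
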