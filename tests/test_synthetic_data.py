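import math

import numpy as np
import pytest

from aedcov.coverage import compute_coverage
from aedcov.geo_core import GEOGRAPHIC, PLANAR, distance_m
from aedcov.io_report import read_points
from aedcov.overlay import aed_density
from aedcov.records import check_unique_ids
from aedcov.synthetic_data import (
    PlantedHotspot,
    PlantedOverlay,
    ScenarioSpec,
    generate_scenario,
    scenario_to_files,
    vaud_like_spec,
)


def spec_with_plants(seed=0, **kw):
    defaults = dict(
        seed=seed,
        n_ohca=60,
        n_background_aeds=20,
        planted_hotspots=[
            PlantedHotspot(center=(2000.0, 8000.0), n_points=6, spread_m=40.0),
            PlantedHotspot(center=(5000.0, 8000.0), n_points=5, spread_m=40.0),
        ],
        planted_overlays=[PlantedOverlay(center=(8000.0, 1000.0), n_aeds=3, spread_m=50.0)],
    )
    defaults.update(kw)
    return ScenarioSpec(**defaults)


class TestGenerateScenario:
    def test_empty_scenario(self):
        ohcas, aeds, truth = generate_scenario(
            ScenarioSpec(n_ohca=0, n_background_aeds=0)
        )
        assert ohcas == [] and aeds == []
        assert truth.hotspot_membership == {}

    def test_same_seed_identical(self):
        a = generate_scenario(spec_with_plants(seed=42))
        b = generate_scenario(spec_with_plants(seed=42))
        assert a[0] == b[0] and a[1] == b[1]
        assert a[2].hotspot_membership == b[2].hotspot_membership

    def test_different_seed_differs(self):
        a = generate_scenario(spec_with_plants(seed=1))
        b = generate_scenario(spec_with_plants(seed=2))
        assert a[0] != b[0]

    def test_counts_and_unique_ids(self):
        spec = spec_with_plants()
        ohcas, aeds, _ = generate_scenario(spec)
        assert len(ohcas) == spec.n_ohca + 11  # background + planted members
        assert len(aeds) == spec.n_background_aeds + 3
        check_unique_ids(ohcas)
        check_unique_ids(aeds)

    def test_home_fraction_binomial_bound(self):
        spec = ScenarioSpec(seed=7, n_ohca=5000, n_background_aeds=0, p_home=0.793)
        ohcas, _, _ = generate_scenario(spec)
        frac = sum(o.location_type == "home" for o in ohcas) / len(ohcas)
        se = math.sqrt(0.793 * (1 - 0.793) / 5000)
        assert abs(frac - 0.793) < 3 * se

    def test_exclusion_labels_consistent_with_marks(self):
        ohcas, _, truth = generate_scenario(spec_with_plants(seed=5, n_ohca=400))
        from aedcov.filtering import apply_inclusion_filters

        included, report = apply_inclusion_filters(ohcas)
        planted = {oid for oid, lab in truth.exclusion_label.items() if lab is not None}
        assert report.n_excluded == len(planted)
        assert {o.id for o in included} == set(truth.exclusion_label) - planted

    def test_planted_hotspots_satisfy_predicate(self):
        spec = spec_with_plants(seed=11)
        ohcas, aeds, truth = generate_scenario(spec)
        cov = compute_coverage(ohcas, aeds, radius_m=spec.radius_m)
        for h_idx, h in enumerate(spec.planted_hotspots):
            members = [o for o in ohcas if truth.hotspot_membership[o.id] == h_idx]
            assert len(members) == h.n_points >= 5
            for m in members:
                assert not cov.per_ohca[m.id].covered
                # member within spread (< r) of the planted centre
                from aedcov.geo_core import GeoPoint

                c = GeoPoint(*h.center, PLANAR)
                assert distance_m(m.point, c) < h.spread_m + 1e-9
            # no AED strictly within r of the centre
            for a in aeds:
                assert distance_m(a.point, GeoPoint(*h.center, PLANAR)) >= spec.radius_m

    def test_planted_overlays_satisfy_predicate(self):
        spec = spec_with_plants(seed=13)
        _, aeds, truth = generate_scenario(spec)
        from aedcov.geo_core import GeoPoint

        for o_idx, o in enumerate(spec.planted_overlays):
            members = [a for a in aeds if truth.overlay_membership[a.id] == o_idx]
            assert len(members) == o.n_aeds >= 2
            counts = aed_density(aeds, [GeoPoint(*o.center, PLANAR)], r=spec.radius_m)
            assert counts[0] > 1

    def test_geographic_mode(self):
        spec = spec_with_plants(seed=3, mode=GEOGRAPHIC)
        ohcas, aeds, _ = generate_scenario(spec)
        assert all(o.point.mode == GEOGRAPHIC for o in ohcas)
        assert all(-180 <= o.point.lon <= 180 and -90 <= o.point.lat <= 90 for o in ohcas)
        # pattern spans roughly the planar region, mapped to degrees
        lats = [o.point.lat for o in ohcas]
        assert max(lats) - min(lats) < 0.2

    def test_infeasible_planting_rejected(self):
        with pytest.raises(ValueError):
            # two hotspots closer than 2r + 1
            ScenarioSpec(
                planted_hotspots=[
                    PlantedHotspot(center=(1000.0, 1000.0)),
                    PlantedHotspot(center=(1100.0, 1000.0)),
                ]
            ).validate()
        with pytest.raises(ValueError):
            ScenarioSpec(region=(0, 0, 50, 50),
                         planted_hotspots=[PlantedHotspot(center=(25.0, 25.0))]).validate()

    def test_bad_probabilities_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(p_home=1.5).validate()
        with pytest.raises(ValueError):
            ScenarioSpec(strata_mix={"urban": 0.9, "intermediate": 0.3, "rural": 0.1}).validate()

    def test_coverage_physics_calibration(self):
        # mean nearest-AED distance decreases as background AEDs double
        means = []
        for n_aeds in (10, 20, 40, 80):
            dists = []
            for seed in range(50):
                spec = ScenarioSpec(seed=seed, n_ohca=40, n_background_aeds=n_aeds)
                ohcas, aeds, _ = generate_scenario(spec)
                cov = compute_coverage(ohcas, aeds)
                dists.extend(v.distance_m for v in cov.per_ohca.values())
            means.append(np.mean(dists))
        assert means == sorted(means, reverse=True)


class TestScenarioToFiles:
    def test_round_trip(self, tmp_path):
        ohcas, aeds, _ = generate_scenario(spec_with_plants(seed=9))
        files = scenario_to_files(ohcas, aeds, tmp_path)
        for key, kind, originals in [
            ("ohca_csv", "ohca", ohcas), ("aed_csv", "aed", aeds),
            ("ohca_geojson", "ohca", ohcas), ("aed_geojson", "aed", aeds),
        ]:
            loaded = read_points(files[key], kind=kind)
            assert len(loaded) == len(originals)
            for got, want in zip(loaded, originals):
                assert got.id == want.id
                assert got.point.lon == pytest.approx(want.point.lon, abs=1e-7)
                assert got.point.lat == pytest.approx(want.point.lat, abs=1e-7)

    def test_empty_scenario_files(self, tmp_path):
        files = scenario_to_files([], [], tmp_path)
        assert read_points(files["ohca_csv"], kind="ohca") == []
        assert read_points(files["aed_geojson"], kind="aed") == []
        header = files["ohca_csv"].read_text().splitlines()[0]
        assert header.startswith("id,lon,lat")

    def test_byte_identical_for_same_seed(self, tmp_path):
        for sub in ("a", "b"):
            ohcas, aeds, _ = generate_scenario(spec_with_plants(seed=21))
            scenario_to_files(ohcas, aeds, tmp_path / sub)
        for name in ("ohca.csv", "aed.csv", "ohca.geojson", "aed.geojson"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_thousand_record_counts_preserved(self, tmp_path):
        spec = ScenarioSpec(seed=17, n_ohca=1000, n_background_aeds=100)
        ohcas, aeds, _ = generate_scenario(spec)
        files = scenario_to_files(ohcas, aeds, tmp_path)
        assert len(read_points(files["ohca_csv"], kind="ohca")) == 1000
        assert len(read_points(files["aed_csv"], kind="aed")) == 100


def test_vaud_like_preset_runs():
    ohcas, aeds, truth = generate_scenario(vaud_like_spec(seed=1))
    strata = {o.stratum for o in ohcas}
    assert strata == {"urban", "intermediate", "rural"}
    assert sum(1 for v in truth.hotspot_membership.values() if v is not None) == 18
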