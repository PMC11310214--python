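"""Binding-event detection, mode classification and local hydration tracking.

Every check runs against scripted trajectories whose ground truth is the
script itself, so detection and classification have an exact oracle.
"""

import numpy as np
import pytest

from hydrosense.errors import ValidationError
from hydrosense.hydration import (
    MolecularSystem,
    bound_fraction,
    bulk_contact_series,
    classify_mode,
    contact_area,
    detect_binding_events,
    local_region,
    local_water_contact,
)
from hydrosense.synthetic import LigandScript, TrajectoryScript, gen_trajectory


def detect_all(system, min_duration=400.0):
    events = []
    for key in system.ligand_keys():
        for ev in detect_binding_events(system, key, min_duration=min_duration):
            classify_mode(ev, system)
            events.append(ev)
    return sorted(events, key=lambda e: (e.ligand, e.start))


class TestEventDetection:
    def test_events_match_script_exactly(self, mixed_trajectory):
        script, system, truth = mixed_trajectory
        expected = [ev for ev in truth if ev["end"] - ev["start"] >= 400.0]
        events = detect_all(system)
        assert len(events) == len(expected)
        for got, want in zip(events, sorted(expected, key=lambda e: (e["ligand"], e["start"]))):
            assert got.ligand == want["ligand"]
            assert got.start == pytest.approx(want["start"], abs=system.frame_dt)
            assert got.end == pytest.approx(want["end"], abs=system.frame_dt)
            assert got.mode == want["mode"]

    def test_short_interval_below_threshold_dropped(self, mixed_trajectory):
        _, system, truth = mixed_trajectory
        short = [ev for ev in truth if ev["end"] - ev["start"] < 400.0]
        assert short, "fixture must contain a sub-threshold interval"
        events = detect_all(system)
        for ev in events:
            assert ev.duration >= 400.0

    def test_gap_longer_than_tolerance_splits_events(self, mixed_trajectory):
        _, system, _ = mixed_trajectory
        events = detect_binding_events(
            system, "dopamine:0", min_duration=100.0, gap_tolerance=50.0
        )
        assert len(events) == 3  # all scripted intervals, none merged

    def test_large_gap_tolerance_merges_events(self, mixed_trajectory):
        _, system, _ = mixed_trajectory
        events = detect_binding_events(
            system, "dopamine:0", min_duration=400.0, gap_tolerance=400.0
        )
        assert len(events) == 1
        assert events[0].start == pytest.approx(100.0)
        assert events[0].end == pytest.approx(1890.0)

    def test_surface_event_collects_contact_carbons(self, mixed_trajectory):
        _, system, _ = mixed_trajectory
        events = detect_all(system)
        surface = [e for e in events if e.mode == 1]
        corona = [e for e in events if e.mode == 2]
        assert all(len(e.contact_carbons) > 0 for e in surface)
        assert all(len(e.contact_carbons) == 0 for e in corona)

    def test_no_ligand_never_bound(self):
        script = TrajectoryScript(n_frames=30, frame_dt=10.0,
                                  ligands=[LigandScript("dopamine", [])], n_waters=50)
        system, truth = gen_trajectory(script, seed=1)
        assert truth == []
        assert detect_binding_events(system, "dopamine:0", min_duration=10.0) == []

    def test_min_duration_below_spacing_warns(self, mixed_trajectory):
        _, system, _ = mixed_trajectory
        with pytest.warns(UserWarning, match="frame spacing"):
            detect_binding_events(system, "dopamine:0", min_duration=5.0)

    def test_time_rescaling_invariance(self, mixed_trajectory):
        """Scaling all frame times (and ns thresholds) leaves events fixed."""
        _, system, _ = mixed_trajectory
        scaled = MolecularSystem(
            coords=system.coords, roles=system.roles, radii=system.radii,
            times=system.times * 2.0, box=system.box, mol_ids=system.mol_ids,
        )
        base = detect_binding_events(system, "dopamine:0", min_duration=400.0)
        twice = detect_binding_events(scaled, "dopamine:0", min_duration=800.0)
        assert [(e.start * 2, e.end * 2) for e in base] == [
            (e.start, e.end) for e in twice
        ]


class TestModeClassification:
    def test_modes_follow_script(self, surface_system, corona_system):
        for (system, truth), want in ((surface_system, 1), (corona_system, 2)):
            events = detect_all(system)
            assert len(events) == 1
            assert events[0].mode == want

    def test_frame_fraction_threshold(self, surface_system):
        system, _ = surface_system
        ev = detect_all(system)[0]
        # demanding surface contact in >100% of frames is unsatisfiable
        assert classify_mode(ev, system, frame_fraction=1.01) == 2
        assert classify_mode(ev, system, frame_fraction=0.5) == 1

    def test_event_without_frames_refused(self, surface_system):
        system, _ = surface_system
        ev = detect_all(system)[0]
        ev.frames = np.array([], dtype=int)
        with pytest.raises(ValidationError):
            classify_mode(ev, system)


class TestLocalRegion:
    def test_region_size_exact(self, surface_system):
        system, _ = surface_system
        ev = detect_all(system)[0]
        for n in (10, 60):
            region = local_region(ev, system, n)
            assert region.carbons.size == n
            assert len(set(region.carbons.tolist())) == n

    def test_region_sits_under_the_ligand(self, surface_system):
        system, truth = surface_system
        ev = detect_all(system)[0]
        region = local_region(ev, system, 60)
        site = truth[0]["site"]
        centroid = system.coords[ev.frames[0], region.carbons].mean(axis=0)
        # compare radial projections along the tube axis (z) and in-plane angle
        assert abs(centroid[2] - site[2]) < 6.0
        assert np.linalg.norm(centroid[:2] - site[:2]) < 8.0

    def test_two_distant_events_get_disjoint_regions(self):
        script = TrajectoryScript(
            n_frames=120, frame_dt=10.0,
            ligands=[
                LigandScript("dopamine", [(0.0, 500.0, "SURFACE")]),
                LigandScript("dopamine", [(700.0, 1200.0, "SURFACE")]),
            ],
            n_waters=50,
        )
        system, _ = gen_trajectory(script, seed=13)
        events = detect_all(system)
        regions = [local_region(ev, system, 40) for ev in events]
        overlap = set(regions[0].carbons) & set(regions[1].carbons)
        # sites are placed randomly; identical placements are excluded by seed
        assert len(overlap) < 40

    def test_invalid_size_refused(self, surface_system):
        system, _ = surface_system
        ev = detect_all(system)[0]
        with pytest.raises(ValidationError):
            local_region(ev, system, 10**6)


class TestLocalWaterContact:
    def test_normalized_max_is_one_and_mode1_displaces_water(self, surface_system):
        system, _ = surface_system
        ev = detect_all(system)[0]
        # a region of ~the ligand footprint concentrates the displacement signal
        region = local_region(ev, system, 40)
        lw = local_water_contact(region, system, stride=1)
        assert lw["series"].areas.max() == pytest.approx(1.0)
        assert lw["bound_mean"] < lw["unbound_mean"]
        noise_band = 3 * np.hypot(lw["bound_sem"], lw["unbound_sem"])
        assert lw["unbound_mean"] - lw["bound_mean"] > noise_band

    def test_mode2_leaves_local_water_unchanged(self, corona_system):
        system, _ = corona_system
        ev = detect_all(system)[0]
        region = local_region(ev, system, 60)
        lw = local_water_contact(region, system, stride=2)
        noise_band = 3 * np.hypot(lw["bound_sem"], lw["unbound_sem"])
        assert abs(lw["bound_mean"] - lw["unbound_mean"]) <= noise_band


class TestBulkContacts:
    def test_control_system_has_no_ligand_contact(self):
        script = TrajectoryScript(
            n_frames=10, frame_dt=10.0,
            ligands=[LigandScript("dopamine", [])], n_waters=200,
        )
        system, _ = gen_trajectory(script, seed=2)
        series = bulk_contact_series(
            system, [("SWCNT_C", "LIGAND"), ("SWCNT_C", "WATER_O")], n_points=240
        )
        assert np.all(series["SWCNT_C-LIGAND"].areas == 0.0)
        water = series["SWCNT_C-WATER_O"]
        assert water.mean > 0
        assert water.areas.std(ddof=1) / water.mean < 0.05  # stable hydration

    def test_surface_bound_ligand_touches_tube(self, surface_system):
        system, _ = surface_system
        series = bulk_contact_series(
            system, [("SWCNT_C", "LIGAND:dopamine")], stride=5, n_points=240
        )
        s = series["SWCNT_C-LIGAND:dopamine"]
        assert s.mean > 0
        assert s.sem >= 0

    def test_empty_group_refused(self, surface_system):
        system, _ = surface_system
        with pytest.raises(ValidationError, match="empty"):
            bulk_contact_series(system, [("SWCNT_C", "LIGAND:caffeine")])

    def test_symmetry_through_system_wrapper(self, surface_system):
        system, _ = surface_system
        a = system.indices("SWCNT_C")[:40]
        b = system.indices("WATER_O")[:80]
        assert contact_area(system, 0, a, b, n_points=240) == pytest.approx(
            contact_area(system, 0, b, a, n_points=240), rel=1e-12
        )


class TestBoundFraction:
    def test_scripted_counts_recovered(self):
        ligs = [
            LigandScript("dopamine", [(0.0, 1000.0, "SURFACE")]),
            LigandScript("dopamine", [(0.0, 1000.0, "SURFACE")]),
            LigandScript("dopamine", [(0.0, 1000.0, "CORONA")]),
            LigandScript("dopamine", [(300.0, 400.0, "SURFACE")]),  # mostly unbound
            LigandScript("riboflavin", [(0.0, 1000.0, "CORONA")]),
        ]
        script = TrajectoryScript(n_frames=100, frame_dt=10.0, ligands=ligs, n_waters=50)
        system, _ = gen_trajectory(script, seed=4)
        tally = bound_fraction(system)
        assert tally["directly_bound"]["dopamine"] == 2
        assert tally["directly_bound"].get("riboflavin", 0) == 0
        assert tally["n_ligands"] == {"dopamine": 4, "riboflavin": 1}

    def test_all_surface_counts_all(self):
        ligs = [LigandScript("dopamine", [(0.0, 300.0, "SURFACE")]) for _ in range(3)]
        script = TrajectoryScript(n_frames=30, frame_dt=10.0, ligands=ligs, n_waters=50)
        system, _ = gen_trajectory(script, seed=6)
        tally = bound_fraction(system)
        assert tally["directly_bound"]["dopamine"] == 3

    def test_empty_system_zero_counts(self):
        script = TrajectoryScript(n_frames=5, frame_dt=10.0, ligands=[], n_waters=50)
        system, _ = gen_trajectory(script, seed=6)
        tally = bound_fraction(system)
        assert tally["directly_bound"] == {}
        assert tally["per_ligand"] == {}
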