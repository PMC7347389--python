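"""Trajectory feature extraction: distances, rotamers, events, SASA,
hydrogen bonds, side-chain RMSD, occupancy grids and backbone dihedrals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loopdyn.features import (DistanceSeries, backbone_dihedral_series,
                              chi1_series, classify_rotamer,
                              detect_loop_events, hbond_occupancy,
                              mass_density_grid, ring_center_distance,
                              rotamer_populations, sasa_series,
                              sidechain_rmsd)
from loopdyn.synthetic import PlantedEvent, gen_loop_trajectory
from loopdyn._geometry import place_atom

from conftest import make_ensemble, random_rigid_motion


class TestRingCenterDistance:
    def test_hexagon_center_to_target(self, hexagon_ensemble):
        d = ring_center_distance(hexagon_ensemble, 70, (109, "SG"))
        assert d.values[0] == pytest.approx(4.0, abs=1e-12)

    def test_translation_invariance(self, hexagon_ensemble, rng):
        rot, trans = random_rigid_motion(rng)
        moved = hexagon_ensemble
        moved.frames = hexagon_ensemble.frames @ rot.T + trans
        d = ring_center_distance(moved, 70, (109, "SG"))
        assert d.values[0] == pytest.approx(4.0, abs=1e-9)

    def test_missing_atom_is_selection_error(self, hexagon_ensemble):
        with pytest.raises(KeyError, match="OG"):
            ring_center_distance(hexagon_ensemble, 70, (109, "OG"))

    def test_closed_toy_geometry_in_crystal_range(self):
        ens = gen_loop_trajectory(n_frames=50, seed=0)
        d = ring_center_distance(ens, 70, (109, "SG"))
        assert 3.0 < np.median(d.values) < 4.5


class TestRotamers:
    @pytest.mark.parametrize("chi1,state", [
        (-60.0, "gauche-"), (180.0, "trans"), (60.0, "gauche+"),
        (-120.0, "gauche-"), (150.0, "trans"), (-121.0, "trans"),
        (0.0, "gauche+"), (119.9, "gauche+"),
    ])
    def test_well_classification(self, chi1, state):
        assert classify_rotamer(chi1) == state

    @pytest.mark.parametrize("chi1", [-60.0, 60.0, 180.0])
    def test_chi1_from_constructed_coordinates(self, chi1):
        n = np.array([0.0, 1.45, 0.0])
        ca = np.zeros(3)
        cb = np.array([1.32, -0.75, 0.0])
        cg = place_atom(n, ca, cb, 1.5, 113.8, chi1)
        ens = make_ensemble([n, ca, cb, cg], ["N", "CA", "CB", "CG"],
                            [7] * 4, ["PHE"] * 4,
                            elements=["N", "C", "C", "C"])
        series = chi1_series(ens, 7)
        assert series.chi1[0] == pytest.approx(chi1, abs=1e-6)
        assert series.states[0] == classify_rotamer(chi1)

    def test_planted_schedule_recovered_exactly(self):
        ens = gen_loop_trajectory(n_frames=200, seed=3, jitter=0.0,
                                  rotamer_schedule={"gauche-": 0.86,
                                                    "trans": 0.14})
        pops = rotamer_populations(chi1_series(ens, 70))
        assert pops["gauche-"] == pytest.approx(0.86)
        assert pops["trans"] == pytest.approx(0.14)

    def test_populations_equal_brute_force_count(self, rng):
        chi1 = rng.uniform(-180.0, 180.0, 500)
        states = classify_rotamer(chi1)
        from loopdyn.features import RotamerSeries
        series = RotamerSeries(times=np.arange(500.0), chi1=chi1, states=states)
        pops = rotamer_populations(series)
        for s in set(states):
            assert pops[s] == np.sum(states == s) / 500

    def test_empty_series_rejected(self):
        from loopdyn.features import RotamerSeries
        series = RotamerSeries(times=np.array([]), chi1=np.array([]),
                               states=np.array([]))
        with pytest.raises(ValueError):
            rotamer_populations(series)


def brute_force_events(times, values, open_t, close_t, min_dur):
    """Exhaustive interval scan oracle for event detection."""
    events = []
    i = 0
    n = len(values)
    while i < n:
        if values[i] >= open_t:
            j = i + 1
            while j < n and values[j] >= close_t:
                j += 1
            end = times[j] if j < n else times[-1]
            if end - times[i] >= min_dur:
                events.append((times[i], end))
            i = j + 1
        else:
            i += 1
    return events


class TestLoopEvents:
    def test_constant_closed_distance_no_events(self):
        d = DistanceSeries(times=np.arange(100.0) * 0.1,
                           values=np.full(100, 4.0))
        assert detect_loop_events(d) == []

    def test_planted_event_recovered_exactly(self):
        ens = gen_loop_trajectory(events=[PlantedEvent(10.0, 15.0, 12.0)],
                                  n_frames=300, dt=0.1, seed=1)
        d = ring_center_distance(ens, 70, (109, "SG"))
        events = detect_loop_events(d)
        assert len(events) == 1
        assert events[0].start == pytest.approx(10.0)
        assert events[0].end == pytest.approx(15.0)
        assert events[0].duration == pytest.approx(5.0)
        assert events[0].max_distance > 10.0

    def test_sub_minimum_excursion_rejected(self):
        ens = gen_loop_trajectory(events=[PlantedEvent(10.0, 10.5, 12.0)],
                                  n_frames=300, dt=0.1, seed=1)
        d = ring_center_distance(ens, 70, (109, "SG"))
        assert detect_loop_events(d) == []

    def test_invalid_thresholds_rejected(self):
        d = DistanceSeries(times=np.arange(10.0), values=np.full(10, 4.0))
        with pytest.raises(ValueError):
            detect_loop_events(d, open_threshold=5.0, close_threshold=6.0)

    def test_hysteresis_keeps_event_open_in_intermediate_band(self):
        # dips into the 6-10 A band do not close the event
        v = np.array([4.0, 12.0, 8.0, 12.0, 8.0, 12.0, 4.0, 4.0])
        d = DistanceSeries(times=np.arange(8.0), values=v)
        events = detect_loop_events(d, min_duration=1.0)
        assert len(events) == 1
        assert events[0].start == 1.0 and events[0].end == 6.0

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_exhaustive_scan_on_random_traces(self, seed):
        r = np.random.default_rng(seed)
        n = r.integers(5, 120)
        values = r.uniform(0.0, 16.0, n)
        times = np.arange(n) * 0.5
        d = DistanceSeries(times=times, values=values)
        got = [(e.start, e.end) for e in detect_loop_events(d, min_duration=1.0)]
        assert got == brute_force_events(times, values, 10.0, 6.0, 1.0)


class TestSASA:
    def test_isolated_atom_is_probe_expanded_sphere(self):
        ens = make_ensemble([[0.0, 0.0, 0.0]], ["C1"], [1], elements=["C"])
        area = sasa_series(ens, [0])[0]
        exact = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert area == pytest.approx(exact, rel=0.01)

    def test_enclosed_atom_has_no_area(self):
        # atom at origin buried under a dense shell of neighbours
        shell = []
        g = np.random.default_rng(0)
        for _ in range(200):
            v = g.normal(size=3)
            shell.append(2.0 * v / np.linalg.norm(v))
        coords = [[0.0, 0.0, 0.0]] + shell
        names = [f"C{i}" for i in range(len(coords))]
        ens = make_ensemble(coords, names, [1] * len(coords),
                            elements=["C"] * len(coords))
        assert sasa_series(ens, [0])[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_sphere_overlap_matches_spherical_caps(self):
        d = 2.0
        ens = make_ensemble([[0.0, 0.0, 0.0], [0.0, 0.0, d]], ["C1", "C2"],
                            [1, 1], elements=["C", "C"])
        area = np.sum(sasa_series(ens, [0, 1])[0])
        r = 1.7 + 1.4
        h = r - d / 2.0
        exact = 2.0 * (4.0 * np.pi * r ** 2 - 2.0 * np.pi * r * h)
        assert area == pytest.approx(exact, rel=0.02)

    def test_unknown_element_raises(self):
        ens = make_ensemble([[0.0, 0.0, 0.0]], ["X1"], [1], elements=["XX"])
        with pytest.raises(KeyError):
            sasa_series(ens, [0])


class TestHbondOccupancy:
    def _ens(self, n_to_o, linear=True):
        n = [0.0, 0.0, 0.0]
        h = [1.0, 0.0, 0.0]
        o = [n_to_o, 0.0, 0.0] if linear else [0.0, n_to_o, 0.0]
        return make_ensemble([n, h, o], ["N", "H", "OD1"], [71, 71, 68],
                             ["TYR", "TYR", "ASP"], elements=["N", "H", "O"])

    def test_ideal_linear_bond_always_formed(self):
        ens = self._ens(2.9)
        assert hbond_occupancy(ens, (71, "N"), (71, "H"), [(68, "OD1")]) == 1.0

    def test_long_distance_never_formed(self):
        ens = self._ens(5.0)
        assert hbond_occupancy(ens, (71, "N"), (71, "H"), [(68, "OD1")]) == 0.0

    def test_bent_geometry_fails_angle_criterion(self):
        ens = self._ens(2.9, linear=False)  # 90 degree D-H...A angle
        assert hbond_occupancy(ens, (71, "N"), (71, "H"), [(68, "OD1")]) == 0.0

    def test_distance_only_fallback_without_hydrogen(self, caplog):
        ens = self._ens(2.9, linear=False)
        occ = hbond_occupancy(ens, (71, "N"), None, [(68, "OD1")])
        assert occ == 1.0  # distance criterion alone is satisfied

    def test_planted_schedule_recovered(self):
        ens = gen_loop_trajectory(n_frames=400, seed=2, hbond_schedule=0.62)
        occ = hbond_occupancy(ens, (71, "N"), (71, "H"),
                              [(68, "OD1"), (68, "OD2")])
        assert occ == pytest.approx(0.62, abs=0.05)


class TestSidechainRMSD:
    def _two_frame_ens(self, displacement):
        # core of 4 atoms + one side-chain atom; frame 1 displaces only the
        # side chain
        core = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]],
                        dtype=float)
        side = np.array([[1.0, 1.0, 1.0]])
        f0 = np.vstack([core, side])
        f1 = np.vstack([core, side + displacement])
        names = ["N", "CA", "C", "O", "CB"]
        return make_ensemble(np.stack([f0, f1]), names, [5] * 5, ["CYS"] * 5,
                             elements=["N", "C", "C", "O", "C"])

    def test_reference_against_itself_is_zero(self):
        ens = self._two_frame_ens([0.0, 0.0, 1.0])
        vals, _, _ = sidechain_rmsd(ens, 0, np.arange(4), 5)
        assert vals[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_of_whole_frame_is_zero(self, rng):
        ens = self._two_frame_ens([0.0, 0.0, 0.0])
        rot, trans = random_rigid_motion(rng)
        ens.frames[1] = ens.frames[1] @ rot.T + trans
        vals, _, _ = sidechain_rmsd(ens, 0, np.arange(4), 5)
        assert vals[1] == pytest.approx(0.0, abs=1e-9)

    def test_planted_displacement_recovered(self):
        ens = self._two_frame_ens([0.0, 0.0, 1.0])
        vals, mean, _ = sidechain_rmsd(ens, 0, np.arange(4), 5)
        assert vals[1] == pytest.approx(1.0, abs=1e-9)

    def test_empty_sidechain_selection_raises(self):
        core = np.array([[0, 0, 0], [3, 0, 0]], dtype=float)
        ens = make_ensemble(core, ["N", "CA"], [5, 5], ["GLY", "GLY"],
                            elements=["N", "C"])
        with pytest.raises(ValueError):
            sidechain_rmsd(ens, 0, np.arange(2), 5)


class TestMassDensityGrid:
    def test_static_atom_single_full_voxel(self):
        coords = np.tile(np.array([[0.26, 0.26, 0.26]]), (10, 1, 1))
        ens = make_ensemble(coords, ["C1"], [1], elements=["C"],
                            times=np.arange(10.0))
        grid = mass_density_grid(ens, [0])
        assert np.sum(grid.counts > 0) == 1
        assert grid.relative.max() == 1.0
        assert grid.counts.sum() == 10

    def test_equal_alternation_gives_two_full_voxels(self):
        a, b = [0.1, 0.1, 0.1], [2.1, 0.1, 0.1]
        coords = np.array([[a], [b], [a], [b]], dtype=float)
        ens = make_ensemble(coords, ["C1"], [1], elements=["C"],
                            times=np.arange(4.0))
        grid = mass_density_grid(ens, [0])
        assert np.sum(np.isclose(grid.relative, 1.0)) == 2

    def test_threshold_count_matches_brute_force(self, rng):
        coords = rng.uniform(0.0, 5.0, (50, 3, 3))
        ens = make_ensemble(coords, ["C1", "C2", "C3"], [1, 1, 1],
                            elements=["C"] * 3, times=np.arange(50.0))
        grid = mass_density_grid(ens, [0, 1, 2], spacing=1.0)
        assert grid.counts.sum() == 150
        level = 0.12
        brute = np.sum(grid.counts / grid.counts.max() >= level)
        assert grid.n_voxels_above(level) == brute

    def test_zero_frames_rejected(self):
        ens = make_ensemble(np.zeros((1, 1, 3)), ["C1"], [1], elements=["C"])
        ens.frames = np.zeros((0, 1, 3))
        ens.times = np.zeros(0)
        with pytest.raises(ValueError):
            mass_density_grid(ens, [0])


def dihedral_oracle(p0, p1, p2, p3):
    """Direct four-point dihedral formula (atan2 of projected vectors)."""
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))


class TestBackboneDihedrals:
    def _chain(self, phi, psi):
        """Three-residue backbone with requested central phi/psi."""
        c0 = np.array([0.0, 0.0, 0.0])
        n1 = np.array([1.33, 0.0, 0.0])
        # build sequentially with standard internal coordinates
        ca1 = place_atom(np.array([-1.0, 1.0, 0.0]), c0, n1, 1.46, 121.7, 180.0)
        c1 = place_atom(c0, n1, ca1, 1.52, 111.0, phi)
        n2 = place_atom(n1, ca1, c1, 1.33, 116.2, psi)
        coords = [c0, n1, ca1, c1, n2]
        names = ["C", "N", "CA", "C", "N"]
        resids = [1, 2, 2, 2, 3]
        return make_ensemble(coords, names, resids,
                             ["ALA"] * 5, elements=["C", "N", "C", "C", "N"])

    @pytest.mark.parametrize("phi,psi", [(-57.0, -47.0), (-120.0, 130.0)])
    def test_constructed_angles_recovered(self, phi, psi):
        ens = self._chain(phi, psi)
        got_phi, got_psi = backbone_dihedral_series(ens, 2)
        assert got_phi[0] == pytest.approx(phi, abs=1e-6)
        assert got_psi[0] == pytest.approx(psi, abs=1e-6)

    def test_mirroring_flips_signs(self):
        ens = self._chain(-57.0, -47.0)
        ens.frames = ens.frames * np.array([1.0, 1.0, -1.0])
        got_phi, got_psi = backbone_dihedral_series(ens, 2)
        assert got_phi[0] == pytest.approx(57.0, abs=1e-6)
        assert got_psi[0] == pytest.approx(47.0, abs=1e-6)

    def test_chain_terminus_flagged_not_fabricated(self, rng):
        pts = rng.normal(0.0, 3.0, (4, 3))
        ens = make_ensemble(pts, ["C", "N", "CA", "C"], [1, 2, 2, 2],
                            ["ALA"] * 4, elements=["C", "N", "C", "C"])
        phi, psi = backbone_dihedral_series(ens, 2)  # no following residue
        assert phi is not None
        assert psi is None

    def test_matches_independent_formula_oracle(self, rng):
        pts = rng.normal(0.0, 3.0, (4, 3))
        ens = make_ensemble(
            [pts[0], pts[1], pts[2], pts[3]],
            ["C", "N", "CA", "C"], [1, 2, 2, 2], ["ALA"] * 4,
            elements=["C", "N", "C", "C"])
        phi, _ = backbone_dihedral_series(ens, 2)
        assert phi[0] == pytest.approx(
            dihedral_oracle(pts[0], pts[1], pts[2], pts[3]), abs=1e-6)


class TestRigidMotionInvariance:
    def test_all_geometric_features_invariant(self, rng):
        ens = gen_loop_trajectory(events=[PlantedEvent(4.0, 9.0, 12.0)],
                                  n_frames=150, dt=0.1, seed=6)
        d0 = ring_center_distance(ens, 70, (109, "SG")).values
        chi0 = chi1_series(ens, 70).chi1
        occ0 = hbond_occupancy(ens, (71, "N"), (71, "H"), [(68, "OD1")])
        for f in range(ens.n_frames):
            rot, trans = random_rigid_motion(rng)
            ens.frames[f] = ens.frames[f] @ rot.T + trans
        d1 = ring_center_distance(ens, 70, (109, "SG")).values
        chi1_moved = chi1_series(ens, 70).chi1
        occ1 = hbond_occupancy(ens, (71, "N"), (71, "H"), [(68, "OD1")])
        np.testing.assert_allclose(d1, d0, atol=1e-6)
        np.testing.assert_allclose(chi1_moved, chi0, atol=1e-6)
        assert occ0 == occ1
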