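"""Trajectory statistics: rotamer series, shape flips, H-bonds, RMSD."""

import math

import numpy as np
import pytest

from pentitol.crystal_survey import RotamerState
from pentitol.geometry import (
    AlditolTopology,
    Conformation,
    PHI_NAMES,
    Trajectory,
    build_frames,
)
from pentitol.synthetic import RotamerJumpModel, plant_hbond_frames, simulate_rotamer_trajectory
from pentitol.trajectory import (
    DihedralSeries,
    HBondCriteria,
    detect_hbonds,
    dihedral_series,
    hbond_frequencies,
    joint_probability,
    rmsd_series,
    shape_series,
    state_populations,
    transition_count,
)

from conftest import make_conformer


def traj_from_phis(topo, phis):
    return Trajectory(topo, build_frames(topo, np.asarray(phis, dtype=float)))


class TestDihedralSeries:
    def test_single_frame_round_trip(self, ribitol):
        traj = traj_from_phis(ribitol, [(171, -62, -172, 71)])
        series = dihedral_series(traj)
        np.testing.assert_allclose(series.values[0], (171, -62, -172, 71), atol=1e-6)

    def test_noiseless_trajectory_hits_state_centres(self, ribitol):
        model = RotamerJumpModel(n_frames=200, seed=5, sigma_deg=0.0)
        traj, _ = simulate_rotamer_trajectory(ribitol, model)
        series = dihedral_series(traj)
        centres = {180.0, -60.0, 60.0}
        assert set(np.round(np.abs(series.values).ravel(), 6)) <= {60.0, 180.0}

    def test_reversing_frames_reverses_series(self, ribitol, rng):
        phis = rng.uniform(-179, 180, size=(20, 4))
        traj = traj_from_phis(ribitol, phis)
        rev = Trajectory(ribitol, traj.coords[::-1].copy())
        np.testing.assert_allclose(
            dihedral_series(rev).values, dihedral_series(traj).values[::-1], atol=1e-9
        )


class TestPopulations:
    def test_constructed_counts(self, ribitol):
        phis = np.zeros((100, 4))
        phis[:, :] = 180.0
        phis[:53, 0] = 175.0  # trans
        phis[53:91, 0] = 62.0  # gauche+
        phis[91:, 0] = -55.0  # gauche-
        pops = state_populations(dihedral_series(traj_from_phis(ribitol, phis)))
        row = pops["phi1"]
        assert row[RotamerState.TRANS] == pytest.approx(53.0)
        assert row[RotamerState.GAUCHE_PLUS] == pytest.approx(38.0)
        assert row[RotamerState.GAUCHE_MINUS] == pytest.approx(9.0)

    def test_identical_frames_single_state(self, ribitol):
        traj = traj_from_phis(ribitol, [(60, 60, 60, 60)] * 7)
        pops = state_populations(dihedral_series(traj))
        assert pops["phi2"][RotamerState.GAUCHE_PLUS] == 100.0

    def test_percentages_sum_to_100(self, ribitol, rng):
        traj = traj_from_phis(ribitol, rng.uniform(-179, 180, size=(321, 4)))
        for row in state_populations(dihedral_series(traj)).values():
            assert sum(row.values()) == pytest.approx(100.0, abs=1e-9)


class TestJointProbability:
    def test_constructed_36_percent(self, ribitol):
        phis = np.full((100, 4), 60.0)
        phis[:36, 1] = 178.0
        phis[:36, 2] = -176.0
        series = dihedral_series(traj_from_phis(ribitol, phis))
        assert joint_probability(series, ("phi2", "phi3"), ("trans", "trans")) == pytest.approx(36.0)

    def test_joint_bounded_by_marginals(self, ribitol, rng):
        series = dihedral_series(traj_from_phis(ribitol, rng.uniform(-179, 180, (400, 4))))
        pops = state_populations(series)
        for sa in RotamerState:
            for sb in RotamerState:
                joint = joint_probability(series, ("phi2", "phi3"), (sa, sb))
                assert joint <= pops["phi2"][sa] + 1e-9
                assert joint <= pops["phi3"][sb] + 1e-9

    def test_independent_dihedrals_factorize(self, ribitol):
        model = RotamerJumpModel(
            stationary={"phi2": (0.6, 0.25, 0.15), "phi3": (0.3, 0.3, 0.4)},
            jump_probability=1.0,  # i.i.d. frames
            n_frames=40_000,
            seed=11,
        )
        traj, _ = simulate_rotamer_trajectory(ribitol, model)
        series = dihedral_series(traj)
        joint = joint_probability(series, ("phi2", "phi3"), ("trans", "trans"))
        assert joint == pytest.approx(100 * 0.6 * 0.3, abs=1.5)

    def test_never_cooccurring_states(self, ribitol):
        phis = np.full((50, 4), 180.0)
        phis[::2, 1] = 60.0  # phi2 alternates; phi3 always trans
        series = dihedral_series(traj_from_phis(ribitol, phis))
        assert joint_probability(series, ("phi2", "phi3"), ("gauche+", "gauche-")) == 0.0


class TestTransitions:
    def test_constant_series_no_transitions(self, ribitol):
        series = dihedral_series(traj_from_phis(ribitol, [(180, 180, 180, 180)] * 10))
        assert all(not c for c in transition_count(series).values())

    def test_alternating_series(self, ribitol):
        phis = np.full((11, 4), 180.0)
        phis[1::2, 0] = 60.0
        counts = transition_count(dihedral_series(traj_from_phis(ribitol, phis)))["phi1"]
        assert sum(counts.values()) == 10

    def test_markov_rate_within_poisson_error(self, ribitol):
        pi = (0.5, 0.25, 0.25)
        model = RotamerJumpModel(
            stationary={"phi1": pi}, jump_probability=0.2, n_frames=20_000, seed=3
        )
        traj, _ = simulate_rotamer_trajectory(ribitol, model)
        counts = transition_count(dihedral_series(traj))["phi1"]
        total = sum(counts.values())
        # expected jump-and-change rate: r * (1 - sum pi^2)
        expect = 0.2 * (1 - sum(p * p for p in pi)) * (model.n_frames - 1)
        assert abs(total - expect) < 4 * math.sqrt(expect)


class TestShape:
    def test_all_trans_is_extended(self, ribitol):
        traj = traj_from_phis(ribitol, [(180, 180, 180, 180)] * 5)
        ss = shape_series(traj, (4.7, 4.9))
        assert set(ss.labels) == {"extended"} and ss.flips == 0

    def test_hysteresis_sequence(self, ribitol):
        # distances 4.5, 4.8, 5.3 -> bent, intermediate, extended; one flip
        ss_labels = []
        traj = traj_from_phis(
            ribitol, [(171, -62, -172, 71), (180, -110, 180, 180), (180, 180, 180, 180)]
        )
        ss = shape_series(traj, (4.7, 4.9))
        assert ss.distances[0] < 4.7 < ss.distances[1] < 4.9 < ss.distances[2]
        assert ss.labels == ["bent", "intermediate", "extended"]
        assert ss.flips == 1

    def test_alternating_trans_gauche_flips_every_frame(self, ribitol):
        phis = [(180, 180, 180, 180), (180, -62, -172, 71)] * 6
        ss = shape_series(traj_from_phis(ribitol, phis), (4.7, 4.9))
        assert "intermediate" not in ss.labels
        assert ss.flips == len(phis) - 1

    def test_inverted_thresholds_rejected(self, ribitol):
        traj = traj_from_phis(ribitol, [(180, 180, 180, 180)])
        with pytest.raises(ValueError):
            shape_series(traj, (4.9, 4.7))


def _brute_force_hbonds(conf, criteria):
    """Plain-loop re-derivation of the three criteria (oracle)."""
    out = []
    for d in range(1, 6):
        for a in range(1, 6):
            if d == a:
                continue
            od = conf.xyz(f"O{d}")
            oa = conf.xyz(f"O{a}")
            h = conf.xyz(f"HO{d}")
            dist = math.dist(od, oa)

            def ang(p, centre, q):
                u = np.array(p) - np.array(centre)
                v = np.array(q) - np.array(centre)
                c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                return math.degrees(math.acos(max(-1.0, min(1.0, c))))

            if (
                dist <= criteria.max_oo_distance
                and ang(h, od, oa) <= criteria.max_donor_angle
                and ang(od, h, oa) > criteria.min_hydrogen_angle
            ):
                out.append((f"O{d}", f"HO{d}", f"O{a}"))
    return out


class TestHydrogenBonds:
    def test_constructed_geometry_detected(self, ribitol):
        sched = [[("O2", "O4")]]
        traj = plant_hbond_frames(ribitol, sched)
        bonds = detect_hbonds(traj.frame(0))
        assert bonds == [("O2", "HO2", "O4")]

    def test_distance_criterion_is_sharp(self, ribitol):
        traj = plant_hbond_frames(ribitol, [[("O2", "O4")]])
        conf = traj.frame(0)
        tight = HBondCriteria(max_oo_distance=1.0)
        assert detect_hbonds(conf, tight) == []

    def test_hydrogen_angle_criterion(self, ribitol):
        traj = plant_hbond_frames(ribitol, [[("O2", "O4")]])
        conf = traj.frame(0)
        strict = HBondCriteria(min_hydrogen_angle=179.5)
        assert detect_hbonds(conf, strict) == []

    def test_rotation_translation_invariance(self, ribitol):
        from scipy.spatial.transform import Rotation

        traj = plant_hbond_frames(ribitol, [[("O2", "O4")]])
        conf = traj.frame(0)
        R = Rotation.random(random_state=np.random.RandomState(1)).as_matrix()
        moved = Conformation(ribitol, conf.coords @ R.T + np.array([5.0, -3.0, 2.0]))
        assert detect_hbonds(moved) == detect_hbonds(conf)

    def test_brute_force_equivalence_on_random_frames(self, ribitol, rng):
        phis = rng.uniform(-179, 180, size=(50, 4))
        oh = rng.uniform(-179, 180, size=(50, 5))
        coords = build_frames(ribitol, phis, oh)
        criteria = HBondCriteria()
        for k in range(50):
            conf = Conformation(ribitol, coords[k])
            assert detect_hbonds(conf, criteria) == _brute_force_hbonds(conf, criteria)

    def test_frequencies_constructed_30_percent(self, ribitol):
        sched = [[("O2", "O4")] if i < 30 else [] for i in range(100)]
        traj = plant_hbond_frames(ribitol, sched)
        stats = hbond_frequencies(traj)
        assert stats.oxygen_fraction["O2"] == pytest.approx(0.30)
        assert stats.oxygen_fraction["O4"] == pytest.approx(0.30)
        for o in ("O1", "O3", "O5"):
            assert stats.oxygen_fraction[o] == 0.0
        assert stats.pair_fraction[("O2", "O4")] == pytest.approx(0.30)
        assert stats.filtered_pairs(0.10) == {("O2", "O4"): pytest.approx(0.30)}

    def test_no_bonds_all_zero(self, ribitol):
        traj = plant_hbond_frames(ribitol, [[] for _ in range(10)])
        stats = hbond_frequencies(traj)
        assert all(v == 0.0 for v in stats.oxygen_fraction.values())
        assert all(v == 0.0 for v in stats.pair_fraction.values())

    def test_oxygen_fraction_dominates_pair_fractions(self, ribitol, rng):
        phis = rng.uniform(-179, 180, size=(60, 4))
        oh = rng.uniform(-179, 180, size=(60, 5))
        traj = Trajectory(ribitol, build_frames(ribitol, phis, oh))
        stats = hbond_frequencies(traj)
        for o in stats.oxygen_fraction:
            pair_max = max(
                [f for (d, a), f in stats.pair_fraction.items() if o in (d, a)],
                default=0.0,
            )
            assert stats.oxygen_fraction[o] >= pair_max - 1e-12


class TestRmsdSeries:
    def test_rigid_copies_are_zero(self, ribitol):
        from scipy.spatial.transform import Rotation

        conf = make_conformer(ribitol, (171, -62, -172, 71))
        frames = []
        rs = np.random.RandomState(4)
        for _ in range(6):
            R = Rotation.random(random_state=rs).as_matrix()
            frames.append(conf.coords @ R.T + rs.normal(scale=5, size=3))
        traj = Trajectory(ribitol, np.stack(frames))
        assert np.max(rmsd_series(traj, conf)) < 1e-9

    def test_first_frame_reference_starts_at_zero(self, ribitol, rng):
        traj = Trajectory(ribitol, build_frames(ribitol, rng.uniform(-179, 180, (10, 4))))
        series = rmsd_series(traj, traj.frame(0))
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(series >= 0)
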