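"""Karplus prediction and three-state population inversion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pentitol.jcoupling import (
    ROTAMER_STATES,
    CouplingSet,
    CouplingError,
    KarplusParams,
    NotDeterminableError,
    RotamerPopulations,
    StateCouplingMatrix,
    ch_karplus_j,
    haasnoot_j,
    invert_populations,
    phi_populations,
    predict_state_couplings,
)
from pentitol.synthetic import forward_couplings


simplex = st.tuples(
    st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)
).map(lambda t: tuple(x / sum(t) for x in t))


class TestKarplusForms:
    def test_haasnoot_unsubstituted_trans(self):
        p = KarplusParams()
        p1, p2, p3, *_ = p.hh_coefficients(2)
        assert haasnoot_j(180.0, [], p) == pytest.approx(p1 - p2 + p3)

    def test_haasnoot_unsubstituted_perpendicular(self):
        p = KarplusParams()
        p3 = p.hh_coefficients(2)[2]
        assert haasnoot_j(90.0, [], p) == pytest.approx(p3, abs=1e-12)

    def test_trans_exceeds_gauche_for_dioxygenated_fragment(self):
        p = KarplusParams()
        subs = [(1.3, 1.0), (1.3, -1.0), (0.4, 1.0)]
        assert haasnoot_j(180.0, subs, p) > haasnoot_j(60.0, subs, p)

    @given(st.floats(-180, 180), st.sampled_from([1.0, -1.0]))
    @settings(max_examples=100, deadline=None)
    def test_periodicity(self, phi, xi):
        p = KarplusParams()
        subs = [(1.3, xi), (0.4, -xi)]
        assert haasnoot_j(phi, subs, p) == pytest.approx(
            haasnoot_j(phi + 360.0, subs, p), abs=1e-9
        )
        assert ch_karplus_j(phi, p) == pytest.approx(ch_karplus_j(phi + 360.0, p), abs=1e-9)

    def test_ch_limits(self):
        p = KarplusParams(ch=(5.0, -1.0, 0.5))
        assert ch_karplus_j(90.0, p) == pytest.approx(0.5, abs=1e-12)
        assert ch_karplus_j(0.0, p) == pytest.approx(4.5)
        assert ch_karplus_j(180.0, p) > ch_karplus_j(60.0, p)

    def test_invalid_xi_rejected(self):
        with pytest.raises(CouplingError):
            haasnoot_j(60.0, [(1.3, 0.5)])


class TestStateCouplingMatrix:
    def test_phi1_matrix_shape_and_offsets(self, ribitol):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        assert m.matrix.shape == (2, 3)
        # within any one state the two prochiral H-H torsions differ by 120 deg,
        # so the two rows cannot coincide
        assert not np.allclose(m.matrix[0], m.matrix[1])

    def test_phi2_matrix_bounds(self, xylitol):
        m = predict_state_couplings(xylitol, "phi2", ("3J(H2,H3)", "3J(C1,H3)"))
        assert m.matrix.shape == (2, 3)
        assert np.all(m.matrix >= 0.0) and np.all(m.matrix <= 13.0)

    def test_enantiomers_mirror_state_columns(self):
        from pentitol.geometry import AlditolTopology

        m_d = predict_state_couplings(
            AlditolTopology.from_name("d-arabitol"), "phi1", ("3J(H1R,H2)", "3J(H1S,H2)")
        )
        m_l = predict_state_couplings(
            AlditolTopology.from_name("l-arabitol"), "phi1", ("3J(H1R,H2)", "3J(H1S,H2)")
        )
        # mirror symmetry: swapping the prochiral rows and the gauche columns
        # maps one enantiomer's matrix onto the other's
        swapped = m_l.matrix[::-1][:, [0, 2, 1]]
        np.testing.assert_allclose(m_d.matrix, swapped, atol=1e-9)


class TestInversion:
    def test_pure_state_identity(self, ribitol):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        for k in range(3):
            pops = invert_populations(m.matrix[:, k], m)
            expect = np.zeros(3)
            expect[k] = 1.0
            np.testing.assert_allclose(pops.as_array(), expect, atol=1e-9)

    @given(simplex)
    @settings(max_examples=200, deadline=None)
    def test_forward_inverse_round_trip(self, p):
        from pentitol.geometry import AlditolTopology

        topo = AlditolTopology.from_name("d-arabitol")
        m = predict_state_couplings(topo, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        j = m.forward(np.array(p))
        pops = invert_populations(j, m)
        np.testing.assert_allclose(pops.as_array(), p, atol=1e-6)

    def test_round_trip_thousand_points(self, xylitol, rng):
        m = predict_state_couplings(xylitol, "phi2", ("3J(H2,H3)", "3J(C1,H3)"))
        raw = rng.dirichlet(np.ones(3), size=1000)
        for p in raw:
            j = m.forward(p)
            back = invert_populations(j, m).as_array()
            np.testing.assert_allclose(back, p, atol=1e-6)

    def test_noisy_input_stays_on_simplex(self, ribitol, rng):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        for _ in range(50):
            j = rng.uniform(0, 12, size=2)
            pops = invert_populations(j, m).as_array()
            assert np.all(pops >= 0) and pops.sum() == pytest.approx(1.0, abs=1e-9)

    def test_grid_search_equivalence(self, ribitol):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        j = np.array([3.00, 7.20])
        pops = invert_populations(j, m).as_array()
        # brute force over the simplex, step 0.001
        step = 0.001
        p1 = np.arange(0, 1 + step / 2, step)
        grid = []
        for a in p1:
            b = np.arange(0, 1 - a + step / 2, step)
            pts = np.column_stack([np.full_like(b, a), b, 1 - a - b])
            grid.append(pts)
        grid = np.vstack(grid)
        resid = np.linalg.norm(grid @ m.matrix.T - j, axis=1)
        best = grid[np.argmin(resid)]
        np.testing.assert_allclose(pops, best, atol=2 * step)

    def test_under_determined_rejected(self, ribitol):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)",))
        with pytest.raises(CouplingError):
            invert_populations([3.0], m)

    def test_rank_deficient_reported(self):
        m = StateCouplingMatrix(("a", "b"), np.array([[4.0, 4.0, 4.0], [7.0, 7.0, 7.0]]))
        with pytest.raises(CouplingError, match="rank"):
            invert_populations([4.0, 7.0], m)


class TestPublishedPopulations:
    """The printed three-state distributions, recomputed from the couplings."""

    @pytest.mark.parametrize(
        "molecule,site,observed,expected",
        [
            ("ribitol", "phi1", {"3J(H1R,H2)": 3.00, "3J(H1S,H2)": 7.20}, (64, 36, 0)),
            ("d-arabitol", "phi1", {"3J(H1R,H2)": 5.00, "3J(H1S,H2)": 7.55}, (57, 17, 26)),
            ("xylitol", "phi1", {"3J(H1R,H2)": 4.5, "3J(H1S,H2)": 7.5}, (59, 21, 19)),
        ],
    )
    def test_phi1_triplets_within_5_points(self, molecule, site, observed, expected):
        pops = phi_populations(molecule, site, CouplingSet(molecule, dict(observed)))
        for got, want in zip(pops.percentages(), expected):
            assert abs(got - want) <= 5

    def test_d_arabitol_phi2_not_determinable(self):
        cs = CouplingSet("d-arabitol", {"3J(H2,H3)": 2.00, "3J(C1,H3)": None})
        with pytest.raises(NotDeterminableError, match=r"3J\(C1,H3\)"):
            phi_populations("d-arabitol", "phi2", cs)

    def test_phi2_outputs_are_valid_distributions(self):
        # the phi2 observables include an error-flagged C,H coupling; the
        # inversion must still return a proper distribution for both molecules
        for mol, obs in [
            ("ribitol", {"3J(H2,H3)": 6.50, "3J(C1,H3)": 3.8}),
            ("xylitol", {"3J(H2,H3)": 4.6, "3J(C1,H3)": 5.4}),
        ]:
            pops = phi_populations(mol, "phi2", CouplingSet(mol, dict(obs)))
            arr = pops.as_array()
            assert np.all(arr >= 0) and arr.sum() == pytest.approx(1.0, abs=1e-9)


class TestForwardCouplings:
    def test_pure_state_returns_column(self, ribitol):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        cs = forward_couplings((1.0, 0.0, 0.0), m)
        np.testing.assert_allclose(
            [cs.get(o) for o in m.observables], m.matrix[:, 0], atol=1e-12
        )

    def test_uniform_returns_row_means(self, ribitol):
        m = predict_state_couplings(ribitol, "phi1", ("3J(H1R,H2)", "3J(H1S,H2)"))
        cs = forward_couplings((1 / 3, 1 / 3, 1 / 3), m)
        np.testing.assert_allclose(
            [cs.get(o) for o in m.observables], m.matrix.mean(axis=1), atol=1e-12
        )


class TestParamsFile:
    def test_round_trip(self, tmp_path):
        p = KarplusParams(ch=(5.7, -0.6, 0.5), provenance="test set")
        f = tmp_path / "params.txt"
        p.to_file(f)
        q = KarplusParams.from_file(f)
        assert q.ch == p.ch
        assert q.hh_sets == dict(p.hh_sets)
        assert q.beta_correction == p.beta_correction

    def test_packaged_defaults_load(self):
        from importlib.resources import files

        q = KarplusParams.from_file(files("pentitol.data") / "karplus_params.txt")
        assert q.ch == KarplusParams().ch
        assert q.hh_sets[3] == KarplusParams().hh_coefficients(3)
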