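"""Current cone enumeration, convex coordinates, Clarke factorization."""

import numpy as np
import pytest
import sympy as sp

from conftest import brute_force_extreme_rays

from chiralnet import models
from chiralnet.network import (
    NetworkError,
    SteadyState,
    stoichiometric_matrix,
    velocity,
)
from chiralnet.sampling import back_map
from chiralnet.sna import (
    cone_for_network,
    convex_coordinates,
    current_symbols,
    e_matrix,
    extended_stoichiometric_matrix,
    extreme_currents,
    extreme_rays_nonneg_kernel,
    sna_matrix,
    verify_clarke_factorization,
)


class TestExtendedMatrix:
    def test_frank_single_tie_row(self, frank):
        net, chiral = frank
        M = extended_stoichiometric_matrix(net, chiral)
        assert M.tolist() == [[1, 0, -1], [0, 1, -1], [1, -1, 0]]

    def test_order_zero_unchanged(self, theta0):
        net, chiral = theta0
        M = extended_stoichiometric_matrix(net, chiral)
        assert M.tolist() == stoichiometric_matrix(net).tolist()

    def test_calvin_paper_mode_skips_racemization_pair(self, calvin):
        net, chiral = calvin
        M = extended_stoichiometric_matrix(net, chiral, mode="paper")
        assert M.shape == (8, 10)
        tie_rows = M[4:].tolist()
        # ties for R0/R1, R2/R3, R6/R7, R8/R9 -- not the racemizations R4/R5
        def tie(p, q):
            row = [0] * 10
            row[p], row[q] = 1, -1
            return row

        assert tie_rows == [tie(0, 1), tie(2, 3), tie(6, 7), tie(8, 9)]

    def test_calvin_all_mode_ties_every_class(self, calvin):
        net, chiral = calvin
        assert extended_stoichiometric_matrix(net, chiral, mode="all").shape == (9, 10)


class TestExtremeCurrents:
    def test_toy_cone(self, theta0):
        net, chiral = theta0
        cone = cone_for_network(net, chiral)
        assert set(cone.currents) == {(1, 3, 0), (0, 1, 1)}
        cone.check()

    def test_frank_extended_single_ray(self, frank):
        net, chiral = frank
        cone = cone_for_network(net, chiral)
        assert cone.currents == ((1, 1, 1),)

    def test_identity_matrix_trivial_cone(self):
        assert extreme_rays_nonneg_kernel(np.eye(3, dtype=int)) == []

    def test_membership_is_exact(self, replicator):
        net, chiral = replicator
        cone = cone_for_network(net, chiral)
        M = cone.matrix_used
        rng = np.random.default_rng(0)
        for _ in range(20):
            j = rng.integers(0, 5, cone.s)
            v = cone.current_array() @ j
            assert (M @ v == 0).all() and (v >= 0).all()

    @pytest.mark.parametrize(
        "name", ["frank", "calvin", "replicator", "iwamoto_perfect"]
    )
    def test_extension_never_increases_current_count(self, name):
        net, chiral = models.fixture(name)
        plain = extreme_currents(stoichiometric_matrix(net))
        ext = cone_for_network(net, chiral)
        assert ext.s <= plain.s

    def test_minimality_no_ray_is_combination_of_others(self, calvin):
        from scipy.optimize import nnls

        net, chiral = calvin
        cone = cone_for_network(net, chiral)
        A = cone.current_array().astype(float)
        for l in range(cone.s):
            others = np.delete(A, l, axis=1)
            sol, resid = nnls(others, A[:, l])
            assert resid > 1e-9

    def test_against_support_subset_brute_force(self):
        rng = np.random.default_rng(1)
        cases = [
            stoichiometric_matrix(models.fixture("theta0")[0]),
            extended_stoichiometric_matrix(*models.fixture("frank")),
        ]
        for _ in range(8):
            cases.append(rng.integers(-2, 3, size=(rng.integers(1, 4), rng.integers(2, 7))))
        for M in cases:
            assert set(extreme_rays_nonneg_kernel(M)) == brute_force_extreme_rays(M)


class TestConvexCoordinates:
    def test_toy_worked_values(self, theta0):
        net, chiral = theta0
        cone = cone_for_network(net, chiral)
        # identify coordinates by ray: (1,3,0) first in descending order
        assert cone.currents == ((1, 3, 0), (0, 1, 1))
        w = cone.composite([1, 2])
        assert w.tolist() == [1, 5, 2]
        coords = convex_coordinates(cone, w)
        assert coords.unique
        assert coords.j == pytest.approx([1.0, 2.0])

    def test_single_current_unit_coordinate(self, frank):
        net, chiral = frank
        cone = cone_for_network(net, chiral)
        coords = convex_coordinates(cone, np.array(cone.currents[0], dtype=float))
        assert coords.j == pytest.approx([1.0])

    def test_round_trip_random_coordinates(self, replicator):
        net, chiral = replicator
        cone = cone_for_network(net, chiral)
        rng = np.random.default_rng(2)
        for _ in range(10):
            j0 = rng.uniform(0, 2, cone.s)
            coords = convex_coordinates(cone, cone.current_array() @ j0)
            if coords.unique:
                assert coords.j == pytest.approx(j0, abs=1e-8)

    def test_velocity_outside_cone_rejected(self, theta0):
        net, chiral = theta0
        cone = cone_for_network(net, chiral)
        with pytest.raises(NetworkError, match="not in the current cone"):
            convex_coordinates(cone, np.array([1.0, 0.0, 5.0]))


class TestLinearizedMatrix:
    def test_toy_e_and_v_matrices(self, theta0):
        net, chiral = theta0
        cone = cone_for_network(net, chiral)
        j1, j2 = current_symbols(2)
        E = e_matrix(cone)
        assert E == sp.diag(j1, 3 * j1 + j2, j2)
        V = sna_matrix(net, cone)
        expected = sp.Matrix([[-3 * j1 + j2, 3 * j1], [3 * j1 - j2, -3 * j1]])
        assert sp.expand(V - expected) == sp.zeros(2, 2)

    def test_single_ray_scalar_e(self, frank):
        net, chiral = frank
        cone = cone_for_network(net, chiral)
        (j,) = current_symbols(1)
        assert e_matrix(cone) == sp.diag(j, j, j)
        V = sna_matrix(net, cone)
        assert sp.expand(V - sp.Matrix([[0, -j], [-j, 0]])) == sp.zeros(2, 2)

    def test_zero_coordinates_zero_matrix(self, theta0):
        net, chiral = theta0
        cone = cone_for_network(net, chiral)
        E = e_matrix(cone, [0.0, 0.0])
        assert np.allclose(E, 0.0)

    @pytest.mark.parametrize("name", ["theta0", "frank", "calvin", "replicator"])
    def test_entries_linear_in_j(self, name):
        net, chiral = models.fixture(name)
        cone = cone_for_network(net, chiral)
        V = sna_matrix(net, cone)
        syms = current_symbols(cone.s)
        for entry in V:
            if entry != 0:
                assert sp.Poly(entry, *syms).total_degree() <= 1


class TestClarkeFactorization:
    def test_toy_worked_state(self, theta0):
        net, chiral = theta0
        st = SteadyState({"I": 1, "A": 1}, {"k1": 1, "k2": 5, "k3": 2})
        assert verify_clarke_factorization(net, st)

    def test_frank_racemic_steady_states(self, frank):
        net, chiral = frank
        cone = cone_for_network(net, chiral)
        rng = np.random.default_rng(3)
        for _ in range(10):
            j = rng.uniform(0.1, 2.0, cone.s)
            x = float(rng.uniform(0.2, 2.0))
            a = float(rng.uniform(0.2, 2.0))
            st = back_map(
                net, chiral, cone, j,
                concentrations={"L": x, "D": x, "A": a, "P": 1.0},
            )
            assert verify_clarke_factorization(net, st, cone)

    def test_zero_concentration_rejected(self, theta0):
        net, chiral = theta0
        st = SteadyState({"I": 0.0, "A": 1.0}, {"k1": 1, "k2": 5, "k3": 2})
        with pytest.raises(NetworkError, match="positive"):
            verify_clarke_factorization(net, st)
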