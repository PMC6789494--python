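"""Symbolic Jacobians, pair blocks, characteristic polynomials, instability."""

import numpy as np
import pytest
import sympy as sp

from chiralnet import models
from chiralnet.network import NetworkError, SteadyState, parse_network
from chiralnet.stability import (
    CharPoly,
    char_poly,
    is_symmetry_breaking_state,
    is_unstable_polynomial,
    mm_matrix,
    racemic_jacobian,
    routh_hurwitz_unstable,
    stability_verdict,
    symbolic_jacobian,
)


def S(name):  # concentration symbol, as used by the implementation
    return sp.Symbol(name, nonnegative=True)


def K(name):  # rate symbol
    return sp.Symbol(name, positive=True)


def assert_sym_equal(A, B):
    assert sp.simplify(sp.Matrix(A) - sp.Matrix(B)) == sp.zeros(*sp.Matrix(A).shape)


class TestSymbolicJacobian:
    def test_toy_network(self, theta0):
        net, _ = theta0
        I, A = S("I"), S("A")
        k1, k2, k3 = K("k1"), K("k2"), K("k3")
        expected = sp.Matrix(
            [
                [-9 * k1 * I**2 + 2 * k2 * I * A - k3 * A, k2 * I**2 - k3 * I],
                [9 * k1 * I**2 - 2 * k2 * I * A + k3 * A, -k2 * I**2 + k3 * I],
            ]
        )
        assert_sym_equal(symbolic_jacobian(net), expected)

    def test_linear_network_constant_jacobian(self):
        net = parse_network("species X Y\nX -> Y | k\n")
        k = K("k")
        assert_sym_equal(symbolic_jacobian(net), sp.Matrix([[-k, 0], [k, 0]]))

    def test_calvin_racemic_jacobian(self, calvin):
        net, chiral = calvin
        L1, L2 = S("L1"), S("L2")
        k0, k2, k4, k6, k8 = (K(f"k{i}") for i in (0, 2, 4, 6, 8))
        a11 = -k0 * L2 - k4 - k6
        a12 = -k0 * L1 + 2 * k2 * L2 + k8
        a21 = k0 * L2 + k6
        a22 = k0 * L1 - 2 * k2 * L2 - k8
        expected = sp.Matrix(
            [
                [a11, a12, k4, 0],
                [a21, a22, 0, 0],
                [k4, 0, a11, a12],
                [0, 0, a21, a22],
            ]
        )
        assert_sym_equal(racemic_jacobian(net, chiral), expected)

    def test_racemic_block_symmetry(self, replicator):
        # rows/cols k+1..2k mirror rows/cols 1..k under the pair swap
        net, chiral = replicator
        J = racemic_jacobian(net, chiral)
        k = chiral.order
        n = J.shape[0]
        perm = list(range(n))
        for i in range(k):
            perm[i], perm[i + k] = perm[i + k], perm[i]
        P = sp.zeros(n, n)
        for i, j in enumerate(perm):
            P[i, j] = 1
        assert sp.expand(P * J * P - J) == sp.zeros(n, n)


class TestMMMatrix:
    def test_calvin_blocks(self, calvin):
        net, chiral = calvin
        J = racemic_jacobian(net, chiral)
        L1, L2 = S("L1"), S("L2")
        k0, k2, k4, k6, k8 = (K(f"k{i}") for i in (0, 2, 4, 6, 8))
        A_expected = sp.Matrix(
            [
                [-k0 * L2 - k4 - k6, -k0 * L1 + 2 * k2 * L2 + k8],
                [k0 * L2 + k6, k0 * L1 - 2 * k2 * L2 - k8],
            ]
        )
        B_expected = sp.Matrix([[k4, 0], [0, 0]])
        assert_sym_equal(J[:2, :2], A_expected)
        assert_sym_equal(J[:2, 2:4], B_expected)
        assert_sym_equal(mm_matrix(net, chiral), A_expected - B_expected)

    def test_frank_scalar_block(self, frank):
        net, chiral = frank
        # J11 - J12 = (k1 A - k3 D) + k3 L, which is k1 A under L = D
        assert_sym_equal(mm_matrix(net, chiral), sp.Matrix([[K("k1") * S("A")]]))

    def test_order_zero_rejected(self, theta0):
        net, chiral = theta0
        with pytest.raises(ValueError):
            mm_matrix(net, chiral)


class TestCharPoly:
    def test_two_by_two_closed_form(self):
        M = np.array([[1.0, 2.0], [3.0, 4.0]])
        cp = char_poly(M)
        assert cp.omegas[0] == pytest.approx(5.0)  # trace
        assert cp.omegas[1] == pytest.approx(-2.0)  # determinant
        assert cp.coefficients() == pytest.approx([1.0, -5.0, -2.0])

    def test_calvin_mm_determinant_factorizes(self, calvin):
        net, chiral = calvin
        cp = char_poly(mm_matrix(net, chiral))
        L1, L2 = S("L1"), S("L2")
        k0, k2, k4, k8 = K("k0"), K("k2"), K("k4"), K("k8")
        expected = -2 * k4 * (k0 * L1 - 2 * k2 * L2 - k8)
        assert sp.expand(cp.omegas[1] - expected) == 0

    def test_numeric_minors_match_eigenvalue_expansion(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            n = int(rng.integers(2, 6))
            M = rng.integers(-4, 5, size=(n, n)).astype(float)
            cp = char_poly(M)
            expected = np.poly(M)
            assert np.allclose(cp.coefficients(), expected, atol=1e-8 * (1 + abs(expected).max()))

    def test_symbolic_minors_match_berkowitz(self):
        lam = sp.Symbol("lam")
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(2, 5))
            M = sp.Matrix(rng.integers(-3, 4, size=(n, n)).tolist())
            mine = char_poly(M).as_expr(lam)
            theirs = M.charpoly(lam).as_expr()
            assert sp.expand(mine - theirs) == 0


class TestInstability:
    def test_degree_one(self):
        assert is_unstable_polynomial([1.0, -1.0])  # lambda - 1
        assert not is_unstable_polynomial([1.0, 1.0])  # lambda + 1

    def test_two_by_two_rule(self):
        # unstable iff trace > 0 or det < 0
        rng = np.random.default_rng(12)
        for _ in range(100):
            M = rng.normal(size=(2, 2))
            tr, det = M.trace(), np.linalg.det(M)
            if abs(max(np.linalg.eigvals(M).real)) < 1e-6:
                continue
            assert is_unstable_polynomial(char_poly(M)) == (tr > 0 or det < 0)

    def test_routh_known_polynomials(self):
        assert routh_hurwitz_unstable([1, 1, 1]) is False
        assert routh_hurwitz_unstable([1, -1, 1]) is True
        # roots on the imaginary axis degenerate the table
        assert routh_hurwitz_unstable([1, 1, 1, 1]) is None

    def test_random_cubics_match_companion_roots(self):
        rng = np.random.default_rng(13)
        checked = 0
        for _ in range(300):
            coeffs = np.concatenate([[1.0], rng.normal(size=3)])
            max_re = np.max(np.roots(coeffs).real)
            if abs(max_re) < 1e-6:
                continue
            assert is_unstable_polynomial(coeffs) == (max_re > 0)
            checked += 1
        assert checked > 250

    def test_verdict_bands(self):
        assert stability_verdict([1.0, -1.0]) == "unstable"
        assert stability_verdict([1.0, 1.0]) == "stable"
        assert stability_verdict([1.0, 0.0]) == "marginal"


class TestSymmetryBreakingState:
    def frank_state(self):
        return SteadyState(
            {"L": 2.0, "D": 2.0, "A": 1.0, "P": 0.0},
            {"k1": 1.0, "k2": 1.0, "k3": 0.5},
        )

    def test_frank_positive_racemic_state_breaks(self, frank):
        net, chiral = frank
        verdict = is_symmetry_breaking_state(net, chiral, self.frank_state())
        assert verdict.breaking
        # the A - B value is k3 L at the steady state
        assert verdict.max_real_part == pytest.approx(0.5 * 2.0)
        assert verdict.eigenvalue.real > 0
        v = verdict.eigenvector
        assert abs(v[0] - v[1]) > 1e-7 * np.linalg.norm(v)

    def test_calvin_racemic_state_never_breaks(self, calvin):
        net, chiral = calvin
        st = SteadyState(
            {"L1": 1.0, "L2": 1.0, "D1": 1.0, "D2": 1.0},
            {f"k{i}": 1.0 for i in range(10)},
        )
        assert not is_symmetry_breaking_state(net, chiral, st)

    def test_non_steady_state_rejected(self, frank):
        net, chiral = frank
        st = self.frank_state()
        st.concentrations["L"] = 5.0  # breaks both steadiness and racemicity
        with pytest.raises(NetworkError):
            is_symmetry_breaking_state(net, chiral, st)

    def test_agreement_on_random_networks_smoke(self):
        # the full suite runs this at scale; here a quick sanity pass
        from chiralnet.sampling import back_map
        from chiralnet.sna import cone_for_network

        rng = np.random.default_rng(14)
        done = 0
        for seed in range(60):
            if done >= 10:
                break
            k = 1 + seed % 2
            net, chiral = models.random_pseudochiral(
                k, 1, 2, seed=seed, reversible=True
            )
            try:
                cone = cone_for_network(net, chiral)
                if cone.s == 0:
                    continue
                st = back_map(net, chiral, cone, rng.uniform(0.1, 2.0, cone.s))
            except NetworkError:
                continue
            # raises RuntimeError if the two decision paths disagree
            is_symmetry_breaking_state(net, chiral, st)
            done += 1
        assert done >= 5
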