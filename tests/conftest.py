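"""Shared fixtures and independent oracle implementations.

The oracles here deliberately avoid the code paths they check: extreme
rays by support-subset enumeration over exact rationals, the mass-action
right-hand side by direct term-by-term evaluation, and stability by
companion-matrix eigenvalues.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
import sympy as sp

from chiralnet import models
from chiralnet.network import ReactionNetwork, SteadyState


@pytest.fixture(scope="session")
def theta0():
    return models.fixture("theta0")


@pytest.fixture(scope="session")
def frank():
    return models.fixture("frank")


@pytest.fixture(scope="session")
def calvin():
    return models.fixture("calvin")


@pytest.fixture(scope="session")
def replicator():
    return models.fixture("replicator")


@pytest.fixture(scope="session")
def iwamoto_perfect():
    return models.fixture("iwamoto_perfect")


@pytest.fixture(scope="session")
def iwamoto_imperfect():
    return models.fixture("iwamoto_imperfect")


# ---------------------------------------------------------------------------
# oracles


def brute_force_extreme_rays(M) -> set[tuple[int, ...]]:
    """Extreme rays of {v >= 0 : M v = 0} by support-subset enumeration.

    A ray is extreme iff the columns of M indexed by its support have a
    one-dimensional kernel containing a strictly positive vector.  Exact
    rational arithmetic throughout; feasible for r <= ~8.
    """
    M = sp.Matrix([[sp.Rational(x) for x in row] for row in np.asarray(M)])
    r = M.cols
    rays: set[tuple[int, ...]] = set()
    for size in range(1, r + 1):
        for T in itertools.combinations(range(r), size):
            sub = M[:, list(T)]
            ns = sub.nullspace()
            if len(ns) != 1:
                continue
            v = ns[0]
            if any(x == 0 for x in v):
                continue
            if all(x > 0 for x in v):
                pass
            elif all(x < 0 for x in v):
                v = -v
            else:
                continue
            denom = sp.Integer(1)
            for x in v:
                denom = sp.ilcm(denom, sp.fraction(x)[1])
            ints = [int(x * denom) for x in v]
            g = 0
            for x in ints:
                g = math.gcd(g, x)
            full = [0] * r
            for pos, col in enumerate(T):
                full[col] = ints[pos] // g
            rays.add(tuple(full))
    return rays


def direct_mass_action_rhs(net: ReactionNetwork, state: SteadyState) -> np.ndarray:
    """dX_i/dt = sum_j k_j (d_ij - c_ij) prod_l X_l^{c_lj}, term by term."""
    out = []
    for s_i in net.dynamic_species:
        total = 0.0
        for rx in net.reactions:
            nu = rx.product_coeffs.get(s_i, 0) - rx.reactant_coeffs.get(s_i, 0)
            if nu == 0:
                continue
            term = state.rate_constants[rx.rate_label] * nu
            for s_l, c in rx.reactants:
                term *= state.concentrations[s_l] ** c
            total += term
        out.append(total)
    return np.array(out)


def random_state(net: ReactionNetwork, rng: np.random.Generator) -> SteadyState:
    """Random positive (not necessarily steady) state in the unit-ish box."""
    return SteadyState(
        concentrations={s: float(rng.uniform(0.2, 2.0)) for s in net.species},
        rate_constants={
            lab: float(rng.uniform(0.2, 2.0)) for lab in set(net.rate_labels)
        },
    )
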