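"""Linear stability analysis of racemic steady states.

For a pseudochiral network of order k in canonical species order
(L_1..L_k, D_1..D_k, achiral) the Jacobian of the mass-action ODE at a
racemic state has a block symmetry: writing A for the k x k block coupling
L-species to L-species and B for the block coupling L-species to
D-species, the racemic steady state is *symmetry-breaking* (it can seed
homochiral dynamics) if and only if the characteristic polynomial of
A - B is unstable, i.e. has a root with positive real part.  This reduces
an n x n eigenproblem to a k x k one and, crucially, separates the
symmetry-breaking instabilities from instabilities that preserve the
racemic composition.

The characteristic polynomial is kept in the coefficient convention

    p(lambda) = lambda^k - W1 lambda^(k-1) + W2 lambda^(k-2) - ...

where W_i is the sum of the i x i principal minors of the matrix (the i-th
elementary symmetric function of its eigenvalues).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sympy as sp

from .chirality import (
    ChiralStructure,
    canonical_species_order,
    check_racemic_steady_preconditions,
    racemic_substitution,
)
from .network import ReactionNetwork, SteadyState, numeric_jacobian

__all__ = [
    "species_symbol",
    "rate_symbol",
    "symbolic_velocity",
    "symbolic_ode_rhs",
    "symbolic_jacobian",
    "racemic_jacobian",
    "mm_matrix",
    "CharPoly",
    "char_poly",
    "routh_hurwitz_unstable",
    "is_unstable_polynomial",
    "stability_verdict",
    "MMVerdict",
    "is_symmetry_breaking_state",
    "INSTABILITY_TOL",
    "EIGENVECTOR_TOL",
]

# Re(lambda) > INSTABILITY_TOL counts as unstable; |Re| <= tol is "marginal".
INSTABILITY_TOL = 1e-9
# relative tolerance for the eigenvector asymmetry v_i != v_{i+k}
EIGENVECTOR_TOL = 1e-7


def symbolic_matrix_to_json(M: sp.MatrixBase) -> str:
    """Serialize a symbolic matrix as JSON: plain-text entries plus
    machine-readable sympy expression trees (srepr)."""
    import json

    return json.dumps(
        {
            "shape": list(M.shape),
            "entries": [
                [{"text": str(M[i, j]), "srepr": sp.srepr(M[i, j])}
                 for j in range(M.shape[1])]
                for i in range(M.shape[0])
            ],
        },
        indent=2,
    )


def species_symbol(name: str) -> sp.Symbol:
    return sp.Symbol(name, nonnegative=True)


def rate_symbol(label: str) -> sp.Symbol:
    return sp.Symbol(label, positive=True)


def symbolic_velocity(net: ReactionNetwork) -> sp.Matrix:
    """Column vector of symbolic mass-action rates (length r)."""
    rates = []
    for rx in net.reactions:
        term = rate_symbol(rx.rate_label)
        for s, c in rx.reactants:
            term *= species_symbol(s) ** c
        rates.append(term)
    return sp.Matrix(rates)


def symbolic_ode_rhs(net: ReactionNetwork) -> sp.Matrix:
    """Symbolic dX/dt for the dynamic species (length n_dynamic)."""
    from .network import stoichiometric_matrix

    S = sp.Matrix(stoichiometric_matrix(net))
    return sp.expand(S * symbolic_velocity(net))


def symbolic_jacobian(net: ReactionNetwork) -> sp.Matrix:
    """Exact symbolic Jacobian d(dX/dt)/dX over the dynamic species.

    Constant (pool) species appear as symbols but are not differentiation
    variables.
    """
    rhs = symbolic_ode_rhs(net)
    dyn = [species_symbol(s) for s in net.dynamic_species]
    return sp.expand(rhs.jacobian(dyn))


def racemic_jacobian(net: ReactionNetwork, chiral: ChiralStructure) -> sp.Matrix:
    """Symbolic Jacobian in canonical order with the racemic condition applied.

    D-species symbols are replaced by their L-partners and every rate label
    by its class representative.
    """
    canon = canonical_species_order(net, chiral)
    J = symbolic_jacobian(canon)
    name_sub = racemic_substitution(net, chiral)
    subs = {}
    for old, new in name_sub.items():
        if any(old == s for s in net.species):
            subs[species_symbol(old)] = species_symbol(new)
        else:
            subs[rate_symbol(old)] = rate_symbol(new)
    return sp.expand(J.subs(subs))


def mm_matrix(net: ReactionNetwork, chiral: ChiralStructure) -> sp.Matrix:
    """The k x k matrix A - B of the racemic Jacobian (canonical order).

    A couples L-species to L-species (rows/cols 1..k); B couples L-species
    to D-species (rows 1..k, cols k+1..2k).
    """
    k = chiral.order
    if k == 0:
        raise ValueError("network has no dynamic enantiomeric pairs (order 0)")
    J = racemic_jacobian(net, chiral)
    A = J[:k, :k]
    B = J[:k, k : 2 * k]
    return sp.expand(A - B)


# ---------------------------------------------------------------------------
# characteristic polynomial via principal minors


@dataclass
class CharPoly:
    """Characteristic polynomial in the alternating-sign convention.

    ``omegas[i-1]`` holds W_i, the sum of all i x i principal minors; the
    polynomial is lambda^k - W1 lambda^(k-1) + W2 lambda^(k-2) - ... The
    entries are sympy expressions or floats.
    """

    omegas: list

    @property
    def degree(self) -> int:
        return len(self.omegas)

    def coefficients(self) -> list:
        """Monic coefficients in descending powers: [1, -W1, +W2, ...]."""
        return [1] + [(-1) ** i * w for i, w in enumerate(self.omegas, start=1)]

    def signed_omega(self, i: int):
        """(-1)^i W_i, the coefficient of lambda^(k-i)."""
        return (-1) ** i * self.omegas[i - 1]

    def as_expr(self, lam: sp.Symbol) -> sp.Expr:
        k = self.degree
        return sp.expand(
            sum(c * lam ** (k - i) for i, c in enumerate(self.coefficients()))
        )


def _principal_minor_sum_sympy(M: sp.Matrix, i: int) -> sp.Expr:
    k = M.shape[0]
    total = sp.Integer(0)
    for idx in itertools.combinations(range(k), i):
        total += M[idx, idx].det()
    return sp.expand(total)


def _principal_minor_sum_numeric(M: np.ndarray, i: int) -> float:
    k = M.shape[0]
    total = 0.0
    for idx in itertools.combinations(range(k), i):
        sub = M[np.ix_(idx, idx)]
        total += float(np.linalg.det(sub))
    return total


def char_poly(M, minor_limit: int = 8) -> CharPoly:
    """Characteristic polynomial coefficients of a square matrix.

    W_i is computed as the sum of all i x i principal minors (exact for
    symbolic matrices).  For numeric matrices larger than ``minor_limit``
    the coefficients are instead recovered from det(lambda I - M) via
    eigenvalues, which is cheaper than enumerating minors.
    """
    if isinstance(M, sp.MatrixBase):
        if M.shape[0] != M.shape[1]:
            raise ValueError("matrix must be square")
        k = M.shape[0]
        return CharPoly([_principal_minor_sum_sympy(M, i) for i in range(1, k + 1)])
    A = np.asarray(M, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    k = A.shape[0]
    if k <= minor_limit:
        return CharPoly([_principal_minor_sum_numeric(A, i) for i in range(1, k + 1)])
    coeffs = np.poly(A)  # [1, c1, ..., ck], c_i = (-1)^i W_i
    return CharPoly([(-1) ** i * coeffs[i] for i in range(1, k + 1)])


# ---------------------------------------------------------------------------
# instability tests


def _coeff_list(p) -> list[float]:
    if isinstance(p, CharPoly):
        return [float(c) for c in p.coefficients()]
    return [float(c) for c in p]


def routh_hurwitz_unstable(coeffs: Sequence[float]) -> bool | None:
    """Routh-table verdict on a polynomial with descending coefficients.

    Returns True (some root with Re > 0), False (all Re < 0), or None when
    the table degenerates (zero pivot: roots on or near the imaginary axis,
    outside the scope of the pure sign-change rule).
    """
    a = [float(c) for c in coeffs]
    if len(a) < 2:
        return None
    if a[0] == 0:
        return None
    if a[0] < 0:
        a = [-c for c in a]
    n = len(a) - 1
    rows = [a[0::2], a[1::2]]
    scale = max(abs(c) for c in a)
    tiny = 1e-12 * scale
    width = len(rows[0])
    rows[1] += [0.0] * (width - len(rows[1]))
    table = [rows[0], rows[1]]
    for _ in range(n - 1):
        prev, cur = table[-2], table[-1]
        if abs(cur[0]) <= tiny:
            return None
        new = []
        for j in range(width - 1):
            new.append((cur[0] * prev[j + 1] - prev[0] * cur[j + 1]) / cur[0])
        new.append(0.0)
        table.append(new)
    first_col = [row[0] for row in table[: n + 1]]
    if any(abs(c) <= tiny for c in first_col):
        return None
    signs = [c > 0 for c in first_col]
    return any(s != signs[0] for s in signs)


def is_unstable_polynomial(p, tol: float = INSTABILITY_TOL) -> bool:
    """True iff the polynomial has a root with real part > ``tol``.

    The verdict is computed from the roots (companion matrix) and
    cross-checked against the Routh-Hurwitz table whenever the table is
    non-degenerate and the spectrum stays outside the +-tol band.
    """
    coeffs = _coeff_list(p)
    if len(coeffs) < 2:
        raise ValueError("polynomial must have degree >= 1")
    roots = np.roots(coeffs)
    max_re = float(np.max(roots.real))
    verdict = max_re > tol
    rh = routh_hurwitz_unstable(coeffs)
    if rh is not None and abs(max_re) > tol and rh != verdict:
        raise RuntimeError(
            f"Routh-Hurwitz table disagrees with root-finding (max Re {max_re:g})"
        )
    return verdict


def stability_verdict(p, tol: float = INSTABILITY_TOL) -> str:
    """'unstable', 'stable' or 'marginal' (|max Re| within the band)."""
    coeffs = _coeff_list(p)
    max_re = float(np.max(np.roots(coeffs).real))
    if max_re > tol:
        return "unstable"
    if max_re < -tol:
        return "stable"
    return "marginal"


# ---------------------------------------------------------------------------
# symmetry-breaking test at a state


@dataclass
class MMVerdict:
    """Outcome of the symmetry-breaking test at a racemic steady state."""

    breaking: bool
    marginal: bool
    max_real_part: float
    eigenvalue: complex | None = None
    eigenvector: np.ndarray | None = None

    def __bool__(self) -> bool:
        return self.breaking


def _numeric_mm(
    net: ReactionNetwork, chiral: ChiralStructure, state: SteadyState
) -> tuple[np.ndarray, np.ndarray]:
    """Full numeric Jacobian in canonical order and its A - B block."""
    canon = canonical_species_order(net, chiral)
    J = numeric_jacobian(canon, state)
    k = chiral.order
    return J, J[:k, :k] - J[:k, k : 2 * k]


def is_symmetry_breaking_state(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    state: SteadyState,
    tol: float = INSTABILITY_TOL,
    steady_tol: float = 1e-8,
) -> MMVerdict:
    """Decide whether a racemic steady state is symmetry-breaking.

    Primary path: evaluate A - B at the state and test the instability of
    its characteristic polynomial.  Oracle path: eigen-decompose the full
    Jacobian and look for an unstable eigenvalue whose eigenvector differs
    between some pair (v_i != v_{i+k}).  The two paths must agree outside
    the marginal band; disagreement raises RuntimeError.

    Raises :class:`~chiralnet.network.NetworkError` if the state is not a
    racemic steady state with equal dual rate constants.
    """
    check_racemic_steady_preconditions(net, chiral, state, tol=steady_tol)
    k = chiral.order
    if k == 0:
        raise ValueError("order-0 network has no symmetry to break")
    J, mm = _numeric_mm(net, chiral, state)

    mm_eigs = np.linalg.eigvals(mm)
    max_re = float(np.max(mm_eigs.real))
    mm_breaking = max_re > tol
    marginal = abs(max_re) <= tol

    # Definition-based oracle on the full Jacobian
    eigvals, eigvecs = np.linalg.eig(J)
    witness_lambda = None
    witness_vec = None
    oracle_breaking = False
    for idx in np.argsort(-eigvals.real):
        lam = eigvals[idx]
        if lam.real <= tol:
            break
        v = eigvecs[:, idx]
        asym = max(abs(v[i] - v[i + k]) for i in range(k))
        if asym > EIGENVECTOR_TOL * np.linalg.norm(v):
            oracle_breaking = True
            witness_lambda = complex(lam)
            witness_vec = v
            break

    if not marginal and abs(np.max(eigvals.real)) > tol and mm_breaking != oracle_breaking:
        raise RuntimeError(
            "A-B block verdict disagrees with the full-Jacobian eigenvector "
            f"oracle (max Re(A-B) {max_re:g})"
        )
    return MMVerdict(
        breaking=mm_breaking and not marginal,
        marginal=marginal,
        max_real_part=max_re,
        eigenvalue=witness_lambda,
        eigenvector=witness_vec,
    )
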