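"""Stoichiometric network analysis: steady-state cone and Clarke factorization.

The velocity function maps the steady-state set of a mass-action network
onto the polyhedral cone C = {v >= 0 : S v = 0}.  A minimal generating set
of extreme rays of C (the *extreme currents* v_1..v_s) provides *convex
coordinates*: every steady-state velocity is a unique nonnegative
combination j_1 v_1 + ... + j_s v_s when the rays are independent.  The
Jacobian factorizes as J = S E R Delta with E = diag(sum_l v_li j_l) and
Delta = diag(1/X_i), so the stability analysis can focus on the matrix
V = S E R, whose entries are *linear* in the convex coordinates j.

For pseudochiral networks the racemic condition forces dual reactions to
carry equal steady-state currents; appending rows e_p - e_q to S for each
rate-label equality class restricts the cone accordingly and typically
reduces the number of extreme currents substantially.

Extreme rays are enumerated by the double-description method in exact
integer arithmetic, with integer-normalized, lexicographically sorted
output for reproducibility.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp

from .chirality import ChiralStructure
from .network import (
    NetworkError,
    ReactionNetwork,
    SteadyState,
    kinetic_order_matrix,
    numeric_jacobian,
    stoichiometric_matrix,
    velocity,
)

__all__ = [
    "CurrentCone",
    "ConvexCoordinates",
    "extended_stoichiometric_matrix",
    "extreme_rays_nonneg_kernel",
    "extreme_currents",
    "e_matrix",
    "sna_matrix",
    "convex_coordinates",
    "verify_clarke_factorization",
    "current_symbols",
]


# ---------------------------------------------------------------------------
# extended stoichiometric matrix


def _interconverting_pair_class(
    net: ReactionNetwork, chiral: ChiralStructure, members: list[int]
) -> bool:
    """True for a dual pair whose two reactions interconvert enantiomers.

    Such a class is exactly a pair {p, q} with q dual to p and R_q equal to
    the reverse of R_p (e.g. the racemization pair L -> D, D -> L).
    """
    if len(members) != 2:
        return False
    p, q = members
    return chiral.dual_map[p] == q and net.reactions[q].same_multisets(
        net.reactions[p].reversed()
    )


def extended_stoichiometric_matrix(
    net: ReactionNetwork,
    chiral: ChiralStructure | None = None,
    mode: str = "all",
) -> np.ndarray:
    """Stoichiometric matrix with appended equal-current rows.

    For every rate-label equality class with reactions p_1..p_m one row
    e_{p_1} - e_{p_i} is appended per extra member, forcing equal
    steady-state currents within the class (the racemic condition on the
    cone).  ``mode='all'`` ties every class; ``mode='paper'`` skips classes
    that are enantiomer-interconverting dual pairs (racemizations), the
    convention used in published extended matrices.
    """
    S = stoichiometric_matrix(net)
    if chiral is None or chiral.order + len(chiral.constant_pairs) == 0:
        return S
    if mode not in ("all", "paper"):
        raise ValueError(f"unknown dual-constraint mode {mode!r}")
    rows: list[np.ndarray] = []
    for cls in chiral.label_classes:
        members = [i for i, rx in enumerate(net.reactions) if rx.rate_label in cls]
        if len(members) < 2:
            continue
        if mode == "paper" and _interconverting_pair_class(net, chiral, members):
            continue
        p0 = members[0]
        for q in members[1:]:
            row = np.zeros(net.r, dtype=int)
            row[p0] = 1
            row[q] = -1
            rows.append(row)
    if not rows:
        return S
    return np.vstack([S, np.array(rows, dtype=int)])


# ---------------------------------------------------------------------------
# double description


def _normalize_ray(ray: Sequence[int]) -> tuple[int, ...]:
    g = 0
    for x in ray:
        g = math.gcd(g, abs(int(x)))
    if g == 0:
        return tuple(int(x) for x in ray)
    return tuple(int(x) // g for x in ray)


def extreme_rays_nonneg_kernel(M) -> list[tuple[int, ...]]:
    """Extreme rays of {v >= 0 : M v = 0} in exact integer arithmetic.

    Double-description iteration over the rows of M starting from the
    nonnegative orthant, with the combinatorial adjacency test on zero-sets
    of coordinates.  Rays are gcd-normalized integer vectors, sorted
    lexicographically.  An empty list means the cone is {0}.
    """
    M = [[int(x) for x in row] for row in np.asarray(M)]
    if not M:
        raise ValueError("matrix must have at least one row")
    r = len(M[0])
    rays: list[tuple[int, ...]] = [
        tuple(1 if i == c else 0 for i in range(r)) for c in range(r)
    ]
    for row in M:
        dots = [sum(a * x for a, x in zip(row, ray)) for ray in rays]
        zero = [i for i, d in enumerate(dots) if d == 0]
        pos = [i for i, d in enumerate(dots) if d > 0]
        neg = [i for i, d in enumerate(dots) if d < 0]
        kept = [rays[i] for i in zero]
        if pos and neg:
            zmasks = [
                sum(1 << c for c in range(r) if ray[c] == 0) for ray in rays
            ]
            for p, n in itertools.product(pos, neg):
                z = zmasks[p] & zmasks[n]
                adjacent = True
                for o in range(len(rays)):
                    if o in (p, n):
                        continue
                    if (zmasks[o] & z) == z:
                        adjacent = False
                        break
                if not adjacent:
                    continue
                comb = [
                    dots[p] * rays[n][c] - dots[n] * rays[p][c] for c in range(r)
                ]
                kept.append(_normalize_ray(comb))
        rays = sorted(set(kept))
    # descending lexicographic output order (deterministic, and the order in
    # which small worked examples are conventionally written)
    return sorted(rays, reverse=True)


@dataclass(frozen=True)
class CurrentCone:
    """Extreme currents of the (possibly extended) steady-state cone."""

    matrix_used: np.ndarray
    currents: tuple[tuple[int, ...], ...]
    mode: str = "all"

    @property
    def s(self) -> int:
        return len(self.currents)

    @property
    def r(self) -> int:
        return self.matrix_used.shape[1]

    def current_array(self) -> np.ndarray:
        """Currents stacked as columns, shape (r, s)."""
        if not self.currents:
            return np.zeros((self.r, 0), dtype=int)
        return np.array(self.currents, dtype=int).T

    def composite(self, j: Sequence) -> np.ndarray:
        """The combination sum_l j_l v_l (dtype follows j)."""
        arr = self.current_array()
        return arr @ np.asarray(list(j))

    def check(self) -> None:
        """Exact membership/normalization invariants of each current."""
        M = self.matrix_used
        for v in self.currents:
            if any(x < 0 for x in v):
                raise AssertionError("extreme current with negative entry")
            if _normalize_ray(v) != v:
                raise AssertionError("extreme current not gcd-normalized")
            resid = M @ np.array(v, dtype=object)
            if any(x != 0 for x in resid):
                raise AssertionError("extreme current not in kernel")

    def to_tsv(self, reaction_labels: Sequence[str] | None = None) -> str:
        from .network import matrix_to_tsv

        return (
            f"# dual-constraint mode: {self.mode}\n"
            + matrix_to_tsv(
                self.current_array(),
                row_labels=reaction_labels,
                col_labels=[f"v{l + 1}" for l in range(self.s)],
            )
        )


@dataclass
class ConvexCoordinates:
    """Nonnegative coordinates of a steady-state velocity over the currents."""

    j: np.ndarray
    unique: bool = True
    residual: float = 0.0


def extreme_currents(M, mode: str = "all") -> CurrentCone:
    """Enumerate the extreme currents of {v >= 0 : M v = 0}."""
    M = np.asarray(M)
    rays = extreme_rays_nonneg_kernel(M)
    return CurrentCone(matrix_used=M, currents=tuple(rays), mode=mode)


def cone_for_network(
    net: ReactionNetwork,
    chiral: ChiralStructure | None = None,
    mode: str = "all",
) -> CurrentCone:
    """Extreme currents of the network's (extended) steady-state cone."""
    M = extended_stoichiometric_matrix(net, chiral, mode=mode)
    return extreme_currents(M, mode=mode)


# ---------------------------------------------------------------------------
# convex coordinates and the linearized Jacobian


def current_symbols(s: int) -> list[sp.Symbol]:
    """The convex-coordinate symbols j1..js (nonnegative)."""
    return [sp.Symbol(f"j{l + 1}", nonnegative=True) for l in range(s)]


def e_matrix(cone: CurrentCone, j: Sequence | None = None):
    """Diagonal r x r matrix E with E[i, i] = sum_l v_l[i] * j_l.

    With symbolic ``j`` (default) the entries are linear forms in the
    convex coordinates; with numeric ``j`` a numpy diagonal is returned.
    """
    if j is None:
        j = current_symbols(cone.s)
    j = list(j)
    if len(j) != cone.s:
        raise ValueError(f"expected {cone.s} coordinates, got {len(j)}")
    symbolic = any(isinstance(x, sp.Basic) for x in j)
    arr = cone.current_array()
    if symbolic:
        diag = [
            sp.expand(sum(int(arr[i, l]) * j[l] for l in range(cone.s)))
            for i in range(cone.r)
        ]
        return sp.diag(*diag) if diag else sp.zeros(0)
    return np.diag(arr.astype(float) @ np.asarray(j, dtype=float))


def sna_matrix(
    net: ReactionNetwork, cone: CurrentCone, j: Sequence | None = None
) -> sp.Matrix:
    """The linearized stability matrix V = S E(j) R, entries linear in j.

    The plain stoichiometric matrix is used in the product; extension rows
    only shape the cone.  Rows/columns follow ``net.dynamic_species``.
    """
    if j is None:
        j = current_symbols(cone.s)
    S = sp.Matrix(stoichiometric_matrix(net))
    if S.shape[1] != cone.r:
        raise ValueError("cone and network reaction counts differ")
    R = sp.Matrix(kinetic_order_matrix(net))
    E = e_matrix(cone, j)
    E = E if isinstance(E, sp.MatrixBase) else sp.Matrix(E)
    return sp.expand(S * E * R)


def convex_coordinates(
    cone: CurrentCone, state_velocity, tol: float = 1e-8
) -> ConvexCoordinates:
    """Coordinates j >= 0 with sum_l j_l v_l equal to the given velocity.

    Solved exactly (rational elimination) when the currents are linearly
    independent; otherwise a nonnegative least-squares solution is returned
    with ``unique=False``.  A residual above ``tol * ||velocity||`` means
    the velocity is not in the cone (the state is not steady).
    """
    w = np.asarray(state_velocity, dtype=float)
    if cone.s == 0:
        if np.linalg.norm(w) > tol:
            raise NetworkError("velocity not in cone: cone is {0}")
        return ConvexCoordinates(j=np.zeros(0), unique=True)
    A = cone.current_array().astype(float)
    rank = np.linalg.matrix_rank(cone.current_array().astype(float))
    if rank == cone.s:
        j, *_ = np.linalg.lstsq(A, w, rcond=None)
        unique = True
    else:
        from scipy.optimize import nnls

        j, _ = nnls(A, w)
        unique = False
    resid = float(np.linalg.norm(A @ j - w))
    wnorm = max(float(np.linalg.norm(w)), 1.0)
    if resid > tol * wnorm:
        raise NetworkError(
            f"velocity not in the current cone (residual {resid:g}); "
            "state is not a steady state of this cone"
        )
    j = np.where(np.abs(j) < tol * wnorm, np.maximum(j, 0.0), j)
    if np.any(j < -tol * wnorm):
        raise NetworkError("no nonnegative convex coordinates for this velocity")
    return ConvexCoordinates(j=np.clip(j, 0.0, None), unique=unique, residual=resid)


def verify_clarke_factorization(
    net: ReactionNetwork,
    state: SteadyState,
    cone: CurrentCone | None = None,
    tol: float = 1e-8,
) -> bool:
    """Check J(state) = S E(j) R Delta numerically at a positive steady state.

    Delta = diag(1/X_i) over the dynamic species; j are the convex
    coordinates of the state's velocity.  Raises on zero concentrations.
    """
    dyn = net.dynamic_species
    x = np.array([state.concentrations[s] for s in dyn], dtype=float)
    if np.any(x <= 0):
        raise NetworkError("Clarke factorization needs strictly positive concentrations")
    if cone is None:
        cone = extreme_currents(stoichiometric_matrix(net))
    w = velocity(net, state)
    coords = convex_coordinates(cone, w, tol=tol)
    S = stoichiometric_matrix(net).astype(float)
    R = kinetic_order_matrix(net).astype(float)
    E = e_matrix(cone, coords.j)
    delta = np.diag(1.0 / x)
    J_fact = S @ E @ R @ delta
    J = numeric_jacobian(net, state)
    scale = max(float(np.max(np.abs(J))), 1.0)
    return float(np.max(np.abs(J - J_fact))) <= tol * scale
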