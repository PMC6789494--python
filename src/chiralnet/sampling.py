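"""Sampling symmetry-breaking racemic steady states in convex coordinates.

Pipeline (for a pseudochiral network of order k):

1. extend the stoichiometric matrix with equal-current rows for the dual
   rate-constant classes and enumerate the extreme currents v_1..v_s;
2. form the linearized stability matrix V = S E(j) R and its pair blocks
   AV = V[:k, :k], BV = V[:k, k:2k];
3. for i = 1..min(k, 5) compute the signed characteristic-polynomial
   coefficients (-1)^i W_i of AV - BV, polynomials of degree <= i in the
   convex coordinates j;
4. a negative coefficient is necessary for a positive real root, so sample
   the sets {j >= 0 : (-1)^i W_i < 0}: a sound certificate (all monomial
   coefficients nonnegative) proves a set empty; the i = 1 set is linear
   and decided exactly by LP, then sampled by hit-and-run; higher i use
   rejection sampling in the box [0, scale]^s;
5. back-map each sampled j to a racemic steady state (all concentrations
   set to 1, rate constants equal to the composite current, which makes
   the scaling matrix Delta the identity so the linearized verdict is
   exact at the sample) and confirm it with the full symmetry-breaking
   test, eigenvector oracle included.

The verdict is *accept* when at least one state is confirmed, *reject*
when every coefficient set is provably empty (or the cone is trivial), and
*inconclusive* otherwise: rejection sampling cannot prove emptiness for
i >= 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import sympy as sp

from .chirality import ChiralStructure, canonical_species_order, check_pseudochiral
from .network import NetworkError, ReactionNetwork, SteadyState
from .sna import (
    CurrentCone,
    cone_for_network,
    current_symbols,
    sna_matrix,
)
from .stability import MMVerdict, char_poly, is_symmetry_breaking_state

__all__ = [
    "SamplingConfig",
    "InstabilityReport",
    "ConfirmedState",
    "omega_polynomials",
    "emptiness_certificate",
    "sample_instability_region",
    "back_map",
    "sna_sampling",
]


@dataclass
class SamplingConfig:
    """Run settings for the instability sampler.

    ``scale`` bounds the sampling box for the convex coordinates (all
    simulation quantities are dimensionless and kept in [0, 2]);
    ``n_samples`` is the sampling budget per coefficient index i;
    ``i_max`` caps the coefficient index (degree of the searched minors).
    """

    seed: int
    n_samples: int = 10_000
    scale: float = 2.0
    i_max: int = 5
    dual_mode: str = "all"
    max_confirm: int = 200
    keep_samples: int = 50
    steady_tol: float = 1e-8
    instability_tol: float = 1e-9

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if self.scale <= 0 or self.n_samples < 1:
            raise ValueError("scale and n_samples must be positive")


@dataclass
class ConfirmedState:
    """A back-mapped racemic steady state confirmed symmetry-breaking."""

    state: SteadyState
    j: np.ndarray
    i: int
    eigenvalue: complex | None
    eigenvector: np.ndarray | None

    def to_dict(self) -> dict:
        return {
            "concentrations": dict(self.state.concentrations),
            "rate_constants": dict(self.state.rate_constants),
            "convex_coordinates": [float(x) for x in self.j],
            "coefficient_index": self.i,
            "eigenvalue": None
            if self.eigenvalue is None
            else [self.eigenvalue.real, self.eigenvalue.imag],
            "eigenvector": None
            if self.eigenvector is None
            else [[z.real, z.imag] for z in self.eigenvector],
        }


@dataclass
class InstabilityReport:
    """Per-coefficient verdicts and the confirmed symmetry-breaking states."""

    verdict: str  # accept | reject | inconclusive
    order: int
    records: list[dict]
    confirmed: list[ConfirmedState]
    cone_size: int
    dual_mode: str
    seed: int
    reason: str | None = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "order": self.order,
            "reason": self.reason,
            "dual_mode": self.dual_mode,
            "seed": self.seed,
            "extreme_current_count": self.cone_size,
            "coefficients": self.records,
            "confirmed_states": [c.to_dict() for c in self.confirmed],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


# ---------------------------------------------------------------------------
# coefficient polynomials and certificates


def omega_polynomials(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    cone: CurrentCone,
    i_max: int = 5,
) -> list[sp.Expr]:
    """Signed coefficients (-1)^i W_i of AV - BV, i = 1..min(k, i_max).

    W_i is the sum of the i x i principal minors of AV - BV, where AV and
    BV are the pair blocks of V = S E(j) R in canonical species order;
    each returned polynomial is homogeneous of degree <= i in j.
    """
    k = chiral.order
    if k < 1:
        raise ValueError("order must be >= 1")
    canon = canonical_species_order(net, chiral)
    V = sna_matrix(canon, cone)
    AV = V[:k, :k]
    BV = V[:k, k : 2 * k]
    cp = char_poly(sp.expand(AV - BV))
    return [sp.expand(cp.signed_omega(i)) for i in range(1, min(k, i_max) + 1)]


def emptiness_certificate(p: sp.Expr, j_syms: Sequence[sp.Symbol]) -> str:
    """'certified_empty' when every monomial coefficient of p is >= 0.

    Then p >= 0 on the nonnegative orthant, so {j >= 0 : p(j) < 0} is
    empty; otherwise 'unknown' (a negative coefficient does not by itself
    make the set nonempty).
    """
    p = sp.expand(p)
    if p == 0:
        return "certified_empty"
    poly = sp.Poly(p, *j_syms)
    return (
        "certified_empty"
        if all(c >= 0 for c in poly.coeffs())
        else "unknown"
    )


# ---------------------------------------------------------------------------
# sampling


def _lambdify(p: sp.Expr, j_syms: Sequence[sp.Symbol]):
    f = sp.lambdify(list(j_syms), p, "numpy")

    def eval_batch(J: np.ndarray) -> np.ndarray:
        vals = f(*(J[:, l] for l in range(J.shape[1])))
        return np.broadcast_to(np.asarray(vals, dtype=float), (J.shape[0],)).copy()

    return eval_batch


def _linear_lp_feasible(
    coeffs: np.ndarray, scale: float
) -> tuple[bool, np.ndarray | None]:
    """Exact emptiness decision for {j >= 0 : c . j < 0} via LP.

    Minimizes c . j over the simplex {j >= 0, sum j <= scale}; the set is
    nonempty iff the minimum is negative.  Returns a strictly negative
    point when feasible.
    """
    from scipy.optimize import linprog

    s = len(coeffs)
    res = linprog(
        c=coeffs,
        A_ub=np.ones((1, s)),
        b_ub=[scale],
        bounds=[(0, None)] * s,
        method="highs",
    )
    if not res.success:
        raise RuntimeError(f"LP solver failed: {res.message}")
    if res.fun >= 0:
        return False, None
    return True, np.asarray(res.x)


def _hit_and_run_linear(
    coeffs: np.ndarray,
    start: np.ndarray,
    n: int,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform-ish samples of {j >= 0, sum j <= scale, c . j < 0}.

    Classic hit-and-run: from the current point, pick a random direction,
    intersect the feasible chord exactly (all constraints are linear) and
    jump to a uniform point on it.
    """
    s = len(coeffs)
    x = 0.9 * start + 0.05 * (scale / max(s, 1))  # pull off the boundary
    if float(coeffs @ x) >= 0:
        x = start
    out = np.empty((n, s))
    for m in range(n):
        d = rng.normal(size=s)
        d /= np.linalg.norm(d)
        lo, hi = -np.inf, np.inf
        # j >= 0  ->  x + t d >= 0
        for l in range(s):
            if d[l] > 0:
                lo = max(lo, -x[l] / d[l])
            elif d[l] < 0:
                hi = min(hi, -x[l] / d[l])
        # sum j <= scale
        sd = float(d.sum())
        rem = scale - float(x.sum())
        if sd > 0:
            hi = min(hi, rem / sd)
        elif sd < 0:
            lo = max(lo, rem / sd)
        # c . j < 0 (strict; keep a hair inside)
        cd = float(coeffs @ d)
        cx = float(coeffs @ x)
        if cd > 0:
            hi = min(hi, -cx / cd)
        elif cd < 0:
            lo = max(lo, -cx / cd)
        if not np.isfinite(lo):
            lo = min(0.0, hi)
        if hi <= lo:
            out[m] = x
            continue
        t = rng.uniform(lo, hi)
        x = x + t * d
        out[m] = x
    return out


def sample_instability_region(
    polys: Sequence[sp.Expr],
    s: int,
    n_samples: int,
    seed: int,
    scale: float = 2.0,
) -> list[dict]:
    """Per-i sampling of {j >= 0 : (-1)^i W_i < 0}.

    Returns one record per polynomial with keys ``i``, ``verdict``
    (certified_empty / found / not_found), ``samples`` (array of j rows
    with a strictly negative value) and bookkeeping counts.  Deterministic
    for a given seed.
    """
    j_syms = current_symbols(s)
    records: list[dict] = []
    for idx, p in enumerate(polys):
        i = idx + 1
        rng = np.random.default_rng((int(seed) + 7919 * i) % (2**31))
        record: dict = {
            "i": i,
            "polynomial": str(sp.expand(p)),
            "n_samples": n_samples,
        }
        cert = emptiness_certificate(p, j_syms)
        if cert == "certified_empty":
            record.update(verdict="certified_empty", samples=np.zeros((0, s)))
            records.append(record)
            continue
        poly = sp.Poly(sp.expand(p), *j_syms)
        if poly.total_degree() <= 1:
            coeffs = np.array(
                [float(poly.diff(v).as_expr()) for v in j_syms], dtype=float
            )
            feasible, point = _linear_lp_feasible(coeffs, scale)
            if not feasible:
                # exact for the linear case: the set really is empty
                record.update(
                    verdict="certified_empty",
                    certificate="lp_infeasible",
                    samples=np.zeros((0, s)),
                )
                records.append(record)
                continue
            samples = _hit_and_run_linear(coeffs, point, n_samples, scale, rng)
            vals = samples @ coeffs
            samples = samples[vals < 0]
            record.update(
                verdict="found" if len(samples) else "not_found", samples=samples
            )
            records.append(record)
            continue
        # i >= 2: rejection sampling in the box
        f = _lambdify(p, j_syms)
        J = rng.uniform(0.0, scale, size=(n_samples, s))
        vals = f(J)
        hits = J[vals < 0]
        record.update(
            verdict="found" if len(hits) else "not_found",
            samples=hits,
            acceptance_fraction=len(hits) / n_samples,
        )
        records.append(record)
    return records


# ---------------------------------------------------------------------------
# back-mapping


def back_map(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    cone: CurrentCone,
    j: Sequence[float],
    concentrations: dict[str, float] | None = None,
    tol: float = 1e-9,
) -> SteadyState:
    """Racemic steady state whose convex coordinates are ``j``.

    Among the infinitely many preimages of the composite current
    w = sum_l j_l v_l the unit-concentration one is chosen: every species
    concentration is set to 1 (unless ``concentrations`` overrides it with
    a racemic assignment) and each rate constant to w_q / monomial_q.  At
    unit concentrations every monomial is 1, the scaling matrix Delta is
    the identity, and the state is exactly racemic and steady.

    Requires w > 0 on every reaction; a zero component means that reaction
    cannot carry current at this point and the coordinate vector is
    rejected, naming the dead reaction.
    """
    j = np.asarray(list(j), dtype=float)
    if len(j) != cone.s:
        raise ValueError(f"expected {cone.s} coordinates")
    if np.any(j < 0):
        raise NetworkError("convex coordinates must be nonnegative")
    w = cone.current_array().astype(float) @ j
    dead = [q for q in range(net.r) if w[q] <= tol]
    if dead:
        labels = ", ".join(f"R{q} ({net.reactions[q].rate_label})" for q in dead)
        raise NetworkError(
            f"composite current vanishes on reaction(s) {labels}; "
            "coordinate vector is not strictly interior"
        )
    conc = {s: 1.0 for s in net.species}
    if concentrations:
        conc.update({s: float(x) for s, x in concentrations.items()})
    for l, d in chiral.all_pairs:
        if abs(conc[l] - conc[d]) > 0:
            raise NetworkError(f"back-map concentrations must be racemic ({l} != {d})")
    rates: dict[str, float] = {}
    for q, rx in enumerate(net.reactions):
        mono = 1.0
        for s_name, c in rx.reactants:
            mono *= conc[s_name] ** c
        val = w[q] / mono
        prev = rates.get(rx.rate_label)
        if prev is not None and abs(prev - val) > 1e-7 * max(abs(prev), abs(val)):
            raise NetworkError(
                f"inconsistent rate constant for shared label {rx.rate_label}: "
                f"{prev:g} vs {val:g}"
            )
        rates[rx.rate_label] = val
    return SteadyState(concentrations=conc, rate_constants=rates)


# ---------------------------------------------------------------------------
# the full pipeline


def sna_sampling(
    net: ReactionNetwork,
    chiral: ChiralStructure | None = None,
    config: SamplingConfig | None = None,
    **kwargs,
) -> InstabilityReport:
    """Decide and sample mirror-symmetry breaking for a pseudochiral network.

    Keyword arguments are forwarded to :class:`SamplingConfig` when no
    config object is given (``seed`` is mandatory).
    """
    if config is None:
        config = SamplingConfig(**kwargs)
    if chiral is None:
        chiral = check_pseudochiral(net)
    k = chiral.order
    cone = cone_for_network(net, chiral, mode=config.dual_mode)
    if cone.s == 0:
        return InstabilityReport(
            verdict="reject",
            order=k,
            records=[],
            confirmed=[],
            cone_size=0,
            dual_mode=config.dual_mode,
            seed=config.seed,
            reason="no positive steady-state currents",
        )
    polys = omega_polynomials(net, chiral, cone, i_max=config.i_max)
    records = sample_instability_region(
        polys, cone.s, config.n_samples, config.seed, scale=config.scale
    )

    confirmed: list[ConfirmedState] = []
    n_candidates = 0
    n_confirm_tried = 0
    for record in records:
        samples = record.pop("samples")
        record["n_negative"] = int(len(samples))
        kept = []
        n_candidates += len(samples)
        marginal = 0
        dead = 0
        for j_vec in samples:
            if n_confirm_tried >= config.max_confirm:
                break
            n_confirm_tried += 1
            try:
                state = back_map(net, chiral, cone, j_vec)
            except NetworkError:
                dead += 1
                continue
            verdict: MMVerdict = is_symmetry_breaking_state(
                net,
                chiral,
                state,
                tol=config.instability_tol,
                steady_tol=config.steady_tol,
            )
            if verdict.marginal:
                marginal += 1
            elif verdict.breaking:
                confirmed.append(
                    ConfirmedState(
                        state=state,
                        j=np.asarray(j_vec, dtype=float),
                        i=record["i"],
                        eigenvalue=verdict.eigenvalue,
                        eigenvector=verdict.eigenvector,
                    )
                )
            if len(kept) < config.keep_samples:
                kept.append([float(x) for x in j_vec])
        record["sample_head"] = kept
        record["n_marginal"] = marginal
        record["n_dead_reaction"] = dead

    all_empty = all(r["verdict"] == "certified_empty" for r in records)
    if confirmed:
        verdict, reason = "accept", None
    elif all_empty:
        verdict, reason = "reject", "all signed coefficients certified nonnegative"
    else:
        verdict, reason = (
            "inconclusive",
            f"{n_candidates} candidate coordinate vectors, none confirmed",
        )
    return InstabilityReport(
        verdict=verdict,
        order=k,
        records=records,
        confirmed=confirmed,
        cone_size=cone.s,
        dual_mode=config.dual_mode,
        seed=config.seed,
        reason=reason,
    )
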