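"""Numerical confirmation of mirror-symmetry breaking.

A symmetry-breaking racemic steady state is confirmed dynamically by
perturbing one enantiomeric pair by a tiny relative amount, integrating
the stiff mass-action ODE and watching the enantiomeric excess

    ee = (L - D) / (L + D)

of a designated pair.  Spontaneous mirror-symmetry breaking (SMSB) is
declared when the final |ee| exceeds a threshold and the two perturbation
signs produce mirror-image outcomes.  One-dimensional bifurcation scans
over a rate constant locate the SMSB window around a sampled state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .chirality import (
    ChiralStructure,
    check_racemic_steady_preconditions,
    enantiomeric_gap,
)
from .network import (
    NetworkError,
    ReactionNetwork,
    SteadyState,
    numeric_jacobian,
    ode_rhs,
    stoichiometric_matrix,
)

__all__ = [
    "Trajectory",
    "BifurcationTable",
    "integrate",
    "enantiomeric_excess",
    "detect_smsb",
    "bifurcation_scan",
]

# integration stops early when concentrations exceed this cap (runaway
# autocatalysis; the enantiomeric excess is already saturated by then)
_CONC_CAP = 1e12
_STEADY_NORM = 1e-12
_DEFAULT_T_END = 1e6


@dataclass
class Trajectory:
    """Concentration time series for the dynamic species."""

    times: np.ndarray
    concentrations: np.ndarray  # shape (n_times, n_dynamic)
    species: tuple[str, ...]
    success: bool
    message: str = ""
    clipped_negative: bool = False

    def series(self, name: str) -> np.ndarray:
        return self.concentrations[:, self.species.index(name)]

    def final_state(
        self, net: ReactionNetwork, state0: SteadyState
    ) -> SteadyState:
        conc = dict(state0.concentrations)
        for i, s in enumerate(self.species):
            conc[s] = float(self.concentrations[-1, i])
        return SteadyState(conc, dict(state0.rate_constants))


@dataclass
class BifurcationTable:
    """Final |ee| along a rate-constant grid, both perturbation signs."""

    parameter: str
    grid: np.ndarray
    ee_plus: np.ndarray
    ee_minus: np.ndarray
    steady_found: np.ndarray  # bool per grid point
    smsb: np.ndarray  # bool per grid point

    def window(self) -> tuple[float, float] | None:
        """(min, max) grid values showing SMSB, or None."""
        vals = self.grid[self.smsb]
        if len(vals) == 0:
            return None
        return float(vals.min()), float(vals.max())

    def to_csv(self) -> str:
        lines = [f"{self.parameter},ee_plus,ee_minus,steady_found,smsb"]
        for i, g in enumerate(self.grid):
            lines.append(
                f"{g},{self.ee_plus[i]},{self.ee_minus[i]},"
                f"{int(self.steady_found[i])},{int(self.smsb[i])}"
            )
        return "\n".join(lines) + "\n"


def _rhs_closure(net: ReactionNetwork, state: SteadyState):
    """Vector field and Jacobian over the dynamic species, constants fixed."""
    dyn = net.dynamic_species
    index = {s: i for i, s in enumerate(dyn)}
    S = stoichiometric_matrix(net).astype(float)
    terms = []
    for rx in net.reactions:
        k = float(state.rate_constants[rx.rate_label])
        const_factor = 1.0
        orders = []
        for s, c in rx.reactants:
            if s in index:
                orders.append((index[s], c))
            else:
                const_factor *= float(state.concentrations[s]) ** c
        terms.append((k * const_factor, orders))

    def rates(x: np.ndarray) -> np.ndarray:
        v = np.empty(len(terms))
        xs = np.maximum(x, 0.0)  # mass-action rates are meaningless below 0
        for q, (k, orders) in enumerate(terms):
            val = k
            for i, c in orders:
                val *= xs[i] ** c
            v[q] = val
        return v

    def f(t, x):
        return S @ rates(x)

    def jac(t, x):
        xs = np.maximum(x, 1e-300)
        J = np.zeros((len(dyn), len(dyn)))
        for q, (k, orders) in enumerate(terms):
            val = k
            for i, c in orders:
                val *= xs[i] ** c
            for i, c in orders:
                J[:, i] += S[:, q] * (val * c / xs[i])
        return J

    return f, jac


def integrate(
    net: ReactionNetwork,
    state0: SteadyState,
    t_end: float,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
    n_points: int = 200,
    max_step: float = np.inf,
) -> Trajectory:
    """Integrate the mass-action ODE with a stiff implicit method.

    Constant (pool) species are held fixed.  Integration stops early when
    a concentration exceeds the runaway cap.  Small negative undershoots
    (within solver tolerance) are clipped and reported.

    ``max_step`` matters when tracking an instability seeded far below the
    error tolerance (e.g. an ulp-scale enantiomeric imbalance): with an
    unrestricted step the A-stable corrector damps a growing mode it
    cannot see, so cap the step well below 1/Re(lambda).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    state0.validate(net)
    dyn = net.dynamic_species
    x0 = np.array([state0.concentrations[s] for s in dyn], dtype=float)
    f, jac = _rhs_closure(net, state0)

    def runaway(t, x):
        return float(np.max(x)) - _CONC_CAP

    runaway.terminal = True  # type: ignore[attr-defined]
    runaway.direction = 1  # type: ignore[attr-defined]

    kwargs = {}
    if method in ("BDF", "Radau", "LSODA"):
        kwargs["jac"] = jac
    sol = solve_ivp(
        f,
        (0.0, t_end),
        x0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=np.linspace(0.0, t_end, n_points) if n_points else None,
        events=[runaway],
        max_step=max_step,
        **kwargs,
    )
    conc = sol.y.T
    times = sol.t
    if sol.status == 1 and sol.t_events[0].size:  # runaway stop
        times = np.append(times, sol.t_events[0][0])
        conc = np.vstack([conc, sol.y_events[0][0]])
    clipped = bool(np.any(conc < -1e-12))
    conc = np.clip(conc, 0.0, None)
    return Trajectory(
        times=times,
        concentrations=conc,
        species=dyn,
        success=sol.status in (0, 1),
        message=sol.message,
        clipped_negative=clipped,
    )


def enantiomeric_excess(traj: Trajectory, pair: tuple[str, str]) -> np.ndarray:
    """Time series of (L - D) / (L + D); defined as 0 where both vanish."""
    L = traj.series(pair[0])
    D = traj.series(pair[1])
    total = L + D
    with np.errstate(invalid="ignore", divide="ignore"):
        ee = np.where(total > 0, (L - D) / np.where(total > 0, total, 1.0), 0.0)
    return ee


def _staged_run(
    net: ReactionNetwork,
    state: SteadyState,
    pair: tuple[str, str],
    t_end: float,
    rtol: float,
    atol: float,
    growth_rate: float | None = None,
    ee_threshold: float = 0.1,
) -> tuple[float, SteadyState]:
    """Integrate in stages until steady, runaway, saturation, or t_end.

    Returns the final ee of ``pair`` and the final state.  When a positive
    ``growth_rate`` (the unstable eigenvalue of the racemic state) is
    known, the step size is capped below its timescale: an imbalance far
    below the error tolerance is otherwise invisible to the step
    controller, and the A-stable corrector would damp it at large steps.
    """
    cur = state
    ee = prev_ee = 0.0
    if growth_rate is not None and growth_rate > 0:
        # ~ e^20 amplification per chunk; enough chunks to lift an
        # ulp-scale seed to saturation, with margin
        chunk = 20.0 / growth_rate
        bounds = np.arange(chunk, min(t_end, 60 * chunk) + chunk, chunk)
        max_step = 0.5 / growth_rate
    else:
        bounds = np.geomspace(1.0, t_end, num=max(2, int(np.log10(t_end)) + 1))
        max_step = np.inf
    for t_chunk in np.diff(np.concatenate([[0.0], bounds])):
        traj = integrate(
            net, cur, float(t_chunk), rtol=rtol, atol=atol, n_points=2,
            max_step=max_step,
        )
        cur = traj.final_state(net, cur)
        L, D = cur.concentrations[pair[0]], cur.concentrations[pair[1]]
        ee = (L - D) / (L + D) if (L + D) > 0 else 0.0
        if float(np.max(list(cur.concentrations.values()))) >= _CONC_CAP:
            break
        if abs(ee) > ee_threshold and abs(ee - prev_ee) < 1e-4:
            break  # saturated
        prev_ee = ee
        rhs = ode_rhs(net, cur)
        if float(np.max(np.abs(rhs))) < _STEADY_NORM:
            break
    return float(ee), cur


def detect_smsb(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    state: SteadyState,
    epsilon: float = 1e-10,
    t_end: float = _DEFAULT_T_END,
    ee_threshold: float = 0.1,
    rtol: float = 1e-10,
    atol: float = 1e-14,
    pair: tuple[str, str] | None = None,
    check_state: bool = True,
    _detail: bool = False,
):
    """Perturb a racemic steady state and watch for symmetry breaking.

    The first enantiomeric pair (or ``pair``) is perturbed by +-epsilon
    (relative); SMSB is declared when both signs drive the final |ee|
    above ``ee_threshold`` with mirror-image outcomes.  Returns the
    verdict and the final ee of the + run.
    """
    if chiral.order == 0:
        raise ValueError("order-0 network has no ee to observe")
    if check_state:
        check_racemic_steady_preconditions(net, chiral, state, tol=1e-6)
    if pair is None:
        pair = chiral.pairs[0]
    if epsilon == 0:
        return (False, 0.0, 0.0) if _detail else (False, 0.0)
    # growth rate of the mirror-asymmetric mode, for step-size control
    from .stability import _numeric_mm

    try:
        _, mm = _numeric_mm(net, chiral, state)
        growth = float(np.max(np.linalg.eigvals(mm).real))
    except Exception:
        growth = None
    finals = []
    for sign in (+1, -1):
        conc = dict(state.concentrations)
        base = conc[pair[0]]
        delta = epsilon * (base if base > 0 else 1.0)
        conc[pair[0]] = base + sign * delta
        conc[pair[1]] = conc[pair[1]] - sign * delta
        if conc[pair[1]] < 0:
            conc[pair[1]] = 0.0
        perturbed = SteadyState(conc, dict(state.rate_constants))
        ee, _ = _staged_run(
            net, perturbed, pair, t_end, rtol, atol,
            growth_rate=growth, ee_threshold=ee_threshold,
        )
        finals.append(ee)
    ee_plus, ee_minus = finals
    broke = (
        abs(ee_plus) > ee_threshold
        and abs(ee_minus) > ee_threshold
        and np.sign(ee_plus) == -np.sign(ee_minus)
    )
    if _detail:
        return bool(broke), float(ee_plus), float(ee_minus)
    return bool(broke), float(ee_plus)


def _requilibrate_racemic(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    state: SteadyState,
    t_relax: float = 1e5,
) -> SteadyState | None:
    """Relax to a racemic steady state by integrating the symmetric subsystem.

    The ODE is integrated from a racemic start (which stays racemic up to
    roundoff) and the pairs are re-symmetrized; returns None when no
    steady state is reached.
    """
    conc = dict(state.concentrations)
    for l, d in chiral.pairs:
        m = 0.5 * (conc[l] + conc[d])
        conc[l] = conc[d] = m
    cur = SteadyState(conc, dict(state.rate_constants))
    for t_chunk in (1e2, 1e3, t_relax):
        traj = integrate(net, cur, t_chunk, rtol=1e-10, atol=1e-14, n_points=2)
        cur = traj.final_state(net, cur)
        for l, d in chiral.pairs:
            m = 0.5 * (cur.concentrations[l] + cur.concentrations[d])
            cur.concentrations[l] = cur.concentrations[d] = m
        rhs = ode_rhs(net, cur)
        scale = max(1.0, float(np.max(np.abs(list(cur.concentrations.values())))))
        if float(np.max(np.abs(rhs))) < 1e-9 * scale:
            return cur
    rhs = ode_rhs(net, cur)
    if float(np.max(np.abs(rhs))) < 1e-7:
        return cur
    return None


def bifurcation_scan(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    state: SteadyState,
    param_label: str,
    grid,
    epsilon: float = 1e-10,
    t_end: float = _DEFAULT_T_END,
    ee_threshold: float = 0.1,
) -> BifurcationTable:
    """Final |ee| after perturbation along a grid of one rate constant.

    The constant (and every member of its dual label class, to preserve
    pseudochirality) is set to each grid value; the racemic steady state
    is re-equilibrated by continuation from the previous point, then the
    perturb-and-integrate test runs for both signs.  Grid points with no
    racemic steady state are flagged and skipped.
    """
    grid = np.asarray(list(grid), dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    if np.any(grid <= 0):
        raise ValueError("rate constants must be positive")
    labels = chiral.label_class_of(param_label)
    ee_plus = np.full(len(grid), np.nan)
    ee_minus = np.full(len(grid), np.nan)
    steady_found = np.zeros(len(grid), dtype=bool)
    smsb = np.zeros(len(grid), dtype=bool)
    cur = state
    for g_idx, val in enumerate(grid):
        rates = dict(cur.rate_constants)
        for lab in labels:
            rates[lab] = float(val)
        trial = SteadyState(dict(cur.concentrations), rates)
        steady = _requilibrate_racemic(net, chiral, trial)
        if steady is None:
            continue
        steady_found[g_idx] = True
        cur = steady
        broke, eep, eem = detect_smsb(
            net,
            chiral,
            steady,
            epsilon=epsilon,
            t_end=t_end,
            ee_threshold=ee_threshold,
            check_state=False,
            _detail=True,
        )
        ee_plus[g_idx] = eep
        ee_minus[g_idx] = eem
        smsb[g_idx] = broke
    return BifurcationTable(
        parameter=param_label,
        grid=grid,
        ee_plus=ee_plus,
        ee_minus=ee_minus,
        steady_found=steady_found,
        smsb=smsb,
    )
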