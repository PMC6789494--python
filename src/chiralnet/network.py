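"""Mass-action reaction networks: data model, text format, stoichiometry.

A network is a finite set of irreversible mass-action reactions

    c1 X1 + ... + cn Xn  ->  d1 X1 + ... + dn Xn        (rate constant k)

over named species.  Species declared ``constant`` are treated under the
pool-chemical approximation: their concentrations enter every rate law but
they contribute no differential equation, no row of the stoichiometric
matrix and no column of the order matrix.

The plain-text network format (one statement per line, ``#`` comments):

    constant A P                  # pool species
    pair L:D                      # enantiomeric pair, L-form first
    dual k1~k2                    # rate labels constrained equal
    L + A -> 2 L | k1             # irreversible reaction
    A + L <-> 2 L | k2, k3        # reversible; split into two reactions
    -> A | k12                    # inflow (zero-order)
    A -> | k13                    # outflow

Omitted stoichiometric coefficients default to 1.  Reversible arrows are
split at parse time into forward/reverse irreversible reactions, so the
reaction count ``r`` always refers to the split set.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "SteadyState",
    "NetworkError",
    "parse_network",
    "write_network",
    "stoichiometric_matrix",
    "kinetic_order_matrix",
    "velocity",
    "ode_rhs",
    "matrix_to_tsv",
]


class NetworkError(ValueError):
    """Raised for malformed network text or inconsistent network data."""


_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_TERM_RE = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_]*)$")


def _freeze(coeffs: Mapping[str, int]) -> tuple[tuple[str, int], ...]:
    items = tuple(sorted((s, int(c)) for s, c in coeffs.items() if int(c) != 0))
    for s, c in items:
        if c < 0:
            raise NetworkError(f"negative stoichiometric coefficient for {s}")
    return items


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction.

    ``reactants`` / ``products`` are frozen (species, coefficient) multisets;
    coefficients are small nonnegative integers.  Either side may be empty
    (inflow / outflow).  ``rate_label`` names the rate constant.
    """

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    rate_label: str

    @classmethod
    def make(
        cls,
        reactants: Mapping[str, int],
        products: Mapping[str, int],
        rate_label: str,
    ) -> "Reaction":
        return cls(_freeze(reactants), _freeze(products), rate_label)

    @property
    def reactant_coeffs(self) -> dict[str, int]:
        return dict(self.reactants)

    @property
    def product_coeffs(self) -> dict[str, int]:
        return dict(self.products)

    def species(self) -> set[str]:
        return {s for s, _ in self.reactants} | {s for s, _ in self.products}

    def reversed(self) -> "Reaction":
        return Reaction(self.products, self.reactants, self.rate_label)

    def same_multisets(self, other: "Reaction") -> bool:
        """True when both sides coincide as multisets (labels ignored)."""
        return self.reactants == other.reactants and self.products == other.products

    def __str__(self) -> str:  # pragma: no cover - repr helper
        def side(terms):
            return " + ".join(
                (f"{c} {s}" if c != 1 else s) for s, c in terms
            )

        return f"{side(self.reactants)} -> {side(self.products)} | {self.rate_label}"


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered mass-action reaction network.

    ``species`` preserves declaration order; ``constant_species`` is the pool
    subset.  ``pairs`` and ``duals`` carry the enantiomeric-pair and
    dual-rate-label declarations from the text format (interpreted by
    :mod:`chiralnet.chirality`).
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    constant_species: frozenset[str] = frozenset()
    pairs: tuple[tuple[str, str], ...] = ()
    duals: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise NetworkError("duplicate species names")
        declared = set(self.species)
        for rx in self.reactions:
            missing = rx.species() - declared
            if missing:
                raise NetworkError(
                    f"reaction '{rx}' references undeclared species {sorted(missing)}"
                )
        unknown = self.constant_species - declared
        if unknown:
            raise NetworkError(f"constant declaration for unknown species {sorted(unknown)}")
        if not self.reactions:
            raise NetworkError("network has no reactions")
        if not self.dynamic_species:
            raise NetworkError("network has no dynamic species")

    @property
    def dynamic_species(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s not in self.constant_species)

    @property
    def n(self) -> int:
        """Number of dynamic species."""
        return len(self.dynamic_species)

    @property
    def r(self) -> int:
        """Number of (irreversible) reactions."""
        return len(self.reactions)

    @property
    def rate_labels(self) -> tuple[str, ...]:
        return tuple(rx.rate_label for rx in self.reactions)

    def with_species_order(self, order: Sequence[str]) -> "ReactionNetwork":
        if sorted(order) != sorted(self.species):
            raise NetworkError("species reordering must be a permutation")
        return ReactionNetwork(
            tuple(order), self.reactions, self.constant_species, self.pairs, self.duals
        )


@dataclass
class SteadyState:
    """A network state: all concentrations plus all rate constants.

    The state of a mass-action system is the (n + r)-tuple of species
    concentrations (nonnegative) and rate constants (positive); rate
    constants are carried in the state even though they do not evolve.
    """

    concentrations: dict[str, float]
    rate_constants: dict[str, float]

    def validate(self, net: ReactionNetwork) -> None:
        for s in net.species:
            if s not in self.concentrations:
                raise NetworkError(f"missing concentration for species {s}")
            if self.concentrations[s] < 0:
                raise NetworkError(f"negative concentration for species {s}")
        for lab in net.rate_labels:
            if lab not in self.rate_constants:
                raise NetworkError(f"missing rate constant {lab}")
            if self.rate_constants[lab] <= 0:
                raise NetworkError(f"rate constant {lab} must be positive")


# ---------------------------------------------------------------------------
# text format


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    coeffs: dict[str, int] = {}
    if not text:
        return coeffs
    for term in text.split("+"):
        term = term.strip()
        m = _TERM_RE.match(term)
        if m is None:
            raise NetworkError(f"line {lineno}: malformed term {term!r}")
        c = int(m.group(1)) if m.group(1) else 1
        coeffs[m.group(2)] = coeffs.get(m.group(2), 0) + c
    return coeffs


def parse_network(text: str) -> ReactionNetwork:
    """Parse the plain-text network format into a :class:`ReactionNetwork`.

    Reversible reactions are split into two irreversible records; species
    order follows first appearance (``species``/reaction declarations).
    """
    species: list[str] = []
    seen: set[str] = set()
    constant: list[str] = []
    pairs: list[tuple[str, str]] = []
    duals: list[tuple[str, str]] = []
    reactions: list[Reaction] = []

    def declare(name: str) -> None:
        if name not in seen:
            seen.add(name)
            species.append(name)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        head, *rest = line.split(None, 1)
        if head == "species":
            for name in rest[0].split():
                if not _NAME_RE.match(name):
                    raise NetworkError(f"line {lineno}: bad species name {name!r}")
                declare(name)
            continue
        if head == "constant":
            if not rest:
                raise NetworkError(f"line {lineno}: empty constant declaration")
            for name in rest[0].split():
                declare(name)
                constant.append(name)
            continue
        if head == "pair":
            if not rest or ":" not in rest[0]:
                raise NetworkError(f"line {lineno}: pair declaration needs L:D")
            l, d = (x.strip() for x in rest[0].split(":", 1))
            declare(l)
            declare(d)
            pairs.append((l, d))
            continue
        if head == "dual":
            if not rest or "~" not in rest[0]:
                raise NetworkError(f"line {lineno}: dual declaration needs a~b")
            a, b = (x.strip() for x in rest[0].split("~", 1))
            duals.append((a, b))
            continue
        # reaction line
        if "|" not in line:
            raise NetworkError(f"line {lineno}: reaction needs '| rate-label'")
        body, labels = (x.strip() for x in line.rsplit("|", 1))
        reversible = "<->" in body
        arrow = "<->" if reversible else "->"
        if arrow not in body:
            raise NetworkError(f"line {lineno}: missing reaction arrow")
        lhs_text, rhs_text = body.split(arrow, 1)
        lhs = _parse_side(lhs_text, lineno)
        rhs = _parse_side(rhs_text, lineno)
        for name in list(lhs) + list(rhs):
            if name not in seen:
                raise NetworkError(
                    f"line {lineno}: undeclared species {name!r} (declare via "
                    "'species', 'constant' or 'pair')"
                )
        label_list = [x.strip() for x in labels.split(",")]
        if reversible:
            if len(label_list) != 2:
                raise NetworkError(
                    f"line {lineno}: reversible reaction needs two rate labels"
                )
            kf, kr = label_list
            reactions.append(Reaction.make(lhs, rhs, kf))
            reactions.append(Reaction.make(rhs, lhs, kr))
        else:
            if len(label_list) != 1 or not label_list[0]:
                raise NetworkError(f"line {lineno}: reaction needs one rate label")
            reactions.append(Reaction.make(lhs, rhs, label_list[0]))

    return ReactionNetwork(
        species=tuple(species),
        reactions=tuple(reactions),
        constant_species=frozenset(constant),
        pairs=tuple(pairs),
        duals=tuple(duals),
    )


def write_network(net: ReactionNetwork) -> str:
    """Serialize back to the text format (reactions stay split)."""
    lines: list[str] = []
    lines.append("species " + " ".join(net.species))
    if net.constant_species:
        lines.append(
            "constant " + " ".join(s for s in net.species if s in net.constant_species)
        )
    for l, d in net.pairs:
        lines.append(f"pair {l}:{d}")
    for a, b in net.duals:
        lines.append(f"dual {a}~{b}")

    def side(terms: tuple[tuple[str, int], ...]) -> str:
        return " + ".join((f"{c} {s}" if c != 1 else s) for s, c in terms)

    for rx in net.reactions:
        lines.append(f"{side(rx.reactants)} -> {side(rx.products)} | {rx.rate_label}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# stoichiometry and kinetics


def stoichiometric_matrix(net: ReactionNetwork) -> np.ndarray:
    """Net-change matrix S, shape (n_dynamic, r): S[i, j] = d_ij - c_ij."""
    dyn = net.dynamic_species
    S = np.zeros((len(dyn), net.r), dtype=int)
    index = {s: i for i, s in enumerate(dyn)}
    for j, rx in enumerate(net.reactions):
        for s, c in rx.reactants:
            if s in index:
                S[index[s], j] -= c
        for s, d in rx.products:
            if s in index:
                S[index[s], j] += d
    return S


def kinetic_order_matrix(net: ReactionNetwork) -> np.ndarray:
    """Reactant-order matrix R, shape (r, n_dynamic): R[j, i] = c_ij.

    Orders of constant species are omitted from the columns (they are fixed
    factors of the rate laws, handled by :func:`velocity`).
    """
    dyn = net.dynamic_species
    R = np.zeros((net.r, len(dyn)), dtype=int)
    index = {s: i for i, s in enumerate(dyn)}
    for j, rx in enumerate(net.reactions):
        for s, c in rx.reactants:
            if s in index:
                R[j, index[s]] += c
    return R


def _state_parts(
    state: SteadyState | tuple[Mapping[str, float], Mapping[str, float]],
) -> tuple[Mapping[str, float], Mapping[str, float]]:
    if isinstance(state, SteadyState):
        return state.concentrations, state.rate_constants
    conc, rates = state
    return conc, rates


def velocity(net: ReactionNetwork, state) -> np.ndarray:
    """Mass-action rate vector, length r: v_j = k_j * prod_i X_i^{c_ij}.

    The product runs over *all* species, constant ones included.
    """
    conc, rates = _state_parts(state)
    v = np.empty(net.r, dtype=float)
    for j, rx in enumerate(net.reactions):
        try:
            val = float(rates[rx.rate_label])
        except KeyError:
            raise NetworkError(f"missing rate constant {rx.rate_label}") from None
        for s, c in rx.reactants:
            try:
                x = float(conc[s])
            except KeyError:
                raise NetworkError(f"missing concentration for {s}") from None
            val *= x**c
        v[j] = val
    return v


def ode_rhs(net: ReactionNetwork, state) -> np.ndarray:
    """Time derivative of the dynamic concentrations: S @ velocity."""
    return stoichiometric_matrix(net) @ velocity(net, state)


def numeric_jacobian(net: ReactionNetwork, state) -> np.ndarray:
    """Analytic Jacobian d(ode_rhs)/dX over dynamic species, evaluated at ``state``."""
    conc, rates = _state_parts(state)
    dyn = net.dynamic_species
    index = {s: i for i, s in enumerate(dyn)}
    S = stoichiometric_matrix(net)
    J = np.zeros((len(dyn), len(dyn)))
    for j, rx in enumerate(net.reactions):
        base = float(rates[rx.rate_label])
        coeffs = rx.reactants
        for s_d, c_d in coeffs:
            if s_d not in index:
                continue
            # d(rate_j)/dX_{s_d} = k * c_d * X_d^{c_d-1} * prod_{other} X^c
            term = base * c_d
            for s, c in coeffs:
                x = float(conc[s])
                term *= x ** (c - 1 if s == s_d else c)
            J[:, index[s_d]] += S[:, j] * term
    return J


def matrix_to_tsv(
    matrix: np.ndarray,
    row_labels: Iterable[str] | None = None,
    col_labels: Iterable[str] | None = None,
) -> str:
    """Render a matrix as tab-separated text with optional labels."""
    rows = []
    mat = np.asarray(matrix)
    cols = list(col_labels) if col_labels is not None else None
    rls = list(row_labels) if row_labels is not None else None
    if cols is not None:
        rows.append("\t".join(([""] if rls is not None else []) + cols))
    for i in range(mat.shape[0]):
        cells = [str(x) for x in mat[i]]
        if rls is not None:
            cells = [rls[i]] + cells
        rows.append("\t".join(cells))
    return "\n".join(rows) + "\n"
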