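"""Enantiomeric structure of a reaction network.

A network modelling absolute asymmetric synthesis lists its chiral species
as enantiomeric pairs (L-form, D-form).  Swapping every pair while fixing
the achiral species defines an involution on species; a network is
*pseudochiral* when that involution maps its reaction set onto itself, each
reaction landing on a *dual* reaction that carries the same rate constant
(enantiomers are indiscernible to achiral chemistry).  The *order* k of a
pseudochiral network is its number of dynamic enantiomeric pairs.

A state is *racemic* when every pair has equal concentrations; the
*enantiomeric gap* sum_i |L_i - D_i| measures the deviation, and is zero
exactly on racemic states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkError, Reaction, ReactionNetwork, SteadyState

__all__ = [
    "ChiralStructure",
    "PseudochiralityError",
    "check_pseudochiral",
    "canonical_species_order",
    "enantiomeric_gap",
    "is_racemic",
    "racemic_substitution",
    "apply_involution",
    "check_racemic_steady_preconditions",
]


class PseudochiralityError(NetworkError):
    """The declared pairing does not make the network pseudochiral."""


@dataclass(frozen=True)
class ChiralStructure:
    """Result of a successful pseudochirality check.

    ``pairs`` are the dynamic enantiomeric pairs (their order defines the
    pair index used by the stability analysis); ``constant_pairs`` are
    pairs of pool species that participate in the involution only.
    ``dual_map[i]`` is the index of the dual reaction of reaction i (an
    involution; self-dual reactions map to themselves).  ``label_classes``
    partitions the rate labels into classes constrained to share one value.
    """

    pairs: tuple[tuple[str, str], ...]
    constant_pairs: tuple[tuple[str, str], ...]
    achiral: tuple[str, ...]
    dual_map: tuple[int, ...]
    label_classes: tuple[tuple[str, ...], ...]

    @property
    def order(self) -> int:
        """Number of dynamic enantiomeric pairs (the order k)."""
        return len(self.pairs)

    @property
    def all_pairs(self) -> tuple[tuple[str, str], ...]:
        return self.pairs + self.constant_pairs

    def species_involution(self) -> dict[str, str]:
        swap: dict[str, str] = {}
        for l, d in self.all_pairs:
            swap[l] = d
            swap[d] = l
        for s in self.achiral:
            swap[s] = s
        return swap

    def label_class_of(self, label: str) -> tuple[str, ...]:
        for cls in self.label_classes:
            if label in cls:
                return cls
        return (label,)

    def class_representative(self, label: str) -> str:
        """Lexicographically smallest label of the class (deterministic)."""
        return min(self.label_class_of(label))

    def dual_table(self) -> str:
        """Two-column report of the dual-reaction map."""
        lines = ["reaction\tdual"]
        for i, j in enumerate(self.dual_map):
            lines.append(f"R{i}\tR{j}")
        return "\n".join(lines) + "\n"


def _involute_reaction(rx: Reaction, swap: dict[str, str]) -> Reaction:
    return Reaction.make(
        {swap[s]: c for s, c in rx.reactants},
        {swap[s]: c for s, c in rx.products},
        rx.rate_label,
    )


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


def check_pseudochiral(
    net: ReactionNetwork,
    pairs: tuple[tuple[str, str], ...] | None = None,
) -> ChiralStructure:
    """Verify pseudochirality and return the dual structure.

    For every reaction the image under the species involution must occur in
    the network (its *dual*), and the two must lie in one rate-label class
    (same label, or labels declared ``dual``).  Raises
    :class:`PseudochiralityError` naming the first offending reaction.
    """
    if pairs is None:
        pairs = net.pairs
    declared = set(net.species)
    used: set[str] = set()
    dyn_pairs: list[tuple[str, str]] = []
    const_pairs: list[tuple[str, str]] = []
    for l, d in pairs:
        for s in (l, d):
            if s not in declared:
                raise PseudochiralityError(f"paired species {s} not declared")
            if s in used:
                raise PseudochiralityError(f"species {s} occurs in two pairs")
            used.add(s)
        l_const = l in net.constant_species
        d_const = d in net.constant_species
        if l_const != d_const:
            raise PseudochiralityError(
                f"pair {l}:{d} mixes a dynamic and a constant species"
            )
        (const_pairs if l_const else dyn_pairs).append((l, d))
    achiral = tuple(s for s in net.species if s not in used)

    chiral = ChiralStructure(
        pairs=tuple(dyn_pairs),
        constant_pairs=tuple(const_pairs),
        achiral=achiral,
        dual_map=(),
        label_classes=(),
    )
    swap = chiral.species_involution()

    # dual-reaction matching
    dual_map: list[int | None] = [None] * net.r
    for i, rx in enumerate(net.reactions):
        if dual_map[i] is not None:
            continue
        image = _involute_reaction(rx, swap)
        if image.same_multisets(rx):
            dual_map[i] = i
            continue
        candidates = [
            j
            for j, other in enumerate(net.reactions)
            if j != i and dual_map[j] is None and other.same_multisets(image)
        ]
        if not candidates:
            raise PseudochiralityError(
                f"not pseudochiral: reaction R{i} ({rx}) has no mirror-image dual"
            )
        # prefer the candidate whose label is tied to ours
        tied = [
            j
            for j in candidates
            if net.reactions[j].rate_label == rx.rate_label
            or (rx.rate_label, net.reactions[j].rate_label) in net.duals
            or (net.reactions[j].rate_label, rx.rate_label) in net.duals
        ]
        j = (tied or candidates)[0]
        dual_map[i] = j
        dual_map[j] = i

    # rate-label classes: same label, declared duals, and dual partners
    uf = _UnionFind()
    for rx in net.reactions:
        uf.find(rx.rate_label)
    for a, b in net.duals:
        uf.union(a, b)
    for i, j in enumerate(dual_map):
        li, lj = net.reactions[i].rate_label, net.reactions[j].rate_label
        if uf.find(li) != uf.find(lj) and li != lj:
            raise PseudochiralityError(
                f"not pseudochiral: dual reactions R{i}/R{j} carry labels "
                f"{li}/{lj} not declared equal"
            )
        uf.union(li, lj)
    groups: dict[str, list[str]] = {}
    for lab in dict.fromkeys(rx.rate_label for rx in net.reactions):
        groups.setdefault(uf.find(lab), []).append(lab)
    label_classes = tuple(
        tuple(sorted(g)) for g in sorted(groups.values(), key=lambda g: sorted(g)[0])
    )

    return ChiralStructure(
        pairs=tuple(dyn_pairs),
        constant_pairs=tuple(const_pairs),
        achiral=achiral,
        dual_map=tuple(dual_map),  # type: ignore[arg-type]
        label_classes=label_classes,
    )


def canonical_species_order(
    net: ReactionNetwork, chiral: ChiralStructure
) -> ReactionNetwork:
    """Reorder species as L_1..L_k, D_1..D_k, dynamic achiral, constants.

    All block extraction downstream (A/B submatrices of the racemic
    Jacobian) assumes this order.  Reaction order is preserved.
    """
    l_side = [l for l, _ in chiral.pairs]
    d_side = [d for _, d in chiral.pairs]
    placed = set(l_side) | set(d_side)
    rest_dyn = [s for s in net.dynamic_species if s not in placed]
    consts = [s for s in net.species if s in net.constant_species]
    return net.with_species_order(l_side + d_side + rest_dyn + consts)


def apply_involution(net: ReactionNetwork, chiral: ChiralStructure) -> ReactionNetwork:
    """Network with every reaction replaced by its mirror image."""
    swap = chiral.species_involution()
    return ReactionNetwork(
        net.species,
        tuple(_involute_reaction(rx, swap) for rx in net.reactions),
        net.constant_species,
        net.pairs,
        net.duals,
    )


def enantiomeric_gap(state: SteadyState, chiral: ChiralStructure) -> float:
    """sum_i |L_i - D_i| over all enantiomeric pairs; zero iff racemic."""
    conc = state.concentrations if isinstance(state, SteadyState) else state
    return float(
        sum(abs(conc[l] - conc[d]) for l, d in chiral.all_pairs)
    )


def is_racemic(state: SteadyState, chiral: ChiralStructure, tol: float = 0.0) -> bool:
    return enantiomeric_gap(state, chiral) <= tol


def racemic_substitution(
    net: ReactionNetwork, chiral: ChiralStructure
) -> dict[str, str]:
    """Name map imposing the racemic condition.

    Sends each D-species name to its L-partner and each rate label to its
    class representative; applying it to the symbolic Jacobian yields the
    racemic Jacobian.
    """
    sub = {d: l for l, d in chiral.all_pairs}
    for rx in net.reactions:
        rep = chiral.class_representative(rx.rate_label)
        if rep != rx.rate_label:
            sub[rx.rate_label] = rep
    return sub


def check_racemic_steady_preconditions(
    net: ReactionNetwork,
    chiral: ChiralStructure,
    state: SteadyState,
    tol: float = 1e-8,
) -> None:
    """Reject states that are not racemic steady states with equal dual rates.

    ``tol`` is relative to the largest reaction rate at the state.
    """
    from .network import ode_rhs, velocity

    state.validate(net)
    scale = max(1.0, float(np.max(np.abs(velocity(net, state)))))
    gap = enantiomeric_gap(state, chiral)
    if gap > tol * scale:
        raise NetworkError(f"state is not racemic (gap {gap:g})")
    rhs = ode_rhs(net, state)
    if np.max(np.abs(rhs)) > tol * scale:
        raise NetworkError(
            f"state is not steady (max |dX/dt| {np.max(np.abs(rhs)):g})"
        )
    for cls in chiral.label_classes:
        vals = [state.rate_constants[lab] for lab in cls if lab in state.rate_constants]
        if vals and (max(vals) - min(vals)) > tol * max(vals):
            raise NetworkError(
                f"dual rate constants {cls} are not equal at this state"
            )
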