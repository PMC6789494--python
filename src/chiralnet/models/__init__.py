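"""Benchmark networks for mirror-symmetry-breaking analysis.

Ships the classic model networks of the homochirality literature as
plain-text fixtures (see ``data/``), a parameterized builder for the
activation-polymerization-epimerization-depolymerization (APED) model,
and a seeded random pseudochiral-network generator for property tests.

Species names are identifier-safe transliterations of the literature
notation; each fixture file records its name map in comments.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np

from ..chirality import ChiralStructure, check_pseudochiral
from ..network import ReactionNetwork, parse_network

__all__ = [
    "FIXTURE_NAMES",
    "fixture",
    "fixture_text",
    "expectations",
    "aped_variant",
    "iwamoto_imperfect_equalized",
    "random_pseudochiral",
]

FIXTURE_NAMES = (
    "theta0",
    "frank",
    "calvin",
    "aped",
    "replicator",
    "iwamoto_perfect",
    "iwamoto_imperfect",
)


def _data(name: str) -> str:
    return resources.files(__package__).joinpath("data", name).read_text()


def fixture_text(name: str) -> str:
    """The plain-text source of a fixture network."""
    if name == "aped":
        return _aped_text(alpha_distinct=True, beta_distinct=True, gamma_distinct=True)
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return _data(f"{name}.crn")


def fixture(name: str) -> tuple[ReactionNetwork, ChiralStructure]:
    """A benchmark network plus its verified enantiomeric structure."""
    net = parse_network(fixture_text(name))
    return net, check_pseudochiral(net)


def expectations() -> dict:
    """Declared pseudochirality order and qualitative verdict per fixture."""
    return json.loads(_data("expectations.json"))


# ---------------------------------------------------------------------------
# APED


def _aped_text(
    alpha_distinct: bool, beta_distinct: bool, gamma_distinct: bool
) -> str:
    """APED network text; primed labels collapse onto their base class when
    the corresponding stereoselectivity factor equals one."""
    kp2 = "kap" if alpha_distinct else "kp"
    kh2 = "kbh" if beta_distinct else "kh"
    ke2 = "kge" if gamma_distinct else "ke"
    lines = [
        "# activation-polymerization-epimerization-depolymerization model",
        "species L D Ls Ds LL DD LD DL",
        "pair L:D",
        "pair Ls:Ds",
        "pair LL:DD",
        "pair LD:DL",
        # activation / deactivation
        "L -> Ls | ka",
        "D -> Ds | ka",
        "Ls -> L | kb",
        "Ds -> D | kb",
        # polymerization (homochiral kp, heterochiral alpha*kp)
        "Ls + L -> LL | kp",
        "Ds + D -> DD | kp",
        f"Ds + L -> DL | {kp2}",
        f"Ls + D -> LD | {kp2}",
        # depolymerization (homochiral kh, heterochiral beta*kh)
        "LL -> L + L | kh",
        "DD -> D + D | kh",
        f"DL -> L + D | {kh2}",
        f"LD -> L + D | {kh2}",
        # epimerization (ke, reverse gamma*ke)
        "LD -> DD | ke",
        "DL -> LL | ke",
        f"DD -> LD | {ke2}",
        f"LL -> DL | {ke2}",
    ]
    return "\n".join(lines) + "\n"


def aped_variant(
    alpha: float = 0.5, beta: float = 0.5, gamma: float = 0.5
) -> ReactionNetwork:
    """APED network for given stereoselectivity factors (all > 0).

    The factors scale the heterochiral polymerization (alpha*p),
    depolymerization (beta*h) and reverse epimerization (gamma*e) rate
    constants.  A factor equal to 1 identifies the primed rate label with
    its base class (the sampler then explores the constrained network);
    factors different from 1 leave the primed labels free, the sampled
    states realizing the factors as rate-constant ratios.
    """
    for name, val in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    return parse_network(
        _aped_text(
            alpha_distinct=(alpha != 1),
            beta_distinct=(beta != 1),
            gamma_distinct=(gamma != 1),
        )
    )


# ---------------------------------------------------------------------------
# Iwamoto with the stability-restoring rate equalities


def iwamoto_imperfect_equalized() -> tuple[ReactionNetwork, ChiralStructure]:
    """Imperfect-condition model with k2=k2a=k4=k4a, k3=k3a=k5=k5a,
    k6=k6a=k8=k8a and k7=k7a=k9=k9a merged into single label classes."""
    net = parse_network(_data("iwamoto_imperfect.crn"))
    extra = (("k2", "k2a"), ("k3", "k3a"), ("k6", "k6a"), ("k7", "k7a"))
    net = ReactionNetwork(
        net.species,
        net.reactions,
        net.constant_species,
        net.pairs,
        net.duals + extra,
    )
    return net, check_pseudochiral(net)


# ---------------------------------------------------------------------------
# random pseudochiral networks (property-test inputs)


def random_pseudochiral(
    order_k: int,
    n_achiral: int,
    n_reactions: int,
    seed: int,
    max_coeff: int = 2,
    reversible: bool = False,
) -> tuple[ReactionNetwork, ChiralStructure]:
    """Seeded random pseudochiral network of the given order.

    ``n_reactions`` seed reactions are drawn with stoichiometric
    coefficients <= ``max_coeff`` and the set is closed under the L/D
    involution, dual partners sharing a rate label; the result always
    passes the pseudochirality check and is identical for identical
    inputs.  With ``reversible=True`` every seed reaction is paired with
    its reverse (own rate label), which guarantees a nontrivial
    steady-state cone (the forward=reverse current is always a steady
    current) -- the variant used to generate racemic steady states in
    property tests.
    """
    if order_k < 1:
        raise ValueError("order_k must be >= 1")
    rng = np.random.default_rng(seed)
    l_side = [f"L{i + 1}" for i in range(order_k)]
    d_side = [f"D{i + 1}" for i in range(order_k)]
    achiral = [f"A{i + 1}" for i in range(n_achiral)]
    species = l_side + d_side + achiral
    swap = {**{l: d for l, d in zip(l_side, d_side)},
            **{d: l for l, d in zip(l_side, d_side)},
            **{a: a for a in achiral}}

    def random_side() -> tuple[tuple[str, int], ...]:
        n_terms = int(rng.integers(0, 3))
        side: dict[str, int] = {}
        for _ in range(n_terms):
            s = species[int(rng.integers(0, len(species)))]
            side[s] = min(max_coeff, side.get(s, 0) + int(rng.integers(1, max_coeff + 1)))
        return tuple(sorted(side.items()))

    def involute(side):
        return tuple(sorted((swap[s], c) for s, c in side))

    seen: set[tuple] = set()
    reactions: list[tuple] = []  # (reactants, products, label)
    label_idx = 0
    attempts = 0
    while len(reactions) < n_reactions and attempts < 200 * n_reactions:
        attempts += 1
        lhs, rhs = random_side(), random_side()
        if lhs == rhs or (not lhs and not rhs):
            continue
        mlhs, mrhs = involute(lhs), involute(rhs)
        keys = [(lhs, rhs), (mlhs, mrhs)]
        if reversible:
            keys += [(rhs, lhs), (mrhs, mlhs)]
        if any(k in seen for k in keys):
            continue
        label = f"k{label_idx + 1}"
        label_idx += 1
        batches = [((lhs, rhs), (mlhs, mrhs), label)]
        if reversible:
            batches.append(((rhs, lhs), (mrhs, mlhs), f"k{label_idx}r"))
        for key, mkey, lab in batches:
            seen.add(key)
            reactions.append((*key, lab))
            if mkey != key:
                seen.add(mkey)
                reactions.append((*mkey, lab))

    lines = ["species " + " ".join(species)]
    lines += [f"pair {l}:{d}" for l, d in zip(l_side, d_side)]
    for lhs, rhs, label in reactions:
        def side_text(side):
            return " + ".join(f"{c} {s}" if c != 1 else s for s, c in side)
        lines.append(f"{side_text(lhs)} -> {side_text(rhs)} | {label}")
    net = parse_network("\n".join(lines) + "\n")
    return net, check_pseudochiral(net)
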