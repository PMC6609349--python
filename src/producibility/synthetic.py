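"""Deterministic toy and random metabolic networks with known structure.

These generators cover the motifs the producibility analysis must get
right — linear chains (disjunctive precursors), fan-in (alternative
routes), conjunctive reactions (AND-structure), and cofactor recycling
loops — plus random networks for property testing and a mid-size network
with native exchanges and a biomass reaction for the perturbation
experiment.  All fixtures use 1:1 stoichiometry, so nothing can be made
from nothing and PM = 1 can only arise via fixed-on inputs.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .network import MetabolicNetwork, Metabolite, Reaction

_C = "c"  # single cytosolic compartment for toy fixtures


def _met(mid: str) -> Metabolite:
    return Metabolite(mid, name=mid, compartment=_C)


def make_chain(n: int) -> MetabolicNetwork:
    """Linear chain M_1 → M_2 → … → M_n → T.

    Every intermediate M_i alone suffices to reach T, so the minimal
    precursor sets are the n singletons and the exact PM of T is 0.5^(1/n).
    """
    if n < 1:
        raise ValueError("chain length must be >= 1")
    mets = [_met(f"M{i}") for i in range(1, n + 1)] + [_met("T")]
    rxns = [
        Reaction(f"R{i}", {f"M{i}": -1.0, f"M{i + 1}": 1.0}, 0.0, 1000.0)
        for i in range(1, n)
    ]
    rxns.append(Reaction(f"R{n}", {f"M{n}": -1.0, "T": 1.0}, 0.0, 1000.0))
    return MetabolicNetwork(mets, rxns)


def make_fan_in(k: int) -> MetabolicNetwork:
    """k independent single-step routes P_i → T; PM solves 1−(1−p)^k = 0.5."""
    if k < 1:
        raise ValueError("fan-in width must be >= 1")
    mets = [_met(f"P{i}") for i in range(1, k + 1)] + [_met("T")]
    rxns = [
        Reaction(f"R{i}", {f"P{i}": -1.0, "T": 1.0}, 0.0, 1000.0)
        for i in range(1, k + 1)
    ]
    return MetabolicNetwork(mets, rxns)


def make_conjunctive(k: int) -> MetabolicNetwork:
    """One reaction consuming k distinct substrates; PM = 1 − 0.5^(1/k)."""
    if k < 1:
        raise ValueError("substrate count must be >= 1")
    mets = [_met(f"P{i}") for i in range(1, k + 1)] + [_met("T")]
    stoich = {f"P{i}": -1.0 for i in range(1, k + 1)}
    stoich["T"] = 1.0
    return MetabolicNetwork(mets, [Reaction("R1", stoich, 0.0, 1000.0)])


def make_cofactor_loop(n_recycle: int = 4) -> MetabolicNetwork:
    """Cofactor-coupled production with recycling routes.

    The target reaction A + NADH → T + NAD is coupled to ``n_recycle``
    recycling reactions X_i + NAD → Y_i + NADH.  Because the LP treats
    cofactor cycling as internal flux, T is producible from {A, X_i} for
    any i (the NADH/NAD pair cycles with zero net input) or from
    {A, NADH}.  With several recycling routes the cofactor is almost never
    limiting, so PM(T) approaches the PM of the plain chain A → T (0.5);
    deleting the recycling reactions leaves only {A, NADH} and lowers
    PM(T) to 1 − √0.5 ≈ 0.293.
    """
    if n_recycle < 0:
        raise ValueError("n_recycle must be >= 0")
    mets = [_met("A"), _met("NADH"), _met("NAD"), _met("T")]
    rxns = [
        Reaction("R_target", {"A": -1.0, "NADH": -1.0, "T": 1.0, "NAD": 1.0}, 0.0, 1000.0)
    ]
    for i in range(1, n_recycle + 1):
        mets += [_met(f"X{i}"), _met(f"Y{i}")]
        rxns.append(
            Reaction(
                f"R_recycle{i}",
                {f"X{i}": -1.0, "NAD": -1.0, f"Y{i}": 1.0, "NADH": 1.0},
                0.0,
                1000.0,
            )
        )
    return MetabolicNetwork(mets, rxns)


def make_random(
    n_mets: int,
    n_rxns: int,
    reversibility: float = 0.0,
    seed: int = 0,
    max_substrates: int = 2,
    n_candidates: Optional[int] = None,
) -> MetabolicNetwork:
    """Random 1:1-stoichiometry network with target T reachable by design.

    Metabolites C1..C{n_mets} feed a target T.  The first reaction always
    converts C1 → T so the target is producible from the full pool; the
    remaining reactions draw 1..max_substrates random substrates and one
    random product (biased towards T-adjacent metabolites), with the given
    fraction made reversible.  When ``n_candidates`` is set, only
    C1..C{n_candidates} take part in reactions, keeping the enumerable
    candidate pool small while extra isolated metabolites pad the network.
    """
    if n_mets < 1 or n_rxns < 1:
        raise ValueError("need at least one metabolite and one reaction")
    rng = np.random.default_rng(seed)
    pool = min(n_candidates or n_mets, n_mets)
    cands = [f"C{i}" for i in range(1, n_mets + 1)]
    active = cands[:pool]
    mets = [_met(c) for c in cands] + [_met("T")]
    rxns: List[Reaction] = [Reaction("R1", {"C1": -1.0, "T": 1.0}, 0.0, 1000.0)]
    for j in range(2, n_rxns + 1):
        n_sub = int(rng.integers(1, max_substrates + 1))
        subs = list(rng.choice(active, size=min(n_sub, len(active)), replace=False))
        # product: T with probability 0.3, else another active metabolite
        if rng.random() < 0.3:
            prod = "T"
        else:
            choices = [c for c in active if c not in subs]
            prod = str(rng.choice(choices)) if choices else "T"
        stoich = {s: -1.0 for s in subs}
        stoich[prod] = stoich.get(prod, 0.0) + 1.0
        if prod in subs:
            continue  # degenerate draw; keep the id sequence deterministic anyway
        lb = -1000.0 if rng.random() < reversibility else 0.0
        rxns.append(Reaction(f"R{j}", stoich, lb, 1000.0))
    return MetabolicNetwork(mets, rxns)


def make_perturbation_network(
    n_internal: int = 60,
    n_nutrients: int = 8,
    n_biomass: int = 20,
    n_reactions: int = 300,
    redundancy: int = 3,
    seed: int = 0,
) -> MetabolicNetwork:
    """Mid-size network with native exchanges, biomass and maintenance.

    Built for the reaction-removal robustness experiment: nutrients
    N1..N{n_nutrients} enter through native exchange reactions, a random
    layered core of internal metabolites C1..C{n_internal} is wired with
    multiple alternative routes (``redundancy`` producing reactions per
    metabolite on average), biomass components B1..B{n_biomass} each have a
    few alternative synthesis routes, and a single biomass reaction
    consumes all components.  The unperturbed network supports biomass
    production on the minimal medium (glucose-like single nutrient N1).
    """
    rng = np.random.default_rng(seed)
    nutrients = [f"N{i}" for i in range(1, n_nutrients + 1)]
    internal = [f"C{i}" for i in range(1, n_internal + 1)]
    biomass_mets = [f"B{i}" for i in range(1, n_biomass + 1)]
    mets = [_met(m) for m in nutrients + internal + biomass_mets + ["BIOMASS"]]

    rxns: List[Reaction] = []
    rid = 0

    def add(stoich, lb=0.0, ub=1000.0, name=""):
        nonlocal rid
        rid += 1
        rxns.append(Reaction(f"R{rid:04d}", stoich, lb, ub, name=name))

    # native exchanges (COBRA convention: negative flux = uptake)
    for n in nutrients:
        rxns.append(Reaction(f"EX_{n}", {n: -1.0}, -1000.0, 1000.0))
    # maintenance placeholder (protected, never in the removal pool)
    add({internal[0]: -1.0, internal[1]: 1.0}, name="ATP maintenance")

    # entry reactions: the backbone nutrient N1 (the minimal medium) feeds
    # every early metabolite, the remaining nutrients feed 2 random ones
    early = internal[: max(4, n_internal // 4)]
    for e in early:
        add({nutrients[0]: -1.0, e: 1.0})
    for n in nutrients[1:]:
        for tgt in rng.choice(early, size=2, replace=False):
            add({n: -1.0, str(tgt): 1.0})

    # layered random core: metabolite C_i is produced from earlier layers,
    # with `redundancy` alternative routes on average
    for i, met in enumerate(internal):
        if met in early:
            continue
        upstream = internal[:i] if i else early
        for _ in range(redundancy):
            n_sub = int(rng.integers(1, 3))
            subs = rng.choice(upstream, size=min(n_sub, len(upstream)), replace=False)
            stoich = {str(s): -1.0 for s in subs}
            stoich[met] = 1.0
            add(stoich)

    # biomass components: 2-3 alternative routes each, 1-2 substrates
    for b in biomass_mets:
        for _ in range(int(rng.integers(2, 4))):
            n_sub = int(rng.integers(1, 3))
            subs = rng.choice(internal, size=n_sub, replace=False)
            stoich = {str(s): -1.0 for s in subs}
            stoich[b] = 1.0
            add(stoich)

    # filler conversions up to the requested reaction count (biomass rxn last)
    while len(rxns) < n_reactions - 1:
        a, b = rng.choice(internal, size=2, replace=False)
        add({str(a): -1.0, str(b): 1.0})

    biomass_stoich = {b: -1.0 for b in biomass_mets}
    biomass_stoich["BIOMASS"] = 1.0
    rxns.append(Reaction("BIOMASS_RXN", biomass_stoich, 0.0, 1000.0, name="biomass"))
    rxns.append(Reaction("EX_BIOMASS", {"BIOMASS": -1.0}, 0.0, 1000.0))
    return MetabolicNetwork(mets, rxns)
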