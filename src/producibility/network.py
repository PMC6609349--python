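"""Core in-memory representation of a stoichiometric metabolic network.

A network is a list of metabolites (each tagged with a compartment), a list
of reactions (sparse stoichiometry plus flux bounds), and an optional
gene→reaction association map.  The representation is deliberately plain:
it carries exactly the information the producibility analysis needs — the
stoichiometric matrix S, the bounds lb/ub, and enough metadata to detect
boundary and maintenance reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Mapping


class NetworkValidationError(ValueError):
    """Raised when a network violates a structural invariant."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    """A reaction with sparse stoichiometry and flux bounds.

    Stoichiometric coefficients are signed: negative for substrates,
    positive for products.  Bounds encode reversibility (lb < 0) and
    knockouts (lb = ub = 0).
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    name: str = ""

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0


@dataclass
class MetabolicNetwork:
    metabolites: List[Metabolite]
    reactions: List[Reaction]
    gene_assoc: Dict[str, FrozenSet[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookup helpers ------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for r in self.reactions:
            if not r.stoichiometry:
                raise NetworkValidationError(f"reaction {r.id} has empty stoichiometry")
            unknown = set(r.stoichiometry) - known
            if unknown:
                raise NetworkValidationError(
                    f"reaction {r.id} references undeclared metabolites: {sorted(unknown)}"
                )
            if r.lower_bound > r.upper_bound:
                raise NetworkValidationError(
                    f"reaction {r.id} has lb={r.lower_bound} > ub={r.upper_bound}"
                )
        for gene, rxns in self.gene_assoc.items():
            missing = set(rxns) - set(rxn_ids)
            if missing:
                raise NetworkValidationError(
                    f"gene {gene} maps to unknown reactions: {sorted(missing)}"
                )
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}

    # -- copy-on-write edits --------------------------------------------
    def with_reaction_bounds(self, bounds: Mapping[str, tuple]) -> "MetabolicNetwork":
        """Return a copy with the given reactions' bounds replaced."""
        new_rxns = [
            r.with_bounds(*bounds[r.id]) if r.id in bounds else r for r in self.reactions
        ]
        return MetabolicNetwork(list(self.metabolites), new_rxns, dict(self.gene_assoc))

    def without_reactions(self, rxn_ids) -> "MetabolicNetwork":
        """Return a copy with the given reactions deleted (metabolites kept)."""
        drop = set(rxn_ids)
        new_rxns = [r for r in self.reactions if r.id not in drop]
        new_genes = {
            g: frozenset(rs - drop) for g, rs in self.gene_assoc.items() if rs - drop
        }
        return MetabolicNetwork(list(self.metabolites), new_rxns, new_genes)
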