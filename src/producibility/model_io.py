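"""Read/write metabolic networks and standardize them for producibility analysis.

SBML (Level 3 + FBC) and COBRA JSON files are parsed through cobrapy and
converted to the plain :class:`~producibility.network.MetabolicNetwork`
container.  :func:`prepare_model` then standardizes a network the way the
percolation analysis expects: native exchange and maintenance reactions are
switched off, and a fresh pair of import/export exchange reactions is added
for every metabolite so that environment composition and the inequality
mass-balance relaxation can be controlled purely through bounds.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Optional, Set, Tuple

import pandas as pd

from .network import MetabolicNetwork, Metabolite, NetworkValidationError, Reaction

logger = logging.getLogger(__name__)

#: id prefixes conventionally used for boundary reactions (COBRA/KBase).
BOUNDARY_PREFIXES = ("EX_", "DM_", "SK_")

#: compartment tags / id suffixes conventionally marking extracellular species.
_EXTRACELLULAR_COMPARTMENTS = {"e", "e0", "extracellular", "c_e", "extraorganism"}
_EXTRACELLULAR_SUFFIX = re.compile(r"(_e\d*$|\[e\]$)")


class FormatError(ValueError):
    """Raised when a model file cannot be parsed under the named standard."""


@dataclass
class PreparedModel:
    """A network standardized for producibility analysis.

    ``base`` keeps the original reactions (with native exchanges and
    maintenance zeroed out); every metabolite additionally gets one import
    exchange (∅ → met) and one export exchange (met → ∅), both initially
    closed.  The percolation and feasibility modules open these by bounds.
    """

    base: MetabolicNetwork
    import_exchange: Dict[str, str]
    export_exchange: Dict[str, str]
    intracellular: FrozenSet[str]
    extracellular: FrozenSet[str]
    disabled_native: FrozenSet[str]
    _full: MetabolicNetwork = field(repr=False, default=None)

    @property
    def network(self) -> MetabolicNetwork:
        """The base network plus all added exchange reactions (all closed)."""
        return self._full

    @property
    def metabolite_ids(self):
        return self.base.metabolite_ids


def read_network(path, fmt: Optional[str] = None) -> MetabolicNetwork:
    """Read an SBML or COBRA-JSON model file into a MetabolicNetwork.

    Parameters
    ----------
    path:
        Model file.  When ``fmt`` is None the format is inferred from the
        extension (``.xml``/``.sbml`` → sbml, ``.json`` → cobra_json).
    fmt:
        ``"sbml"`` or ``"cobra_json"``.
    """
    import cobra.io

    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {"": "sbml", ".xml": "sbml", ".sbml": "sbml", ".json": "cobra_json"}.get(
            suffix, "sbml"
        )
    if fmt not in ("sbml", "cobra_json"):
        raise ValueError(f"unknown format {fmt!r}; expected 'sbml' or 'cobra_json'")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "sbml":
            model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:  # pragma: no cover - cobra error classes vary
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    return from_cobra(model)


def from_cobra(model) -> MetabolicNetwork:
    """Convert a cobrapy Model to a MetabolicNetwork."""
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "") for m in model.metabolites
    ]
    rxns = []
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        rxns.append(
            Reaction(
                r.id,
                stoich,
                float(r.lower_bound),
                float(r.upper_bound),
                name=r.name or "",
            )
        )
    genes = {
        g.id: frozenset(rx.id for rx in g.reactions) for g in model.genes if g.reactions
    }
    try:
        return MetabolicNetwork(mets, rxns, genes)
    except NetworkValidationError as exc:
        raise FormatError(f"model failed validation: {exc}") from exc


def to_cobra(net: MetabolicNetwork, model_id: str = "model"):
    """Convert a MetabolicNetwork to a cobrapy Model (for writing)."""
    import cobra

    model = cobra.Model(model_id)
    cobra_mets = {}
    for m in net.metabolites:
        cm = cobra.Metabolite(m.id, name=m.name, compartment=m.compartment or "c")
        cobra_mets[m.id] = cm
    model.add_metabolites(list(cobra_mets.values()))
    rxns = []
    for r in net.reactions:
        cr = cobra.Reaction(r.id, name=r.name)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    model.add_reactions(rxns)
    for r in net.reactions:
        model.reactions.get_by_id(r.id).add_metabolites(
            {cobra_mets[k]: v for k, v in r.stoichiometry.items()}
        )
    return model


def write_network(net: MetabolicNetwork, path, fmt: Optional[str] = None) -> None:
    """Write a network as SBML or COBRA JSON."""
    import cobra.io

    path = Path(path)
    if fmt is None:
        fmt = "cobra_json" if path.suffix.lower() == ".json" else "sbml"
    model = to_cobra(net, model_id=path.stem or "model")
    if fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    elif fmt == "cobra_json":
        cobra.io.save_json_model(model, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def classify_compartments(
    net: MetabolicNetwork,
) -> Tuple[Set[str], Set[str]]:
    """Partition metabolites into (intracellular, extracellular) by convention.

    A metabolite is extracellular when its compartment tag or id suffix
    matches a standard extracellular convention (``_e``, ``[e]``, ``_e0``,
    compartment named "extracellular", ...).  Everything else — including
    metabolites with unrecognized tags — defaults to intracellular, which is
    the conservative choice for the candidate-input pool.
    """
    intra: Set[str] = set()
    extra: Set[str] = set()
    for m in net.metabolites:
        comp = (m.compartment or "").strip().lower()
        if comp in _EXTRACELLULAR_COMPARTMENTS or _EXTRACELLULAR_SUFFIX.search(m.id):
            extra.add(m.id)
        else:
            if comp and comp not in {"c", "c0", "cytosol", "cytoplasm", "in", "p", "p0",
                                     "periplasm", "intracellular", "c_c"}:
                logger.debug("unknown compartment %r for %s; treating as intracellular",
                             m.compartment, m.id)
            intra.add(m.id)
    return intra, extra


def is_boundary_reaction(rxn: Reaction) -> bool:
    """Native exchange/demand/sink detection: single-metabolite stoichiometry
    or a conventional boundary id prefix."""
    if len(rxn.stoichiometry) == 1:
        return True
    return rxn.id.startswith(BOUNDARY_PREFIXES)


def is_maintenance_reaction(rxn: Reaction) -> bool:
    rid = rxn.id.lower()
    return rid == "atpm" or "maintenance" in rxn.name.lower() or "maintenance" in rid


def prepare_model(net: MetabolicNetwork) -> PreparedModel:
    """Standardize a network for producibility analysis.

    Native boundary and maintenance reactions are switched off (bounds
    zeroed, recorded in ``disabled_native``); a closed import exchange
    (∅ → met) and export exchange (met → ∅) is added for every metabolite.
    Base stoichiometry is otherwise untouched.
    """
    disabled = {
        r.id
        for r in net.reactions
        if is_boundary_reaction(r) or is_maintenance_reaction(r)
    }
    base = net.with_reaction_bounds({rid: (0.0, 0.0) for rid in disabled})

    existing = set(base.reaction_ids)
    import_exchange: Dict[str, str] = {}
    export_exchange: Dict[str, str] = {}
    extra_rxns = []
    for m in base.metabolites:
        imp_id, exp_id = f"IMP__{m.id}", f"EXP__{m.id}"
        if imp_id in existing or exp_id in existing:  # pragma: no cover
            raise NetworkValidationError(f"exchange id collision for {m.id}")
        import_exchange[m.id] = imp_id
        export_exchange[m.id] = exp_id
        extra_rxns.append(Reaction(imp_id, {m.id: 1.0}, 0.0, 0.0))
        extra_rxns.append(Reaction(exp_id, {m.id: -1.0}, 0.0, 0.0))

    full = MetabolicNetwork(
        list(base.metabolites), list(base.reactions) + extra_rxns, dict(base.gene_assoc)
    )
    intra, extra = classify_compartments(net)
    return PreparedModel(
        base=base,
        import_exchange=import_exchange,
        export_exchange=export_exchange,
        intracellular=frozenset(intra),
        extracellular=frozenset(extra),
        disabled_native=frozenset(disabled),
        _full=full,
    )


# ---------------------------------------------------------------------------
# PM matrix TSV round trip
# ---------------------------------------------------------------------------

def write_pm_matrix(matrix: pd.DataFrame, path) -> None:
    """Write an organisms × metabolites PM matrix as TSV (headers both axes)."""
    matrix.to_csv(path, sep="\t", index_label="organism")


def read_pm_matrix(path) -> pd.DataFrame:
    """Read a PM matrix TSV written by :func:`write_pm_matrix`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed PM matrix {path}: {exc}") from exc
    df.index.name = "organism"
    return df
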