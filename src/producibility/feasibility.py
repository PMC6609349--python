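"""LP-based producibility feasibility and plain FBA.

The central question answered here: given a prepared network and a set of
input metabolites (whose import exchanges are open), can the network carry a
steady-state flux that produces a target metabolite above a small threshold?

Mass balance comes in two flavours:

``inequality``
    S v ≥ 0 — net accumulation of any metabolite is allowed.  Implemented by
    opening every export exchange, so byproducts can always be drained.
    This is the default for producibility analysis, which probes a local
    property (production of one metabolite) and should not be constrained by
    a global steady-state requirement.

``equality``
    S v = 0 — strict steady state; only the targets' exports are open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Optional, Set, Union

from .lp import INFEASIBLE, OPTIMAL, UNBOUNDED, LinearProgram
from .model_io import PreparedModel, is_boundary_reaction
from .network import MetabolicNetwork

#: flux bound used for open exchange reactions; feasibility is scale-free
#: above the threshold, so any large positive cap works.
EXCHANGE_BOUND = 1000.0

#: minimum export flux for a metabolite to count as produced.
PRODUCIBILITY_THRESHOLD = 1e-3


@dataclass(frozen=True)
class FeasibilityQuery:
    inputs: FrozenSet[str]
    targets: FrozenSet[str]
    balance: str = "inequality"
    threshold: float = PRODUCIBILITY_THRESHOLD

    def __post_init__(self):
        if self.balance not in ("inequality", "equality"):
            raise ValueError(f"unknown balance mode {self.balance!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not self.targets:
            raise ValueError("query needs at least one target")


class FeasibilitySolver:
    """Reusable solver bound to one PreparedModel.

    The LP is built once; each query only flips exchange bounds and the
    objective, then restores them.  Results are memoized per
    (inputs, targets, balance) so repeated environment samples on small
    candidate pools cost a dictionary lookup.
    """

    def __init__(self, prep: PreparedModel, cache: bool = True):
        self.prep = prep
        net = prep.network
        self._col: Dict[str, int] = {r.id: j for j, r in enumerate(net.reactions)}
        self._lp = LinearProgram(len(net.metabolites), len(net.reactions))
        row = {m.id: i for i, m in enumerate(net.metabolites)}
        entries = []
        for j, r in enumerate(net.reactions):
            for met, coef in r.stoichiometry.items():
                entries.append((row[met], j, coef))
        self._lp.set_matrix(entries)
        for j, r in enumerate(net.reactions):
            self._lp.set_col_bounds(j, r.lower_bound, r.upper_bound)
        self._cache: Optional[dict] = {} if cache else None
        self.n_lp_calls = 0

    def _import_col(self, met: str) -> int:
        try:
            return self._col[self.prep.import_exchange[met]]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met!r}") from None

    def _export_col(self, met: str) -> int:
        try:
            return self._col[self.prep.export_exchange[met]]
        except KeyError:
            raise KeyError(f"unknown metabolite id {met!r}") from None

    def feasible(self, query: FeasibilityQuery) -> bool:
        key = None
        if self._cache is not None:
            key = (query.inputs, query.targets, query.balance)
            hit = self._cache.get(key)
            if hit is not None:
                return hit
        result = self._solve(query)
        if self._cache is not None:
            self._cache[key] = result
        return result

    def _solve(self, query: FeasibilityQuery) -> bool:
        self.n_lp_calls += 1
        lp = self._lp
        changed = []  # (col, lb, ub) to restore

        def set_bounds(col: int, lb: float, ub: float):
            changed.append(col)
            lp.set_col_bounds(col, lb, ub)

        mets = self.prep.metabolite_ids
        # imports: open only for query.inputs
        for met in query.inputs:
            set_bounds(self._import_col(met), 0.0, EXCHANGE_BOUND)
        # exports: inequality balance opens all of them
        if query.balance == "inequality":
            for met in mets:
                set_bounds(self._export_col(met), 0.0, EXCHANGE_BOUND)
        try:
            if len(query.targets) == 1:
                (target,) = query.targets
                tcol = self._export_col(target)
                set_bounds(tcol, 0.0, EXCHANGE_BOUND)
                lp.set_objective({tcol: 1.0})
                status, obj = lp.solve()
                if status == UNBOUNDED:  # pragma: no cover - exports are capped
                    return True
                return status == OPTIMAL and obj > query.threshold
            # joint production: each target's export must carry >= threshold
            for met in query.targets:
                set_bounds(self._export_col(met), query.threshold, EXCHANGE_BOUND)
            lp.set_objective({})
            status, _ = lp.solve()
            return status in (OPTIMAL, UNBOUNDED)
        finally:
            net = self.prep.network
            rxns = net.reactions
            for col in changed:
                r = rxns[col]
                lp.set_col_bounds(col, r.lower_bound, r.upper_bound)


def feas(
    prep: PreparedModel,
    query_or_inputs: Union[FeasibilityQuery, Iterable[str]],
    targets: Optional[Iterable[str]] = None,
    balance: str = "inequality",
    threshold: float = PRODUCIBILITY_THRESHOLD,
    solver: Optional[FeasibilitySolver] = None,
) -> bool:
    """Decide whether the targets are producible from the given inputs.

    Either pass a :class:`FeasibilityQuery`, or inputs/targets directly.
    A shared :class:`FeasibilitySolver` may be supplied to amortize LP
    construction across many calls.
    """
    if isinstance(query_or_inputs, FeasibilityQuery):
        query = query_or_inputs
    else:
        if targets is None:
            raise ValueError("targets required when not passing a FeasibilityQuery")
        tset = frozenset([targets] if isinstance(targets, str) else targets)
        query = FeasibilityQuery(
            frozenset(query_or_inputs), tset, balance=balance, threshold=threshold
        )
    if solver is None:
        solver = FeasibilitySolver(prep, cache=False)
    return solver.feasible(query)


# ---------------------------------------------------------------------------
# Plain FBA on the native network
# ---------------------------------------------------------------------------

def _native_exchanges(net: MetabolicNetwork) -> Dict[str, str]:
    """Map metabolite id → native boundary reaction id (first match wins)."""
    out: Dict[str, str] = {}
    for r in net.reactions:
        if is_boundary_reaction(r) and len(r.stoichiometry) == 1:
            (met,) = r.stoichiometry
            out.setdefault(met, r.id)
    return out


def fba_biomass(
    net: MetabolicNetwork,
    medium: Union[Set[str], str],
    objective_reaction: str,
    uptake_bound: float = EXCHANGE_BOUND,
) -> float:
    """Maximize a biomass/objective reaction under standard equality FBA.

    ``medium`` is either the string ``"complete"`` (all native exchange
    imports open) or a set of metabolite ids whose native exchanges are
    opened for uptake.  Native exchanges follow the COBRA sign convention:
    negative flux = uptake.  An infeasible LP returns 0 (biomass not
    producible), not an exception.
    """
    if not net.has_reaction(objective_reaction):
        raise KeyError(f"objective reaction {objective_reaction!r} not in network")
    exchanges = _native_exchanges(net)
    lp = LinearProgram(len(net.metabolites), len(net.reactions))
    row = {m.id: i for i, m in enumerate(net.metabolites)}
    col = {r.id: j for j, r in enumerate(net.reactions)}
    entries = []
    for j, r in enumerate(net.reactions):
        for met, coef in r.stoichiometry.items():
            entries.append((row[met], j, coef))
    lp.set_matrix(entries)
    exchange_ids = set(exchanges.values())
    if medium == "complete":
        open_mets = set(exchanges)
    else:
        open_mets = set(medium)
    for j, r in enumerate(net.reactions):
        lb, ub = r.lower_bound, r.upper_bound
        if r.id in exchange_ids:
            # uptake blocked unless the metabolite is in the medium
            (met,) = r.stoichiometry
            coef = r.stoichiometry[met]
            if met in open_mets:
                if coef < 0:  # EX_x: x ->, negative flux imports
                    lb, ub = -uptake_bound, max(ub, 0.0)
                else:
                    lb, ub = min(lb, 0.0), uptake_bound
            else:
                if coef < 0:
                    lb = max(lb, 0.0)
                    ub = max(ub, lb)
                else:
                    ub = min(ub, 0.0)
                    lb = min(lb, ub)
    # exports always allowed through the boundary reaction's secretion side
        lp.set_col_bounds(j, lb, ub)
    lp.set_objective({col[objective_reaction]: 1.0})
    status, obj = lp.solve()
    if status == INFEASIBLE:
        return 0.0
    if status == UNBOUNDED:  # pragma: no cover
        return float("inf")
    return max(obj, 0.0)
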