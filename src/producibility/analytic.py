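"""Exact producibility on small networks: the combinatorial counterpart of
the sampling estimator.

Feasibility is monotone in the input set, so the feasible subsets of a
candidate pool form an upward-closed family fully described by its
antichain of inclusion-minimal members — the minimal precursor sets.  With
independent Bernoulli inputs at probability ``p`` the exact producibility is

    P_out(p) = Σ_k c_k · p^k (1−p)^(m−k)

where ``c_k`` counts feasible subsets of size ``k`` among ``m`` candidates.
The PM follows as 1 minus the unique root of ``P_out(p) = 0.5``.  For a
linear chain of ``n`` independent single-metabolite precursors this gives
the closed form PM = 0.5^(1/n); for a single conjunctive reaction with
``k`` substrates, PM = 1 − 0.5^(1/k).

Everything here is exact by construction and serves as the independent
oracle for the sampling estimator on enumerable fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import FrozenSet, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import brentq

from .feasibility import FeasibilityQuery, FeasibilitySolver
from .model_io import PreparedModel
from .network import MetabolicNetwork

ENUMERATION_CAP = 20


class EnumerationCapError(ValueError):
    """Candidate pool too large for exhaustive enumeration."""


@dataclass(frozen=True)
class PrecursorStructure:
    candidates: Tuple[str, ...]
    minimal_sets: Tuple[FrozenSet[str], ...]
    poly: Tuple[int, ...]  # c_k = number of feasible subsets of size k

    @property
    def m(self) -> int:
        return len(self.candidates)

    @property
    def empty_feasible(self) -> bool:
        return bool(self.minimal_sets) and min(len(s) for s in self.minimal_sets) == 0


def enumerate_structure(
    prep: PreparedModel,
    target: Union[str, Sequence[str]],
    candidates: Optional[Sequence[str]] = None,
    balance: str = "inequality",
    cap: int = ENUMERATION_CAP,
    solver: Optional[FeasibilitySolver] = None,
) -> PrecursorStructure:
    """Exhaustively determine the minimal precursor sets and subset counts.

    Subsets are visited in increasing size; a subset containing a known
    minimal set is feasible without solving (monotonicity), so LPs are only
    spent on potential new minimal sets.
    """
    tset = frozenset([target] if isinstance(target, str) else target)
    if candidates is None:
        cands = sorted(prep.intracellular - tset)
    else:
        cands = list(candidates)
    m = len(cands)
    if m > cap:
        raise EnumerationCapError(
            f"{m} candidates exceed the enumeration cap ({cap}); "
            "use the sampling estimator (calc_pm) instead"
        )
    if solver is None:
        solver = FeasibilitySolver(prep)

    minimal: List[FrozenSet[str]] = []
    for size in range(0, m + 1):
        for combo in combinations(cands, size):
            s = frozenset(combo)
            if any(ms <= s for ms in minimal):
                continue
            q = FeasibilityQuery(s, tset, balance=balance)
            if solver.feasible(q):
                minimal.append(s)  # minimal: contains no smaller feasible set

    poly = _subset_counts(cands, minimal)
    return PrecursorStructure(tuple(cands), tuple(minimal), tuple(poly))


def _subset_counts(cands: Sequence[str], minimal: Sequence[FrozenSet[str]]) -> np.ndarray:
    """c_k for k = 0..m via bitmask sweep over all 2^m subsets."""
    m = len(cands)
    idx = {c: i for i, c in enumerate(cands)}
    subsets = np.arange(1 << m, dtype=np.uint64)
    feasible = np.zeros(1 << m, dtype=bool)
    for ms in minimal:
        mask = np.uint64(sum(1 << idx[c] for c in ms))
        feasible |= (subsets & mask) == mask
    sizes = np.bitwise_count(subsets)
    counts = np.bincount(sizes[feasible].astype(np.int64), minlength=m + 1)
    return counts[: m + 1]


def exact_pout(structure: PrecursorStructure, p: float) -> float:
    """Evaluate the exact producibility polynomial at input probability p."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    m = structure.m
    k = np.arange(m + 1)
    c = np.asarray(structure.poly, dtype=float)
    # guard 0**0 at the boundaries
    with np.errstate(divide="ignore"):
        terms = c * np.power(float(p), k) * np.power(1.0 - float(p), m - k)
    return float(np.sum(terms))


def pout_inclusion_exclusion(structure: PrecursorStructure, p: float) -> float:
    """Independent evaluation of P_out by inclusion–exclusion over minimal sets.

    P(some minimal set fully present) expanded over non-empty subfamilies;
    used as a cross-check of the subset-count polynomial.
    """
    sets = structure.minimal_sets
    n = len(sets)
    total = 0.0
    for r in range(1, n + 1):
        for fam in combinations(sets, r):
            union = frozenset().union(*fam)
            total += (-1) ** (r + 1) * p ** len(union)
    return total


def analytic_pm(structure: PrecursorStructure, tol: float = 1e-10) -> float:
    """PM = 1 − root of P_out(p) = 0.5, solved by bracketed root finding.

    Conventions: no minimal set at all → PM = 0; the empty set feasible
    (P_out ≡ 1) → PM = 1.
    """
    if not structure.minimal_sets:
        return 0.0
    if structure.empty_feasible:
        return 1.0
    f = lambda p: exact_pout(structure, p) - 0.5
    root = brentq(f, 0.0, 1.0, xtol=tol)
    return 1.0 - float(root)


def pathway_scores(
    net: MetabolicNetwork, pathway_reactions: Sequence[str]
) -> Tuple[int, int]:
    """Pathway completeness scores for an ordered linear pathway.

    ``pathway_reactions`` runs from the reaction adjacent to the target
    backwards.  Returns (pathway_sum, pathway_length): the number of listed
    reactions present in the model, and the length of the unbroken present
    prefix starting at the target end.  A knocked-out reaction (bounds
    fixed at zero) counts as absent.
    """
    present = []
    for rid in pathway_reactions:
        if not net.has_reaction(rid):
            present.append(False)
            continue
        r = net.reaction(rid)
        present.append(not (r.lower_bound == 0.0 and r.upper_bound == 0.0))
    pathway_sum = sum(present)
    pathway_length = 0
    for ok in present:
        if not ok:
            break
        pathway_length += 1
    return pathway_sum, pathway_length
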