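"""Structured in-silico experiments: reaction-removal robustness and gene
knockouts.

The perturbation study mirrors the classic draft-network scenario: starting
from an intact network, remove ``n`` random reactions (the biomass and
maintenance reactions are protected), then compare how FBA biomass flux and
the producibility metric of the biomass components degrade relative to the
intact network.  FBA collapses as soon as any essential route is cut; the
PM, probing many alternative routes, degrades gradually — the property the
producibility analysis exists to exploit on gappy networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .feasibility import FeasibilitySolver, fba_biomass
from .model_io import is_maintenance_reaction, prepare_model
from .network import MetabolicNetwork
from .percolation import PMParams, calc_pm

logger = logging.getLogger(__name__)


def remove_random_reactions(
    net: MetabolicNetwork,
    n: int,
    protected: Iterable[str],
    rng: np.random.Generator,
) -> MetabolicNetwork:
    """Delete n uniformly chosen reactions, never touching protected ones."""
    protected = set(protected)
    removable = [r.id for r in net.reactions if r.id not in protected]
    if n > len(removable):
        raise ValueError(f"cannot remove {n} of {len(removable)} removable reactions")
    removed = rng.choice(removable, size=n, replace=False)
    return net.without_reactions(set(str(r) for r in removed))


def knockout_genes(net: MetabolicNetwork, genes: Iterable[str]) -> MetabolicNetwork:
    """Zero the bounds of every reaction associated with the given genes.

    All reactions touched by a knocked-out gene are disabled, including
    those shared with isoenzymes.  Stoichiometry and reaction count are
    unchanged — only bounds move.
    """
    genes = set(genes)
    unknown = genes - set(net.gene_assoc)
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)}")
    hit: Set[str] = set()
    for g in genes:
        hit |= net.gene_assoc[g]
    return net.with_reaction_bounds({rid: (0.0, 0.0) for rid in hit})


@dataclass(frozen=True)
class PerturbationResult:
    level: int
    replicate: int
    fba_accuracy_minimal: float
    fba_accuracy_complete: float
    pm_accuracy: float
    fba_biomass_ok_minimal: bool
    fba_biomass_ok_complete: bool
    pm_biomass_ok_low: bool
    pm_biomass_ok_high: bool


def _pm_vector(
    net: MetabolicNetwork,
    components: Sequence[str],
    params: PMParams,
    base_seed: int,
) -> np.ndarray:
    """PM of each component, with per-component RNG streams derived from a
    fixed base seed.  Every network (intact or perturbed) is scored with the
    same streams — common random numbers — so an unperturbed copy scores
    accuracy exactly 1 and sampling noise partially cancels in differences."""
    prep = prepare_model(net)
    solver = FeasibilitySolver(prep)
    pms = []
    for j, c in enumerate(components):
        rng = np.random.default_rng(np.random.SeedSequence([base_seed, j]))
        pms.append(calc_pm(prep, c, params=params, rng=rng, solver=solver).pm)
    return np.array(pms)


def perturbation_study(
    net: MetabolicNetwork,
    biomass_components: Sequence[str],
    objective_reaction: str,
    minimal_medium: Set[str],
    levels: Sequence[int] = (4, 16, 64, 256, 1024),
    reps: int = 50,
    pm_params: Optional[PMParams] = None,
    protected: Iterable[str] = (),
    rng: Optional[np.random.Generator] = None,
    pm_threshold_low: float = 0.1,
    pm_threshold_high: float = 0.6,
    fba_fraction: float = 0.01,
) -> List[PerturbationResult]:
    """Random reaction-removal robustness experiment.

    For each removal level and replicate, the perturbed network is scored
    against the intact one:

    * FBA quantitative accuracy = 1 − |flux₀ − flux| / flux₀ (floored at 0),
      on the minimal medium and on the complete medium;
    * PM quantitative accuracy = 1 − Σ_i |PM_i⁰ − PM_i| / Σ_i PM_i⁰
      (floored at 0) over the biomass components;
    * biomass booleans: perturbed FBA flux > ``fba_fraction``·flux₀, and all
      components' PM above the low/high thresholds.

    Components whose intact-network PM is 0 are excluded from the PM
    scores (they carry no signal about degradation).
    """
    pm_params = pm_params or PMParams()
    if rng is None:
        rng = np.random.default_rng(pm_params.seed)
    base_seed = pm_params.seed if pm_params.seed is not None else 0
    protected = set(protected) | {objective_reaction}
    protected |= {r.id for r in net.reactions if is_maintenance_reaction(r)}

    flux0_min = fba_biomass(net, minimal_medium, objective_reaction)
    flux0_com = fba_biomass(net, "complete", objective_reaction)
    if flux0_min <= 0 or flux0_com <= 0:
        raise ValueError("original network cannot produce biomass; check the medium")
    pm0 = _pm_vector(net, biomass_components, pm_params, base_seed)
    keep = pm0 > 0
    if not keep.all():
        dropped = [c for c, k in zip(biomass_components, keep) if not k]
        logger.info("excluding components with PM 0 in the intact network: %s", dropped)
    components = [c for c, k in zip(biomass_components, keep) if k]
    pm0 = pm0[keep]
    pm0_sum = float(pm0.sum())
    if pm0_sum <= 0:
        raise ValueError("no biomass component has positive PM in the intact network")

    results: List[PerturbationResult] = []
    for level in levels:
        for rep in range(reps):
            pert = remove_random_reactions(net, level, protected, rng)
            f_min = fba_biomass(pert, minimal_medium, objective_reaction)
            f_com = fba_biomass(pert, "complete", objective_reaction)
            pm = _pm_vector(pert, components, pm_params, base_seed)
            acc_min = max(0.0, 1.0 - abs(flux0_min - f_min) / flux0_min)
            acc_com = max(0.0, 1.0 - abs(flux0_com - f_com) / flux0_com)
            acc_pm = max(0.0, 1.0 - float(np.sum(np.abs(pm0 - pm))) / pm0_sum)
            results.append(
                PerturbationResult(
                    level=level,
                    replicate=rep,
                    fba_accuracy_minimal=acc_min,
                    fba_accuracy_complete=acc_com,
                    pm_accuracy=acc_pm,
                    fba_biomass_ok_minimal=f_min > fba_fraction * flux0_min,
                    fba_biomass_ok_complete=f_com > fba_fraction * flux0_com,
                    pm_biomass_ok_low=bool(np.all(pm > pm_threshold_low)),
                    pm_biomass_ok_high=bool(np.all(pm > pm_threshold_high)),
                )
            )
    return results


def summarize_perturbation(results: Sequence[PerturbationResult]) -> pd.DataFrame:
    """Per-level means and standard errors of the accuracy measures."""
    df = pd.DataFrame([r.__dict__ for r in results])
    num = df.drop(columns=["replicate"]).astype(float)
    g = num.groupby("level")
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_se")
    return mean.join(sem)
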