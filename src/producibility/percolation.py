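"""Producibility-metric estimation by environment sampling and curve fitting.

The producibility metric (PM) of a target metabolite quantifies how robustly
a network synthesizes it under uncertain environments.  Candidate input
metabolites are drawn independently with Bernoulli probability ``P_in``; the
probability ``P_out`` that the target is producible from a random draw,
viewed as a function of ``P_in``, is the producibility curve.  The curve is
monotone (feasibility is monotone in the input set), rising from
``P_out(0) = 0`` to ``P_out(1) = 1`` whenever the target is producible from
the full candidate pool but not from nothing.  The PM is defined from the
half-crossing of that curve:

    PM = 1 − P_in,0.5      where  P_out(P_in,0.5) = 0.5

so targets that remain producible under sparse environments score high.

The estimator samples the curve adaptively: starting at ``P_in = 0.5``, it
fits a two-parameter sigmoid to the sampled points, reads off the fitted
half-crossing, and samples the next point near it (uniform jitter of
half-width ``noise``), converging when the last ``n_conv`` estimates agree
within ``thresh``.  Two exact boundary points, (0, 0) and (1, 1) — known
from the boundary feasibility checks performed first — anchor the fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .feasibility import FeasibilityQuery, FeasibilitySolver, PRODUCIBILITY_THRESHOLD
from .model_io import PreparedModel

logger = logging.getLogger(__name__)

TargetSpec = Union[str, Iterable[str]]


def _as_target_set(target: TargetSpec) -> FrozenSet[str]:
    return frozenset([target] if isinstance(target, str) else target)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Bernoulli input-environment specification.

    ``p_in`` is a scalar probability or a per-metabolite map; ``fixed_on``
    metabolites are always present (P_in = 1), ``fixed_off`` never, and
    ``candidates`` is the pool subject to random draws.
    """

    candidates: FrozenSet[str]
    p_in: Union[float, Mapping[str, float]] = 0.5
    fixed_on: FrozenSet[str] = frozenset()
    fixed_off: FrozenSet[str] = frozenset()

    def __post_init__(self):
        if self.fixed_on & self.fixed_off:
            raise ValueError("fixed_on and fixed_off overlap")
        probs = (
            self.p_in.values() if isinstance(self.p_in, Mapping) else [self.p_in]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("input probabilities must lie in [0, 1]")

    def prob_of(self, met: str) -> float:
        if isinstance(self.p_in, Mapping):
            return float(self.p_in.get(met, 0.0))
        return float(self.p_in)


def default_environment(
    prep: PreparedModel,
    targets: TargetSpec,
    p_in: Union[float, Mapping[str, float]] = 0.5,
    fixed_on: Iterable[str] = (),
    fixed_off: Iterable[str] = (),
) -> EnvironmentSpec:
    """Standard candidate pool: all intracellular metabolites except targets.

    Targets are removed both from the candidate pool and from ``fixed_on``
    (a target is never handed to itself as an input).
    """
    tset = _as_target_set(targets)
    fon = frozenset(fixed_on) - tset
    foff = frozenset(fixed_off)
    cands = frozenset(prep.intracellular) - tset - fon - foff
    return EnvironmentSpec(candidates=cands, p_in=p_in, fixed_on=fon, fixed_off=foff)


@dataclass(frozen=True)
class ProducibilityCurvePoint:
    p_in: float
    p_out: float
    n_samples: int
    n_feasible: int


@dataclass(frozen=True)
class PMParams:
    """Tuning knobs of the sampling estimator (defaults used throughout)."""

    samp: int = 50          # environment samples per curve point
    noise: float = 0.3      # half-width of the next-point jitter
    n_conv: int = 7         # consecutive estimates checked for convergence
    thresh: float = 0.01    # convergence window on the PM scale
    runs: int = 10          # independent repeats averaged into the PM
    max_points: int = 100   # iteration cap per run
    seed: Optional[int] = None

    def __post_init__(self):
        if min(self.samp, self.n_conv, self.runs, self.max_points) <= 0:
            raise ValueError("samp, n_conv, runs and max_points must be positive")
        if not (0 < self.thresh < 1):
            raise ValueError("thresh must lie in (0, 1)")
        if self.noise < 0:
            raise ValueError("noise must be non-negative")


@dataclass
class PMEstimate:
    pm: float
    p_half: float
    run_values: List[float]
    converged: bool
    curve: List[ProducibilityCurvePoint] = field(default_factory=list)


def sample_inputs(
    env: EnvironmentSpec, rng: np.random.Generator, p_in: Optional[float] = None
) -> FrozenSet[str]:
    """One Bernoulli draw over the candidate pool (fixed_on always included)."""
    cands = sorted(env.candidates - env.fixed_on - env.fixed_off)
    if p_in is not None:
        probs = np.full(len(cands), float(p_in))
    else:
        probs = np.array([env.prob_of(c) for c in cands])
    u = rng.random(len(cands))
    drawn = {c for c, ui, pi in zip(cands, u, probs) if ui < pi}
    return frozenset(drawn) | env.fixed_on


def estimate_pout(
    prep: PreparedModel,
    target: TargetSpec,
    env: EnvironmentSpec,
    p_in: float,
    samp: int,
    rng: np.random.Generator,
    solver: Optional[FeasibilitySolver] = None,
    balance: str = "inequality",
    threshold: float = PRODUCIBILITY_THRESHOLD,
) -> ProducibilityCurvePoint:
    """Estimate one producibility-curve point: fraction of feasible samples."""
    tset = _as_target_set(target)
    if tset & env.candidates:
        raise ValueError("targets must be excluded from the candidate pool")
    if solver is None:
        solver = FeasibilitySolver(prep)
    n_feasible = 0
    for _ in range(samp):
        inputs = sample_inputs(env, rng, p_in=p_in)
        q = FeasibilityQuery(inputs, tset, balance=balance, threshold=threshold)
        if solver.feasible(q):
            n_feasible += 1
    return ProducibilityCurvePoint(float(p_in), n_feasible / samp, samp, n_feasible)


def _sigmoid(p: np.ndarray, log_a: float, log_b: float) -> np.ndarray:
    """Kumaraswamy-CDF sigmoid: P_out = 1 − (1 − p^a)^b on [0, 1].

    The family runs from 0 to 1, is monotone, and contains both pure
    disjunctive curves 1 − (1−p)^n (a = 1) and pure conjunctive curves
    p^k (b = 1), so producibility curves of AND/OR precursor structures
    are fit without the midpoint bias a symmetric sigmoid would impose.
    """
    a, b = np.exp(log_a), np.exp(log_b)
    return 1.0 - np.power(1.0 - np.power(p, a), b)


def _sigmoid_half_crossing(log_a: float, log_b: float) -> float:
    a, b = np.exp(log_a), np.exp(log_b)
    return float((1.0 - 0.5 ** (1.0 / b)) ** (1.0 / a))


_LOG_PARAM_RANGE = (np.log(1e-2), np.log(1e2))


def _fit_half_crossing(points: Sequence[ProducibilityCurvePoint], m0: float) -> float:
    """Least-squares sigmoid fit; returns the half-crossing clamped to [0,1]."""
    p = np.array([pt.p_in for pt in points])
    y = np.array([pt.p_out for pt in points])

    def resid(theta):
        return _sigmoid(p, theta[0], theta[1]) - y

    best = None
    for x0 in ((0.0, 0.0), (np.log(2.0), 0.0), (0.0, np.log(2.0))):
        try:
            sol = least_squares(
                resid,
                x0=x0,
                bounds=(
                    (_LOG_PARAM_RANGE[0],) * 2,
                    (_LOG_PARAM_RANGE[1],) * 2,
                ),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
            )
        except Exception:  # pragma: no cover - fit pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:  # pragma: no cover
        return float(np.clip(m0, 0.0, 1.0))
    return float(np.clip(_sigmoid_half_crossing(*best.x), 0.0, 1.0))


def calc_pm(
    prep: PreparedModel,
    target: TargetSpec,
    env: Optional[EnvironmentSpec] = None,
    params: Optional[PMParams] = None,
    rng: Optional[np.random.Generator] = None,
    solver: Optional[FeasibilitySolver] = None,
    balance: str = "inequality",
) -> PMEstimate:
    """Estimate the producibility metric of a target (or joint target set).

    Boundary shortcuts run first: a target unproducible even from the full
    candidate pool has PM = 0; a target producible from the fixed-on inputs
    alone (an empty random draw) has PM = 1.  Otherwise the adaptive
    sampling/fitting loop runs ``params.runs`` times and the PM is the mean
    of the per-run estimates.
    """
    params = params or PMParams()
    tset = _as_target_set(target)
    if env is None:
        env = default_environment(prep, tset)
    else:
        # a target never serves as its own input
        env = EnvironmentSpec(
            candidates=env.candidates - tset,
            p_in=env.p_in,
            fixed_on=env.fixed_on - tset,
            fixed_off=env.fixed_off,
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    if solver is None:
        solver = FeasibilitySolver(prep)

    full = env.candidates | env.fixed_on
    q_full = FeasibilityQuery(full, tset, balance=balance)
    if not solver.feasible(q_full):
        return PMEstimate(
            pm=0.0,
            p_half=1.0,
            run_values=[0.0] * params.runs,
            converged=True,
            curve=[ProducibilityCurvePoint(1.0, 0.0, 1, 0)],
        )
    q_empty = FeasibilityQuery(env.fixed_on, tset, balance=balance)
    if solver.feasible(q_empty):
        return PMEstimate(
            pm=1.0,
            p_half=0.0,
            run_values=[1.0] * params.runs,
            converged=True,
            curve=[ProducibilityCurvePoint(0.0, 1.0, 1, 1)],
        )

    anchors = [
        ProducibilityCurvePoint(0.0, 0.0, params.samp, 0),
        ProducibilityCurvePoint(1.0, 1.0, params.samp, params.samp),
    ]
    run_values: List[float] = []
    all_points: List[ProducibilityCurvePoint] = list(anchors)
    all_converged = True
    for _ in range(params.runs):
        points = list(anchors)
        p_next = 0.5
        estimates: List[float] = []
        converged = False
        for _ in range(params.max_points):
            pt = estimate_pout(
                prep, tset, env, p_next, params.samp, rng, solver=solver,
                balance=balance,
            )
            points.append(pt)
            all_points.append(pt)
            p_hat = _fit_half_crossing(points, m0=1.0 - estimates[-1] if estimates else 0.5)
            estimates.append(1.0 - p_hat)
            window = estimates[-params.n_conv:]
            if len(window) == params.n_conv and max(window) - min(window) <= params.thresh:
                converged = True
                break
            p_next = float(np.clip(p_hat + rng.uniform(-params.noise, params.noise), 0.0, 1.0))
        if not converged:
            logger.warning(
                "PM run did not converge after %d points (target %s)",
                params.max_points, sorted(tset),
            )
            all_converged = False
        run_values.append(estimates[-1])

    pm = float(np.mean(run_values))
    return PMEstimate(
        pm=pm,
        p_half=1.0 - pm,
        run_values=run_values,
        converged=all_converged,
        curve=all_points,
    )


def pm_matrix(
    models: Mapping[str, PreparedModel],
    targets: Sequence[str],
    params: Optional[PMParams] = None,
    env_of: Optional[Mapping[str, EnvironmentSpec]] = None,
    balance: str = "inequality",
):
    """PM values for every (organism, metabolite) pair as a DataFrame.

    Jobs are independent; each derives its own RNG stream from the master
    seed and its (organism, target) index, so serial and parallel execution
    agree and the same seed reproduces the matrix exactly.  Per-job failures
    are recorded as missing values.
    """
    import pandas as pd

    params = params or PMParams()
    master = params.seed if params.seed is not None else 0
    orgs = list(models)
    values = np.full((len(orgs), len(targets)), np.nan)
    for i, org in enumerate(orgs):
        prep = models[org]
        solver = FeasibilitySolver(prep)
        for j, tgt in enumerate(targets):
            job = i * len(targets) + j
            rng = np.random.default_rng(np.random.SeedSequence([master, job]))
            try:
                env = None if env_of is None else env_of.get(org)
                est = calc_pm(
                    prep, tgt, env=env, params=params, rng=rng, solver=solver,
                    balance=balance,
                )
                values[i, j] = est.pm
            except KeyError as exc:
                logger.warning("PM job failed for (%s, %s): %s", org, tgt, exc)
    return pd.DataFrame(values, index=orgs, columns=list(targets))


def enriched_delta(
    prep: PreparedModel,
    targets: Sequence[str],
    fixed_on: Iterable[str],
    params: Optional[PMParams] = None,
    balance: str = "inequality",
) -> Dict[str, float]:
    """ΔPM per target between an enriched environment and the baseline.

    The enriched environment fixes ``fixed_on`` metabolites to always be
    present (P_in = 1); a target is dropped from the fixed-on set for its
    own computation.  ΔPM = PM(enriched) − PM(baseline).
    """
    params = params or PMParams()
    fixed_on = frozenset(fixed_on)
    solver = FeasibilitySolver(prep)
    master = params.seed if params.seed is not None else 0
    out: Dict[str, float] = {}
    for j, tgt in enumerate(targets):
        rng = np.random.default_rng(np.random.SeedSequence([master, 2 * j]))
        base = calc_pm(prep, tgt, params=params, rng=rng, solver=solver, balance=balance)
        env = default_environment(prep, tgt, fixed_on=fixed_on - {tgt})
        rng = np.random.default_rng(np.random.SeedSequence([master, 2 * j + 1]))
        enriched = calc_pm(
            prep, tgt, env=env, params=params, rng=rng, solver=solver, balance=balance
        )
        out[tgt] = enriched.pm - base.pm
    return out
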