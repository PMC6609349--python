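"""Sampling estimator: environment draws, curve points and PM estimation."""

import numpy as np
import pytest
from scipy.stats import binom

from producibility import (
    EnvironmentSpec,
    FeasibilitySolver,
    MetabolicNetwork,
    Metabolite,
    PMParams,
    Reaction,
    calc_pm,
    default_environment,
    enriched_delta,
    estimate_pout,
    pm_matrix,
    prepare_model,
    sample_inputs,
)
from producibility import synthetic

FAST = PMParams(runs=3, seed=0)


class TestSampleInputs:
    def test_p_one_returns_everything(self, rng):
        env = EnvironmentSpec(candidates=frozenset("abcde"), p_in=1.0)
        assert sample_inputs(env, rng) == frozenset("abcde")

    def test_p_zero_returns_only_fixed_on(self, rng):
        env = EnvironmentSpec(
            candidates=frozenset("abcde"), p_in=0.0, fixed_on=frozenset("z")
        )
        assert sample_inputs(env, rng) == frozenset("z")

    def test_fixed_off_never_drawn(self, rng):
        env = EnvironmentSpec(
            candidates=frozenset("abcde"), p_in=1.0, fixed_off=frozenset("c")
        )
        assert "c" not in sample_inputs(env, rng)

    def test_mean_size_matches_binomial(self, rng):
        env = EnvironmentSpec(candidates=frozenset(f"m{i}" for i in range(10)), p_in=0.5)
        sizes = [len(sample_inputs(env, rng)) for _ in range(10_000)]
        # 3 sigma bound on the mean of 10k Binomial(10, 0.5) draws
        sigma = np.sqrt(10 * 0.25 / 10_000)
        assert abs(np.mean(sizes) - 5.0) < 3 * sigma

    def test_per_metabolite_probabilities(self, rng):
        env = EnvironmentSpec(
            candidates=frozenset({"always", "never"}),
            p_in={"always": 1.0, "never": 0.0},
        )
        for _ in range(20):
            assert sample_inputs(env, rng) == frozenset({"always"})

    def test_overlapping_fixed_sets_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentSpec(candidates=frozenset(), fixed_on=frozenset("a"),
                            fixed_off=frozenset("a"))


class TestEstimatePout:
    def test_single_precursor_p1(self, chain3_prep, chain3_solver, rng):
        env = default_environment(chain3_prep, "T", p_in=1.0)
        pt = estimate_pout(chain3_prep, "T", env, 1.0, 20, rng, solver=chain3_solver)
        assert pt.p_out == 1.0

    def test_unproducible_target_always_zero(self, rng):
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("T")], [Reaction("R", {"T": -1.0, "A": 1.0})]
        )
        prep = prepare_model(net)
        env = default_environment(prep, "T")
        for p in (0.2, 0.9):
            pt = estimate_pout(prep, "T", env, p, 20, rng)
            assert pt.p_out == 0.0

    def test_binomial_interval_single_precursor(self, rng):
        prep = prepare_model(synthetic.make_chain(1))
        env = default_environment(prep, "T")
        pt = estimate_pout(prep, "T", env, 0.5, 50, rng)
        lo, hi = binom.ppf([0.005, 0.995], 50, 0.5)
        assert lo <= pt.n_feasible <= hi

    def test_ratio_invariant(self, chain3_prep, chain3_solver, rng):
        env = default_environment(chain3_prep, "T")
        pt = estimate_pout(chain3_prep, "T", env, 0.4, 33, rng, solver=chain3_solver)
        assert pt.p_out == pt.n_feasible / pt.n_samples


class TestCalcPM:
    def test_boundary_unproducible_is_zero(self):
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("T")], [Reaction("R", {"T": -1.0, "A": 1.0})]
        )
        est = calc_pm(prepare_model(net), "T", params=FAST)
        assert est.pm == 0.0 and est.converged

    def test_boundary_fixed_on_is_one(self, chain3_prep):
        env = default_environment(chain3_prep, "T", fixed_on={"M3"})
        est = calc_pm(chain3_prep, "T", env=env, params=FAST)
        assert est.pm == 1.0

    def test_single_precursor_near_half(self):
        prep = prepare_model(synthetic.make_chain(1))
        est = calc_pm(prep, "T", params=PMParams(seed=0))
        assert abs(est.pm - 0.5) < 0.03

    def test_two_alternative_precursors(self):
        prep = prepare_model(synthetic.make_fan_in(2))
        est = calc_pm(prep, "T", params=PMParams(seed=0))
        assert abs(est.pm - 2 ** -0.5) < 0.03

    def test_pm_within_unit_interval_and_runs_recorded(self, chain3_prep):
        est = calc_pm(chain3_prep, "T", params=FAST)
        assert 0.0 <= est.pm <= 1.0
        assert len(est.run_values) == FAST.runs
        assert est.pm == pytest.approx(np.mean(est.run_values))

    def test_deterministic_under_seed(self, chain3_prep):
        a = calc_pm(chain3_prep, "T", params=PMParams(runs=2, seed=7))
        b = calc_pm(chain3_prep, "T", params=PMParams(runs=2, seed=7))
        assert a.pm == b.pm and a.run_values == b.run_values

    def test_run_dispersion_shrinks_with_samples(self):
        prep = prepare_model(synthetic.make_chain(1))
        solver = FeasibilitySolver(prep)
        sds = []
        for samp in (10, 200):
            est = calc_pm(prep, "T", params=PMParams(samp=samp, runs=6, seed=1),
                          solver=solver)
            sds.append(np.std(est.run_values))
        assert sds[1] < sds[0]


class TestPMMatrix:
    def test_shape_and_determinism(self, chain3_prep):
        models = {"o1": chain3_prep, "o2": chain3_prep}
        targets = ["T", "M3", "M2"]
        params = PMParams(runs=2, seed=9)
        a = pm_matrix(models, targets, params=params)
        b = pm_matrix(models, targets, params=params)
        assert a.shape == (2, 3)
        assert a.equals(b)

    def test_rows_independent_of_other_models(self, chain3_prep):
        params = PMParams(runs=2, seed=9)
        solo = pm_matrix({"o1": chain3_prep}, ["T"], params=params)
        both = pm_matrix({"o1": chain3_prep, "o2": chain3_prep}, ["T"], params=params)
        assert solo.loc["o1", "T"] == both.loc["o1", "T"]


class TestEnrichedDelta:
    def test_sole_precursor_fixed_on(self):
        # fixing the unique precursor makes the target producible with no
        # random inputs: enriched PM = 1, baseline PM ~ 0.5
        prep = prepare_model(synthetic.make_chain(1))
        delta = enriched_delta(prep, ["T"], fixed_on={"M1"},
                               params=PMParams(runs=3, seed=2))
        assert delta["T"] == pytest.approx(0.5, abs=0.03)

    def test_unreachable_fixed_on_no_effect(self):
        # the fixed metabolite Z feeds nothing upstream of T
        net = MetabolicNetwork(
            [Metabolite("M1"), Metabolite("T"), Metabolite("Z")],
            [Reaction("R1", {"M1": -1.0, "T": 1.0})],
        )
        prep = prepare_model(net)
        delta = enriched_delta(prep, ["T"], fixed_on={"Z"},
                               params=PMParams(runs=3, seed=2))
        assert abs(delta["T"]) < 0.05

    def test_target_dropped_from_its_own_fixed_on(self, chain3_prep):
        delta = enriched_delta(chain3_prep, ["T"], fixed_on={"T"},
                               params=PMParams(runs=2, seed=2))
        assert abs(delta["T"]) < 0.05  # fixing only the target itself is a no-op
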