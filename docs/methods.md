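# Methods

## Model and definitions

A metabolic network is a stoichiometric matrix *S* (metabolites × reactions)
with flux bounds *lb* ≤ *v* ≤ *ub*. Before analysis, `prepare_model`
standardizes a network: native boundary reactions (single-metabolite
stoichiometry, or ids prefixed `EX_`/`DM_`/`SK_`) and maintenance reactions
(id `ATPM`, or "maintenance" in the id/name, case-insensitive) are switched
off by zeroing bounds, and every metabolite receives one import exchange
(∅ → met) and one export exchange (met → ∅), both initially closed. All
environment manipulation afterwards happens purely through the bounds of
these exchanges.

**Feasibility.** A target is *producible* from an input set when the LP
maximize *c*ᵀ*v* s.t. *S v* = 0, *lb* ≤ *v* ≤ *ub* — with the inputs'
import exchanges opened to [0, 1000] and the target's export as objective —
attains an optimum above the threshold 0.001. Under the default *inequality
mass balance*, every export exchange is open ([0, 1000]), so any metabolite
may accumulate and be drained; this relaxation (*S v* ≥ 0 in effect) is
deliberate: producibility is a local property and should not be blocked by a
global steady-state requirement. Under *equality* balance only the targets'
exports open. For a target *set*, each member's export receives a lower
bound equal to the threshold and the LP is tested for feasibility — joint
production, so one abundant member cannot mask an unproducible one (a summed
objective would). The exchange cap of 1000 is arbitrary: feasibility is
scale-free above the threshold.

Feasibility is monotone in the input set (opening imports only enlarges the
feasible polytope): the foundation for both the estimator and the exact
theory below.

**Producibility metric.** Candidate inputs (by default all intracellular
metabolites except the target; targets are never their own inputs) are drawn
independently with probability *P*<sub>in</sub>; *P*<sub>out</sub> is the
probability the target is producible. PM = 1 − *P*<sub>in,0.5</sub> with
*P*<sub>out</sub>(*P*<sub>in,0.5</sub>) = 0.5. Fixed-on metabolites
(*P*<sub>in</sub> = 1) and fixed-off metabolites (*P*<sub>in</sub> = 0)
model enriched or restricted environments; per-metabolite probability maps
are supported.

## The sampling estimator

`calc_pm` first runs two boundary checks. If the target is not producible
even from the full candidate pool, the curve is identically 0 and PM = 0; if
it is producible from the fixed-on inputs alone, the curve starts at 1 and
PM = 1. These shortcuts avoid fitting curves that have no half-crossing.

Otherwise, per run: sample *P*<sub>out</sub> at *P*<sub>in</sub> = 0.5
(`samp` = 50 Bernoulli environment draws, each decided by one LP); fit a
sigmoid to all sampled points; read off the fitted half-crossing *p̂*; place
the next sample point at *p̂* plus uniform jitter of half-width `noise` = 0.3
(clamped to [0, 1]); repeat. The run converges when the last `n_conv` = 7
estimates of 1 − *p̂* span at most `thresh` = 0.01; the run's PM is the last
estimate, and the reported PM is the mean over `runs` = 10 independent runs
(per-run values are retained for dispersion). A run hitting the iteration
cap (`max_points` = 100) is reported with `converged=False` and a logged
warning rather than an exception.

**Sigmoid choice.** The fitted curve is the Kumaraswamy CDF
*P*<sub>out</sub> = 1 − (1 − *p*<sup>a</sup>)<sup>b</sup>, least-squares in
(log *a*, log *b*). This family was chosen over a logistic because it runs
exactly from 0 to 1 and contains both pure disjunctive curves
1 − (1−*p*)<sup>n</sup> (*a* = 1) and pure conjunctive curves *p*<sup>k</sup>
(*b* = 1) — the two extremes generated by OR- and AND-structured precursor
sets. A symmetric logistic fit to these asymmetric curves biases the
half-crossing toward 0.5 by up to ~0.03, which we measured directly on chain
and fan-in fixtures; with the Kumaraswamy form the worst fixture error drops
below 0.01. The half-crossing is analytic:
*p̂* = (1 − 0.5<sup>1/b</sup>)<sup>1/a</sup>.

**Anchors.** The two exact boundary points (0, 0) and (1, 1) — guaranteed by
the boundary checks above — are added to every fit. They stabilize the first
iterations, when only one or two noisy points exist, without distorting the
fit later (the family passes through both endpoints anyway).

**Randomness and determinism.** All draws flow from one
`numpy.random.Generator`. Matrix-scale computations (`pm_matrix`,
`enriched_delta`) derive an independent stream per (organism, target) job
from the master seed and the job index via `SeedSequence`, so serial and
parallel execution produce identical results and per-job failures stay
isolated (recorded as missing values).

**Caching.** A `FeasibilitySolver` memoizes feasibility per (inputs,
targets, balance). On small candidate pools the same input sets recur across
samples and runs, reducing thousands of LP calls to dictionary lookups. The
LP itself is built once per model in GLPK and mutated in place; the simplex
warm-starts from the previous basis (~0.5 ms per solve on a 300-reaction
network). Solver tolerances are 1e-9 (primal/dual), far below the 0.001
producibility threshold; a numerically failed solve is retried once from a
fresh basis with 1e-11 tolerances before raising.

## Exact theory on small networks

Because feasibility is monotone, the feasible subsets of an *m*-candidate
pool form an upward-closed family determined by its antichain of minimal
members — the minimal precursor sets. `enumerate_structure` visits subsets
in increasing size, spending an LP only on subsets not containing a known
minimal set, and counts c<sub>k</sub> (feasible subsets of size *k*) by a
bitmask sweep. Then

  *P*<sub>out</sub>(*p*) = Σ<sub>k</sub> c<sub>k</sub> *p*<sup>k</sup> (1−*p*)<sup>m−k</sup>,

evaluated exactly; `analytic_pm` brackets the unique root of
*P*<sub>out</sub> = 0.5 (Brent, xtol 1e-10). Conventions: no minimal set →
PM = 0; empty set feasible → PM = 1. An independent inclusion–exclusion
evaluation over the minimal sets cross-checks the polynomial to 1e-12 in the
tests. Enumeration is capped at 20 candidates (2²⁰ subsets with pruning);
beyond the cap an explicit error points to the sampling estimator. For a
linear chain of *n* single-metabolite precursors the root is closed-form:
PM = 0.5<sup>1/n</sup>; for a *k*-substrate conjunctive reaction,
PM = 1 − 0.5<sup>1/k</sup>.

`pathway_scores` complements the PM with the two classical pathway
completeness scores for an ordered linear pathway: the number of listed
reactions present (`pathway_sum`) and the unbroken present-prefix length
from the target end (`pathway_length`). A single-reaction knockout always
scores *n* − 1 on `pathway_sum` regardless of position, whereas the PM falls
more the closer the cut is to the target — the contrast the metric exists to
expose.

## Pairwise metrics and statistics

PM distance is the L1 norm between two organisms' PM vectors; PM
complementarity (A→B) is Σ(max[PM<sub>i</sub><sup>A</sup>,
PM<sub>i</sub><sup>B</sup>] − PM<sub>i</sub><sup>B</sup>) / Σ
PM<sub>i</sub><sup>A</sup>, in [0, 1], undefined when A's vector sums to 0.
Missing PM entries are dropped pairwise.

Seed sets follow the NetSeed construction: a directed metabolite graph with
an edge reactant → product for every reactant/product pair (both directions
when the reaction's bounds allow reversal), condensed into strongly
connected components; members of in-degree-0 components are seeds with score
1/|component|. All components count (minComponentSize = 0, no giant-component
restriction), so an isolated metabolite is its own seed. Seed distance is L1
on score vectors over a shared universe; seed competition (A→B) is the
fraction of A's seeds that are seeds of B; seed complementarity (A→B) the
fraction of A's seeds that are interior metabolites of B.

Genus collapsing averages a pairwise matrix over organism pairs, excluding
self-pairs within a genus (including the zero diagonal would bias
within-genus distances downward); symmetric distance matrices keep a zero
diagonal by convention, and a singleton genus has no valid within-genus pair
for directional metrics (missing).

The Mantel test correlates the off-diagonal cells of two aligned square
matrices (Spearman with average ranks for ties, or Pearson) and permutes the
organism labels of the first matrix — rows and columns together — counting
permutations with larger |ρ|; p = (n_stronger + 1)/(N + 1), so p is never
below 1/(N+1). The partial variant controls for a third matrix through the
first-order partial-correlation formula and permutes only the first matrix.
For directional metric matrices both triangles are used by default; an
`upper` triangle mode exists for symmetric growth-style matrices. A constant
off-diagonal or a |ρ<sub>yz</sub>| = 1 control raises a
`DegenerateMatrixError` rather than returning a number.

## Experiments

`knockout_genes` zeroes the bounds of every reaction associated with the
knocked-out genes (isoenzyme-shared reactions included); stoichiometry and
reaction count never change. `remove_random_reactions` deletes a uniform
sample of non-protected reactions outright, mirroring the generation of
independent gapped networks.

`perturbation_study` scores perturbed networks against the intact one: FBA
accuracy 1 − |flux₀ − flux|/flux₀ and PM accuracy 1 − Σ|ΔPM|/ΣPM₀, both
floored at 0 (the normalized L1 can exceed 1 when the perturbed sum exceeds
the original; we normalize by the intact network's magnitude and clamp).
Biomass-production booleans use a 1% flux fraction for FBA and PM thresholds
of 0.1 and 0.6. Components whose intact-network PM is 0 are excluded (they
carry no degradation signal). All PM vectors — intact and perturbed — use
per-component RNG streams derived from the same base seed (common random
numbers), so a level-0 control scores exactly 1 and sampling noise partially
cancels in differences. "Complete medium" opens every native exchange for
uptake; the minimal medium is an explicit metabolite set supplied by the
caller.

## Synthetic data

The generators produce the motifs the method must get right, all with 1:1
stoichiometry so nothing is producible from nothing and PM = 1 arises only
via fixed-on inputs:

* `make_chain(n)` / `make_fan_in(k)` — OR-structure; exact PM
  0.5<sup>1/n</sup> and 0.5<sup>1/k</sup>.
* `make_conjunctive(k)` — AND-structure; exact PM 1 − 0.5<sup>1/k</sup>.
* `make_cofactor_loop(n_recycle)` — A + NADH → T + NAD with `n_recycle`
  recycling reactions X<sub>i</sub> + NAD → Y<sub>i</sub> + NADH. The LP
  treats the cofactor cycle as internal flux, so {A, X<sub>i</sub>} is a
  minimal precursor set for every route; with the default 4 routes (11
  candidates, comfortably enumerable) PM(T) ≈ 0.486, within 0.03 of the
  cofactor-free chain's 0.5, while severing the loop drops PM(T) to
  1 − √0.5 ≈ 0.293. This reproduces the key qualitative property that
  recycled cofactors barely influence a target's PM.
* `make_random(M, R, …)` — random 1:1 networks with the target reachable by
  construction and an optional cap on the active candidate pool so
  enumeration stays tractable (≤ 12 in the tests).
* `make_perturbation_network(…)` — ~300 reactions: 8 nutrients behind native
  exchanges (the first one a backbone nutrient feeding every early
  metabolite, so the single-nutrient minimal medium supports growth), a
  layered random core with ~3 alternative producing reactions per
  metabolite, 20 biomass components with 2–3 routes each, a biomass
  reaction, and a protected maintenance reaction.

What the generators deliberately do **not** emulate: realistic stoichiometric
coefficients (no 2:1 couplings), compartmentalization and transport,
thermodynamic direction constraints, or genome-scale redundancy patterns.
Passing tests therefore demonstrate correctness of the machinery and the
combinatorial theory on controlled structures — not calibration against any
particular organism's network. Runs on curated genome-scale models (e.g.
BiGG's *E. coli* core model) are supported through the SBML/JSON readers and
exercised by an optional test that activates when such a model file is
placed under `external_models/`.

## Problem sizes and defaults

Estimator defaults: samp = 50, noise = 0.3, n_conv = 7, thresh = 0.01,
runs = 10, max_points = 100 — the standard operating point used throughout;
the tests of the analytic–sampling agreement run at exactly these defaults.
The perturbation experiment in the test suite uses a 300-reaction network,
20 biomass components, removal levels {4, 16, 30} (≈1–10% of reactions) with
20 replicates, and a reduced estimator setting (samp = 8, runs = 1,
n_conv = 4): the experiment compares *accuracy aggregates over many
networks*, where per-PM precision matters less than replicate count, and the
common-random-number scheme removes most sampling noise from the
differences. The Mantel calibration test uses 1000 simulated independent
matrix pairs at N = 999 permutations, which makes the [0.03, 0.07]
acceptance band on the type-I error a ~3σ statement (at 200 simulations the
binomial noise alone would fail a perfectly calibrated test in roughly one
run out of seven).

## Known limitations

* Inequality mass balance cannot distinguish biosynthetic from degradative
  producibility; direction annotations in the input model are trusted as-is.
* The sampling estimator's error concentrates near the half-crossing; curve
  regions far from it are sampled sparsely, so the reported curve points are
  not a uniform-accuracy reconstruction of the whole producibility curve.
* Enumeration is exponential in the candidate count and capped at 20.
* The Kumaraswamy family fits mixed AND/OR structures approximately, not
  exactly; residual estimator bias on such networks is bounded by the 0.03
  agreement tests but not by theory.
* Seed scores implement the plain 1/|component| normalization; confidence
  weightings from richer seed-detection variants are out of scope.
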