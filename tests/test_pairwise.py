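"""Pairwise organism metrics: PM vectors, seed sets, reaction vectors,
genus collapsing."""

import numpy as np
import pandas as pd
import pytest

from producibility import (
    MetabolicNetwork,
    Metabolite,
    Reaction,
    collapse_to_genus,
    pairwise_matrix,
    pm_complementarity,
    pm_distance,
    reaction_distance,
    reaction_jaccard,
    seed_competition,
    seed_complementarity,
    seed_distance,
    seed_set,
)


class TestPMMetrics:
    def test_distance_identity_and_example(self):
        assert pm_distance([1, 0, 0.5], [1, 0, 0.5]) == 0.0
        assert pm_distance([1, 0, 0.5], [0, 0, 0.5]) == 1.0

    def test_distance_symmetric(self, rng):
        a, b = rng.random(20), rng.random(20)
        assert pm_distance(a, b) == pm_distance(b, a)

    def test_complementarity_printed_formula(self):
        assert pm_complementarity([1, 1], [0, 1]) == pytest.approx(0.5)

    def test_complementarity_self_zero(self, rng):
        a = rng.random(10)
        assert pm_complementarity(a, a) == 0.0

    def test_complementarity_against_zeros_is_one(self, rng):
        a = rng.random(10) + 0.1
        assert pm_complementarity(a, np.zeros(10)) == pytest.approx(1.0)

    def test_complementarity_bounded_and_antitone_in_b(self, rng):
        a = rng.random(15)
        b = rng.random(15)
        v = pm_complementarity(a, b)
        assert 0.0 <= v <= 1.0
        b_higher = np.clip(b + 0.2, 0, 1)
        assert pm_complementarity(a, b_higher) <= v + 1e-12

    def test_zero_a_vector_missing(self):
        assert np.isnan(pm_complementarity([0, 0], [1, 1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pm_distance([1, 2], [1, 2, 3])

    def test_missing_entries_dropped_pairwise(self):
        a = [1.0, np.nan, 0.5]
        b = [0.0, 0.7, 0.5]
        assert pm_distance(a, b) == 1.0


def _chain_net():
    return MetabolicNetwork(
        [Metabolite("A"), Metabolite("B"), Metabolite("C")],
        [Reaction("R1", {"A": -1.0, "B": 1.0}), Reaction("R2", {"B": -1.0, "C": 1.0})],
    )


def _cycle_feeding_net():
    # A <-> B (2-cycle via reversible reaction), B -> C
    return MetabolicNetwork(
        [Metabolite("A"), Metabolite("B"), Metabolite("C")],
        [
            Reaction("R1", {"A": -1.0, "B": 1.0}, -1000.0, 1000.0),
            Reaction("R2", {"B": -1.0, "C": 1.0}),
        ],
    )


class TestSeedSets:
    def test_chain_single_source(self):
        s = seed_set(_chain_net())
        assert dict(s.seed_score) == {"A": 1.0}

    def test_two_cycle_shared_score(self):
        s = seed_set(_cycle_feeding_net())
        assert s.seed_score == {"A": 0.5, "B": 0.5}

    def test_isolated_metabolite_kept_with_score_one(self):
        net = MetabolicNetwork(
            [Metabolite("A"), Metabolite("B"), Metabolite("LONER")],
            [Reaction("R1", {"A": -1.0, "B": 1.0})],
        )
        s = seed_set(net)
        assert s.seed_score["LONER"] == 1.0

    def test_zero_indegree_always_seed(self, rng):
        from producibility import synthetic

        net = synthetic.make_random(10, 14, seed=3)
        s = seed_set(net)
        consumed_only = set(net.metabolite_ids)
        for r in net.reactions:
            for m, c in r.stoichiometry.items():
                if c > 0 or (c < 0 and r.reversible):
                    consumed_only.discard(m)
        for m in consumed_only:
            assert s.seed_score.get(m) == pytest.approx(1.0)

    def test_seed_distance_examples(self):
        a = seed_set(_chain_net(), "a")
        assert seed_distance(a, a) == 0.0
        # disjoint singleton seeds, both score 1 -> L1 distance 2
        n1 = MetabolicNetwork(
            [Metabolite("X"), Metabolite("Y")], [Reaction("R", {"X": -1.0, "Y": 1.0})]
        )
        n2 = MetabolicNetwork(
            [Metabolite("P"), Metabolite("Q")], [Reaction("R", {"P": -1.0, "Q": 1.0})]
        )
        assert seed_distance(seed_set(n1), seed_set(n2)) == 2.0

    def test_seed_competition_examples(self):
        a = seed_set(_chain_net(), "a")
        assert seed_competition(a, a) == 1.0
        other = seed_set(
            MetabolicNetwork(
                [Metabolite("Z"), Metabolite("W")],
                [Reaction("R", {"Z": -1.0, "W": 1.0})],
            )
        )
        assert seed_competition(a, other) == 0.0

    def test_seed_complementarity_interior_fraction(self):
        a = seed_set(_chain_net(), "a")  # seeds(a) = {A}
        # in b, A is interior (produced from P)
        b = seed_set(
            MetabolicNetwork(
                [Metabolite("P"), Metabolite("A")],
                [Reaction("R", {"P": -1.0, "A": 1.0})],
            )
        )
        assert seed_complementarity(a, b) == 1.0
        # in c, A is absent entirely
        c = seed_set(
            MetabolicNetwork(
                [Metabolite("Z"), Metabolite("W")],
                [Reaction("R", {"Z": -1.0, "W": 1.0})],
            )
        )
        assert seed_complementarity(a, c) == 0.0

    def test_no_seeds_missing(self):
        # strongly connected network: reversible cycle has no source comp...
        # a single reversible 2-cycle IS its own source component, so use
        # an empty seed set via the threshold route instead
        a = seed_set(_chain_net(), "a")
        b = type(a)("b", {}, frozenset({"A"}))
        assert np.isnan(seed_competition(b, a))


class TestReactionMetrics:
    def test_identical(self):
        u = ["r1", "r2", "r3"]
        assert reaction_distance({"r1", "r2"}, {"r1", "r2"}, u) == 0.0
        assert reaction_jaccard({"r1", "r2"}, {"r1", "r2"}, u) == 0.0

    def test_disjoint_sizes_two_three(self):
        u = [f"r{i}" for i in range(5)]
        a, b = {"r0", "r1"}, {"r2", "r3", "r4"}
        assert reaction_distance(a, b, u) == 5.0
        assert reaction_jaccard(a, b, u) == 1.0

    def test_nested_sets(self):
        u = ["r1", "r2"]
        assert reaction_distance({"r1"}, {"r1", "r2"}, u) == 1.0
        assert reaction_jaccard({"r1"}, {"r1", "r2"}, u) == 0.5

    def test_empty_union_missing(self):
        assert np.isnan(reaction_jaccard(set(), set(), ["r1"]))


class TestCollapseToGenus:
    def _matrix(self):
        orgs = ["a1", "a2", "b1", "b2"]
        m = pd.DataFrame(0.0, index=orgs, columns=orgs)
        for i in orgs:
            for j in orgs:
                if i != j:
                    m.loc[i, j] = 3.0
        return m

    def test_constant_off_diagonal_preserved(self):
        genus = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = collapse_to_genus(self._matrix(), genus, symmetric=True)
        assert out.loc["A", "B"] == 3.0
        assert out.loc["A", "A"] == 0.0  # distance diagonal convention

    def test_singleton_genus_unchanged_off_diagonal(self):
        m = self._matrix()
        genus = {o: o.upper() for o in m.index}  # all singletons
        out = collapse_to_genus(m, genus, symmetric=False)
        assert out.loc["A1", "B2"] == 3.0

    def test_singleton_within_genus_missing_for_directional(self):
        m = self._matrix()
        genus = {o: o.upper() for o in m.index}
        out = collapse_to_genus(m, genus, symmetric=False)
        assert np.isnan(out.loc["A1", "A1"])

    def test_within_genus_excludes_self_pairs(self):
        genus = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = collapse_to_genus(self._matrix(), genus, symmetric=False)
        assert out.loc["A", "A"] == 3.0  # the two i != j pairs, not the 0 diagonal

    def test_row_permutation_invariant(self):
        m = self._matrix()
        genus = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        perm = ["b2", "a1", "b1", "a2"]
        out1 = collapse_to_genus(m, genus, symmetric=True)
        out2 = collapse_to_genus(m.loc[perm, perm], genus, symmetric=True)
        assert out1.equals(out2)

    def test_unlabeled_organism_rejected(self):
        with pytest.raises(ValueError):
            collapse_to_genus(self._matrix(), {"a1": "A"})


class TestPairwiseMatrix:
    def test_symmetric_assembly(self, rng):
        vectors = {o: rng.random(5) for o in ["x", "y", "z"]}
        m = pairwise_matrix(vectors, pm_distance, symmetric=True)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0.0)

    def test_directional_assembly(self, rng):
        vectors = {"x": np.array([1.0, 1.0]), "y": np.array([0.0, 1.0])}
        m = pairwise_matrix(vectors, pm_complementarity)
        assert m.loc["x", "y"] == pytest.approx(0.5)
        assert m.loc["y", "x"] == pytest.approx(0.0)
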