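import itertools
import math
from collections import Counter

import numpy as np
import pytest

from oncovote.ddi import (DomainPairMatrix, RandomizationPlan,
                          domain_pairs_of_edge, edge_ddi_score,
                          interaction_matrix, null_mean_matrix,
                          randomize_annotations, ratio_matrix)
from oncovote.exceptions import (DomainlessProteinError, EmptySelectionError,
                                 ProvenanceError)
from oncovote.io_data import annotations_from_mapping, network_from_edges

from oracles import brute_edge_ddi, brute_interaction_matrix


def ann(mapping):
    return annotations_from_mapping(mapping)


class TestDomainPairs:
    @pytest.mark.parametrize("sa,sb,expected", [
        (["a"], ["b"], {("a", "b")}),
        (["a", "b"], ["a"], {("a", "a"), ("a", "b")}),
        (["a", "b"], ["c", "d"],
         {("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")}),
    ])
    def test_cartesian_unordered(self, sa, sb, expected):
        a = ann({"P1": sa, "P2": sb})
        assert domain_pairs_of_edge(a, ("P1", "P2")) == expected

    def test_domainless_endpoint_raises(self):
        a = ann({"P1": ["a"]})
        with pytest.raises(DomainlessProteinError):
            domain_pairs_of_edge(a, ("P1", "P2"))

    def test_self_loop_uses_own_square(self):
        a = ann({"P1": ["a", "b"]})
        assert domain_pairs_of_edge(a, ("P1", "P1")) == \
            {("a", "a"), ("a", "b"), ("b", "b")}


class TestInteractionMatrix:
    def test_single_edge_unit_mass(self):
        net = network_from_edges([("P1", "P2")], cancer=["P1", "P2"])
        m = interaction_matrix(net, ann({"P1": ["a"], "P2": ["b"]}))
        assert m[("a", "b")] == pytest.approx(1.0)

    def test_two_domain_split(self):
        net = network_from_edges([("P1", "P2")], cancer=["P1", "P2"])
        m = interaction_matrix(net, ann({"P1": ["a", "b"], "P2": ["c"]}))
        assert m[("a", "c")] == pytest.approx(0.5)
        assert m[("b", "c")] == pytest.approx(0.5)

    def test_accumulation_over_edges(self):
        # two edges sharing domain pairs; expected masses enumerated by hand
        net = network_from_edges([("P1", "P2"), ("P3", "P4")],
                                 cancer=["P1", "P2", "P3", "P4"])
        a = ann({"P1": ["a"], "P2": ["b"], "P3": ["a", "b"], "P4": ["a"]})
        m = interaction_matrix(net, a)
        assert m[("a", "b")] == pytest.approx(1.5)
        assert m[("a", "a")] == pytest.approx(0.5)

    def test_empty_selection(self):
        net = network_from_edges([("P1", "P2")])  # no cancer labels -> no CC
        with pytest.raises(EmptySelectionError):
            interaction_matrix(net, ann({"P1": ["a"], "P2": ["b"]}))

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(3, 10)
            proteins = [f"P{i}" for i in range(n)]
            domains = [f"d{i}" for i in range(rng.integers(2, 6))]
            mapping = {p: list(rng.choice(domains, size=rng.integers(1, 4)))
                       for p in proteins}
            edges = {tuple(sorted(rng.choice(proteins, size=2, replace=False)))
                     for _ in range(rng.integers(1, 8))}
            net = network_from_edges(edges, cancer=proteins)
            got = interaction_matrix(net, ann(mapping))
            want = brute_interaction_matrix(sorted(edges), mapping)
            assert set(got.mass) == set(want)
            for key, val in want.items():
                assert got.mass[key] == pytest.approx(val)

    def test_mass_conservation(self):
        rng = np.random.default_rng(7)
        proteins = [f"P{i}" for i in range(12)]
        mapping = {p: list(rng.choice(["a", "b", "c", "d", "e"],
                                      size=rng.integers(1, 5)))
                   for p in proteins}
        edges = {tuple(sorted(rng.choice(proteins, 2, replace=False)))
                 for _ in range(20)}
        net = network_from_edges(edges, cancer=proteins)
        m = interaction_matrix(net, ann(mapping))
        assert m.total_mass() == pytest.approx(m.n_edges, abs=1e-9)
        assert m.n_edges == len(net.edges)


class TestRandomizeAnnotations:
    def test_single_protein_identity(self):
        a = ann({"P1": ["a", "b"]})
        out = randomize_annotations(a, seed=1)
        assert out.assignments["P1"] == Counter(["a", "b"])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 17])
    def test_counts_and_global_multiset_preserved(self, seed):
        rng = np.random.default_rng(seed)
        mapping = {f"P{i}": list(rng.choice(["a", "b", "c", "d"],
                                            size=rng.integers(1, 5)))
                   for i in range(8)}
        a = ann(mapping)
        out = randomize_annotations(a, seed=seed)
        for p in mapping:
            assert out.n_instances(p) == a.n_instances(p)
        pooled = Counter()
        for c in out.assignments.values():
            pooled += c
        want = Counter()
        for c in a.assignments.values():
            want += c
        assert pooled == want

    def test_two_slot_permutation_is_fair(self):
        from scipy.stats import binomtest
        a = ann({"P1": ["a"], "P2": ["b"]})
        swaps = sum(randomize_annotations(a, seed=s).assignments["P1"]["b"]
                    for s in range(1000))
        assert binomtest(swaps, 1000, 0.5).pvalue > 0.01


class TestNullMean:
    def test_conservation_under_distinct_singletons(self):
        # one distinct domain per protein: every draw is a relabeling
        proteins = [f"P{i}" for i in range(6)]
        mapping = {p: [f"d{i}"] for i, p in enumerate(proteins)}
        net = network_from_edges([("P0", "P1"), ("P2", "P3"), ("P0", "P4")],
                                 cancer=proteins)
        null = null_mean_matrix(net, ann(mapping),
                                plan=RandomizationPlan(n_randomizations=5, seed=3))
        assert null.total_mass() == pytest.approx(3.0, abs=1e-9)

    def test_b1_equals_single_randomization(self):
        mapping = {"P1": ["a", "b"], "P2": ["c"], "P3": ["d"]}
        net = network_from_edges([("P1", "P2"), ("P1", "P3")],
                                 cancer=["P1", "P2", "P3"])
        plan = RandomizationPlan(n_randomizations=1, seed=11)
        null = null_mean_matrix(net, ann(mapping), plan=plan)
        seed = int(np.random.default_rng(11).integers(0, 2**31 - 1, size=1)[0])
        single = interaction_matrix(net, randomize_annotations(ann(mapping), seed))
        assert null.mass == pytest.approx(single.mass)

    def test_matches_exhaustive_permutation_expectation(self):
        # 4 assignment slots -> 24 equally likely permutations, averaged exactly
        mapping = {"P1": ["a", "b"], "P2": ["c"], "P3": ["d"]}
        net = network_from_edges([("P1", "P2"), ("P1", "P3")],
                                 cancer=["P1", "P2", "P3"])
        pool = ["a", "b", "c", "d"]
        exact: dict = {}
        sq: dict = {}
        perms = list(itertools.permutations(pool))
        for perm in perms:
            m = brute_interaction_matrix(
                [("P1", "P2"), ("P1", "P3")],
                {"P1": list(perm[:2]), "P2": [perm[2]], "P3": [perm[3]]})
            for k in set(m):
                exact[k] = exact.get(k, 0.0) + m[k] / len(perms)
                sq[k] = sq.get(k, 0.0) + m[k] ** 2 / len(perms)
        b = 200
        null = null_mean_matrix(net, ann(mapping),
                                plan=RandomizationPlan(n_randomizations=b, seed=5))
        for key, mean in exact.items():
            se = math.sqrt(max(sq[key] - mean ** 2, 0.0) / b)
            assert abs(null.mass.get(key, 0.0) - mean) <= 3 * se + 1e-12


class TestRatioAndScore:
    def make_ratio(self, mass, n_rand=40, max_mn=4):
        return DomainPairMatrix(mass=dict(mass), mode="ratio", subset="CC",
                                n_randomizations=n_rand, max_mn=max_mn)

    def test_simple_ratio(self):
        obs = DomainPairMatrix(mass={("a", "b"): 1.0}, mode="observed",
                               n_edges=1, max_mn=1)
        null = DomainPairMatrix(mass={("a", "b"): 0.5}, mode="null_mean",
                                n_randomizations=40)
        r = ratio_matrix(obs, null)
        assert r[("a", "b")] == pytest.approx(2.0)

    def test_unobserved_pair_scores_zero(self):
        obs = DomainPairMatrix(mass={}, mode="observed", max_mn=1)
        null = DomainPairMatrix(mass={("a", "b"): 0.7}, mode="null_mean",
                                n_randomizations=4)
        assert ratio_matrix(obs, null)[("a", "b")] == 0.0

    def test_self_null_identity(self):
        mass = {("a", "b"): 1.5, ("a", "a"): 0.5}
        obs = DomainPairMatrix(mass=dict(mass), mode="observed", max_mn=2)
        null = DomainPairMatrix(mass=dict(mass), mode="null_mean",
                                n_randomizations=1)
        r = ratio_matrix(obs, null)
        assert all(v == pytest.approx(1.0) for v in r.mass.values())

    def test_zero_null_floored(self):
        obs = DomainPairMatrix(mass={("a", "b"): 0.25}, mode="observed",
                               max_mn=4)
        null = DomainPairMatrix(mass={}, mode="null_mean", n_randomizations=40)
        r = ratio_matrix(obs, null)
        assert r[("a", "b")] == pytest.approx(0.25 * 40 * 4)

    def test_provenance_mismatch(self):
        obs = DomainPairMatrix(mass={}, mode="observed", subset="CC")
        null = DomainPairMatrix(mass={}, mode="null_mean", subset="all",
                                n_randomizations=1)
        with pytest.raises(ProvenanceError):
            ratio_matrix(obs, null)

    def test_strict_threshold(self):
        a = ann({"P1": ["a", "b"], "P2": ["c", "d"]})
        r = self.make_ratio({("a", "c"): 2.0, ("a", "d"): 1.5,
                             ("b", "c"): 1.0, ("b", "d"): 0.9})
        assert edge_ddi_score(r, a, ("P1", "P2")) == pytest.approx(3.5)

    def test_all_below_threshold_scores_zero(self):
        a = ann({"P1": ["a"], "P2": ["b"]})
        assert edge_ddi_score(self.make_ratio({("a", "b"): 1.0}), a,
                              ("P1", "P2")) == 0.0

    def test_partial_coverage(self):
        a = ann({"P1": ["a"], "P2": ["b", "c"]})
        r = self.make_ratio({("a", "b"): 2.5, ("a", "c"): 0.5})
        assert edge_ddi_score(r, a, ("P1", "P2")) == pytest.approx(2.5)

    def test_orientation_invariance(self):
        a = ann({"P1": ["a", "b"], "P2": ["c"]})
        r = self.make_ratio({("a", "c"): 3.0, ("b", "c"): 1.2})
        assert edge_ddi_score(r, a, ("P1", "P2")) == \
            edge_ddi_score(r, a, ("P2", "P1"))

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        domains = [f"d{i}" for i in range(6)]
        for _ in range(50):
            ratio_map = {tuple(sorted((x, y))): float(rng.uniform(0, 3))
                         for x in domains for y in domains}
            da = list(rng.choice(domains, size=rng.integers(1, 4)))
            db = list(rng.choice(domains, size=rng.integers(1, 4)))
            a = ann({"P1": da, "P2": db})
            got = edge_ddi_score(self.make_ratio(ratio_map), a, ("P1", "P2"))
            assert got == pytest.approx(brute_edge_ddi(ratio_map, da, db))


def test_ratio_near_one_on_shuffled_annotations():
    """With label-independent domains, mass-weighted mean ratio tends to 1."""
    rng = np.random.default_rng(0)
    proteins = [f"P{i}" for i in range(40)]
    mapping = {p: list(rng.choice([f"d{i}" for i in range(5)],
                                  size=rng.integers(1, 4)))
               for p in proteins}
    edges = {tuple(sorted(rng.choice(proteins, 2, replace=False)))
             for _ in range(120)}
    net = network_from_edges(edges, cancer=proteins)
    a = ann(mapping)
    obs = interaction_matrix(net, a)
    null = null_mean_matrix(net, a, plan=RandomizationPlan(200, seed=9))
    r = ratio_matrix(obs, null)
    weighted = sum(obs.mass[k] * r.mass[k] for k in r.mass) / obs.total_mass()
    assert weighted == pytest.approx(1.0, abs=0.1)
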