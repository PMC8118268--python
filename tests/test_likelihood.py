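import itertools
import json
import math

import numpy as np
import pytest

import pbdelim as pb
from pbdelim.exceptions import InputError

from conftest import (
    random_lineage_tree,
    random_partition,
    steiner_subtrees_overlap,
)


class TestBranchProbability:
    def test_zero_rate(self):
        assert pb.branch_no_event_probability(0.0, 5.0) == 1.0

    def test_closed_form(self):
        assert pb.branch_no_event_probability(0.1, 10.0) == pytest.approx(
            math.exp(-1.0)
        )

    def test_monotone_vanishing(self):
        probs = [pb.branch_no_event_probability(s, 2.0) for s in (0.1, 1, 10, 1e6)]
        assert all(a > b for a, b in zip(probs, probs[1:]))
        assert probs[-1] < 1e-300

    def test_domain_errors(self):
        with pytest.raises(InputError):
            pb.branch_no_event_probability(-0.1, 1.0)
        with pytest.raises(InputError):
            pb.branch_no_event_probability(0.1, 0.0)


class TestConfigurationProbability:
    def test_all_quiet_is_product_of_exponentials(self, balanced4):
        sigma = 0.3
        config = pb.EventConfiguration(balanced4, np.zeros(6, dtype=int))
        expected = math.exp(-sigma * balanced4.total_length)
        assert pb.configuration_probability(balanced4, config, sigma) == (
            pytest.approx(expected)
        )

    def test_cherry_single_event(self, cherry):
        config = pb.EventConfiguration(cherry, [1, 0])
        expected = (1 - math.exp(-0.5)) * math.exp(-0.5)
        assert pb.configuration_probability(cherry, config, 0.1) == (
            pytest.approx(expected, rel=1e-9)
        )
        assert expected == pytest.approx(0.238651, abs=1e-6)

    def test_configurations_partition_unit_mass(self, balanced4):
        total = sum(
            pb.configuration_probability(
                balanced4, pb.EventConfiguration(balanced4, bits), 0.37
            )
            for bits in itertools.product((0, 1), repeat=6)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


class TestBruteForce:
    def test_cherry_closed_forms(self):
        t = pb.LineageTree.from_newick("(A:2,B:3);")
        sigma = 0.2
        together = pb.partition_probability_bruteforce(
            t, pb.SpeciesPartition([["A", "B"]]), sigma
        )
        apart = pb.partition_probability_bruteforce(
            t, pb.SpeciesPartition([["A"], ["B"]]), sigma
        )
        assert together.probability == pytest.approx(math.exp(-sigma * 5))
        assert apart.probability == pytest.approx(1 - math.exp(-sigma * 5))

    def test_non_convex_partition_impossible(self, balanced4):
        p = pb.SpeciesPartition([["A", "D"], ["B", "C"]])
        assert pb.partition_probability_bruteforce(balanced4, p, 0.4).probability == 0.0

    def test_zero_rate_forces_single_species(self, balanced4):
        single = pb.SpeciesPartition([["A", "B", "C", "D"]])
        assert pb.partition_probability_bruteforce(
            balanced4, single, 0.0
        ).probability == pytest.approx(1.0)
        other = pb.SpeciesPartition([["A", "B"], ["C", "D"]])
        assert pb.partition_probability_bruteforce(
            balanced4, other, 0.0
        ).probability == 0.0


class TestDynamicProgram:
    def test_matches_bruteforce_on_random_instances(self):
        # the full 500-case equivalence sweep lives in the acceptance suite
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            tree = random_lineage_tree(rng, n)
            part = random_partition(rng, tree.leaf_label_set)
            sigma = float(rng.uniform(0, 0.5))
            bf = pb.partition_probability_bruteforce(tree, part, sigma)
            dp = pb.partition_probability(tree, part, sigma)
            assert dp.probability == pytest.approx(
                bf.probability, rel=1e-10, abs=1e-300
            )

    def test_polytomy_handled(self):
        tree = pb.LineageTree.from_newick("((A:1,B:1,C:1):1,D:2);")
        for part in pb.enumerate_compatible_partitions(tree.leaf_labels):
            bf = pb.partition_probability_bruteforce(tree, part, 0.3)
            dp = pb.partition_probability(tree, part, 0.3)
            assert dp.probability == pytest.approx(bf.probability, rel=1e-10)

    def test_normalizes_over_all_partitions(self):
        rng = np.random.default_rng(1)
        tree = random_lineage_tree(rng, 5)
        for sigma in (0.01, 0.3, 2.0):
            total = sum(
                pb.partition_probability(tree, p, sigma).probability
                for p in pb.enumerate_compatible_partitions(tree.leaf_labels)
            )
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_monotone_in_rate(self, balanced4):
        singletons = pb.SpeciesPartition([[l] for l in "ABCD"])
        single = pb.SpeciesPartition([list("ABCD")])
        sigmas = [0.01, 0.1, 0.5, 2.0, 10.0]
        p_sing = [
            pb.partition_probability(balanced4, singletons, s).probability
            for s in sigmas
        ]
        p_one = [
            pb.partition_probability(balanced4, single, s).probability
            for s in sigmas
        ]
        assert all(a <= b for a, b in zip(p_sing, p_sing[1:]))
        assert all(a >= b for a, b in zip(p_one, p_one[1:]))

    def test_no_underflow_on_large_tree(self):
        # 200 tips, branch rate-durations up to ~50: log space must survive
        tree = pb.simulate_lineage_tree(pb.PBDParams(0.1, 0.0, 0.0), 200, seed=3)
        sigma = 50.0 / float(tree.branch_lengths.max())
        singletons = pb.SpeciesPartition([[l] for l in tree.leaf_label_set])
        logp = pb.partition_log_probability(tree, singletons, sigma)
        assert math.isfinite(logp)
        assert logp <= 0.0
        single = pb.SpeciesPartition([list(tree.leaf_label_set)])
        logp1 = pb.partition_log_probability(tree, single, sigma)
        assert logp1 == pytest.approx(-sigma * tree.total_length)

    def test_zero_probability_iff_steiner_subtrees_overlap(self):
        rng = np.random.default_rng(9)
        for _ in range(6):
            n = int(rng.integers(4, 7))
            tree = random_lineage_tree(rng, n)
            for part in pb.enumerate_compatible_partitions(tree.leaf_labels):
                dp_zero = (
                    pb.partition_log_probability(tree, part, 0.3) == -math.inf
                )
                assert dp_zero == steiner_subtrees_overlap(tree, part)


class TestRanking:
    def test_cherry_closed_form_table(self, cherry):
        table = pb.rank_partitions(cherry, None, 0.1)
        assert len(table) == 2
        assert table.map_partition == pb.SpeciesPartition([["A"], ["B"]])
        assert table.conditional_probabilities[0] == pytest.approx(
            1 - math.exp(-1), abs=1e-4
        )
        assert table.conditional_probabilities[1] == pytest.approx(
            math.exp(-1), abs=1e-4
        )
        assert table.credibility_set_size == 2  # 0.632 alone is below 0.95

    def test_zero_rate_certain_single_species(self, balanced4):
        table = pb.rank_partitions(balanced4, None, 0.0)
        assert table.map_partition == pb.SpeciesPartition([list("ABCD")])
        assert table.conditional_probabilities[0] == pytest.approx(1.0)
        assert table.credibility_set_size == 1

    def test_conditional_probabilities_normalize(self, caterpillar5):
        c = pb.ConstraintSet({"A": "sp1", "B": "sp1", "E": "sp2"})
        table = pb.rank_partitions(caterpillar5, c, 0.2)
        assert table.conditional_probabilities.sum() == pytest.approx(
            1.0, abs=1e-8
        )
        assert table.cumulative[table.credibility_set_size - 1] >= 0.95
        if table.credibility_set_size > 1:
            assert table.cumulative[table.credibility_set_size - 2] < 0.95
        for p in table.partitions:
            assert pb.is_compatible(p, c)

    def test_ranking_is_deterministic(self, caterpillar5):
        t1 = pb.rank_partitions(caterpillar5, None, 0.15)
        t2 = pb.rank_partitions(caterpillar5, None, 0.15)
        assert t1.partitions == t2.partitions

    def test_table_serialization_validates(self, cherry, tmp_path):
        table = pb.rank_partitions(cherry, None, 0.1)
        doc = json.loads(table.to_json())
        pb.validate_results(doc)
        tsv = tmp_path / "table.tsv"
        table.to_tsv(tsv)
        lines = tsv.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 partitions


class TestConspecificity:
    def test_constrained_pairs_are_certain(self, balanced4):
        c = pb.ConstraintSet({"A": "sp1", "B": "sp1", "C": "sp2"})
        assert pb.conspecificity_probability(
            balanced4, c, 0.2, {"A", "B"}
        ) == pytest.approx(1.0)
        assert pb.conspecificity_probability(
            balanced4, c, 0.2, {"A", "C"}
        ) == 0.0

    def test_cherry_unconstrained_closed_form(self, cherry):
        assert pb.conspecificity_probability(
            cherry, None, 0.1, {"A", "B"}
        ) == pytest.approx(math.exp(-1), rel=1e-9)
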