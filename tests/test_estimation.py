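import math

import numpy as np
import pytest

import pbdelim as pb
from pbdelim.exceptions import InputError
from pbdelim.model import BOUNDARY_INFINITE, BOUNDARY_NONE, BOUNDARY_ZERO

from conftest import random_lineage_tree


def painted_dataset(n_tips, sigma, seed, require_interior=True):
    """Model-exact data: tree + Poisson-painted events + induced partition."""
    for offset in range(40):
        tree = pb.simulate_lineage_tree(
            pb.PBDParams(0.1, 0.0, 0.0), n_tips, seed=seed + 1000 * offset
        )
        config = pb.paint_completion_events(tree, sigma, seed=seed + offset)
        part = pb.induced_partition(tree, config)
        if not require_interior or 1 < part.n_species < n_tips:
            return tree, part
    raise AssertionError("no interior dataset found")


class TestLogLikelihood:
    def test_single_block_closed_form(self, balanced4):
        single = pb.SpeciesPartition([list("ABCD")])
        for sigma in (0.05, 0.7):
            assert pb.sigma_log_likelihood(
                balanced4, single, sigma
            ) == pytest.approx(-sigma * balanced4.total_length)

    def test_matches_bruteforce(self, caterpillar5):
        part = pb.SpeciesPartition([["A", "B"], ["C"], ["D", "E"]])
        for sigma in (0.1, 0.6):
            bf = pb.partition_probability_bruteforce(caterpillar5, part, sigma)
            assert pb.sigma_log_likelihood(
                caterpillar5, part, sigma
            ) == pytest.approx(bf.log_probability, rel=1e-10)

    def test_impossible_partition_gives_neg_inf(self, balanced4):
        p = pb.SpeciesPartition([["A", "D"], ["B", "C"]])
        assert pb.sigma_log_likelihood(balanced4, p, 0.2) == -math.inf

    def test_all_singletons_increases_to_one(self, balanced4):
        singletons = pb.SpeciesPartition([[l] for l in "ABCD"])
        lls = [
            pb.sigma_log_likelihood(balanced4, singletons, s)
            for s in (0.1, 1.0, 10.0, 100.0)
        ]
        assert all(a < b for a, b in zip(lls, lls[1:]))
        assert lls[-1] == pytest.approx(0.0, abs=1e-3)


class TestEstimateSigma:
    def test_all_conspecific_boundary(self, balanced4):
        res = pb.estimate_sigma(balanced4, pb.SpeciesPartition([list("ABCD")]))
        assert res.boundary == BOUNDARY_ZERO
        assert res.sigma_hat == 0.0
        assert res.speciation_completion_time == math.inf

    def test_all_heterospecific_boundary(self, balanced4):
        res = pb.estimate_sigma(
            balanced4, pb.SpeciesPartition([[l] for l in "ABCD"])
        )
        assert res.boundary == BOUNDARY_INFINITE
        assert math.isinf(res.sigma_hat)
        assert not res.ci_defined

    def test_optimum_beats_log_grid(self):
        tree, part = painted_dataset(30, 0.02, seed=5)
        res = pb.estimate_sigma(tree, part)
        assert res.boundary == BOUNDARY_NONE
        grid = np.logspace(-5, 2, 50)
        best_grid = max(pb.sigma_log_likelihood(tree, part, s) for s in grid)
        assert res.log_likelihood >= best_grid - 1e-6

    def test_parameter_recovery_median_within_factor_two(self):
        ests = []
        for rep in range(30):
            tree, part = painted_dataset(60, 0.01, seed=20_000 + rep)
            res = pb.estimate_sigma(tree, part)
            assert res.boundary == BOUNDARY_NONE
            ests.append(res.sigma_hat)
        med = float(np.median(ests))
        assert 0.005 <= med <= 0.02


class TestConfidenceInterval:
    def test_interval_brackets_estimate(self):
        tree, part = painted_dataset(40, 0.02, seed=77)
        res = pb.estimate_sigma(tree, part)
        assert res.ci_defined
        assert 0.0 <= res.ci_low <= res.sigma_hat <= res.ci_high

    def test_coverage_near_nominal_under_exact_model(self):
        # model-exact data, so the Fisher interval should cover ~95% of runs
        hits = total = 0
        for rep in range(40):
            tree, part = painted_dataset(40, 0.01, seed=40_000 + rep)
            res = pb.estimate_sigma(tree, part)
            if not res.ci_defined:
                continue
            total += 1
            hits += res.ci_low <= 0.01 <= res.ci_high
        assert total >= 30
        assert 0.85 <= hits / total <= 1.0

    def test_width_shrinks_with_tree_size(self):
        widths = {}
        for n in (20, 80):
            w = []
            for rep in range(12):
                tree, part = painted_dataset(n, 0.02, seed=60_000 + rep)
                res = pb.estimate_sigma(tree, part)
                if res.ci_defined:
                    w.append(res.ci_high - res.ci_low)
            widths[n] = float(np.mean(w))
        assert widths[80] < widths[20]

    def test_requires_interior_estimate(self, balanced4):
        with pytest.raises(InputError):
            pb.sigma_confidence_interval(
                balanced4, pb.SpeciesPartition([list("ABCD")]), math.inf
            )


class TestDelimitationModes:
    def test_full_constraints_reduce_to_rate_estimation(self):
        ds = pb.simulate_dataset(pb.PBDParams(0.1, 0.0, 0.02), 12, seed=8)
        names = ds.partition.names
        assignments = {
            l: names[ds.partition.block_of(l)] for l in ds.tree.leaf_label_set
        }
        res = pb.constrained_delimitation(
            ds.tree, pb.ConstraintSet(assignments)
        )
        assert len(res.table) == 1
        assert res.table.conditional_probabilities[0] == pytest.approx(1.0)
        assert res.map_partition == pb.SpeciesPartition(ds.partition.blocks)
        direct = pb.estimate_sigma(ds.tree, ds.partition)
        assert res.rate.sigma_hat == pytest.approx(direct.sigma_hat, rel=1e-6)

    def test_all_conspecific_constraints_give_certain_lump(self, balanced4):
        c = pb.ConstraintSet({"A": "sp1", "B": "sp1"})
        res = pb.constrained_delimitation(balanced4, c)
        assert res.rate.boundary == BOUNDARY_ZERO
        assert res.map_partition == pb.SpeciesPartition([list("ABCD")])
        assert res.table.conditional_probabilities[0] == pytest.approx(1.0)

    def test_unconstrained_requires_positive_rate(self, balanced4):
        with pytest.raises(InputError):
            pb.unconstrained_delimitation(balanced4, 0.0)

    def test_unconstrained_matches_rank_partitions(self, caterpillar5):
        res = pb.unconstrained_delimitation(caterpillar5, 0.2)
        ref = pb.rank_partitions(caterpillar5, None, 0.2)
        assert res.table.partitions == ref.partitions
        np.testing.assert_allclose(
            res.table.conditional_probabilities, ref.conditional_probabilities
        )

    def test_conspecificity_through_results(self, cherry):
        res = pb.unconstrained_delimitation(cherry, 0.1)
        assert res.conspecificity_probability({"A", "B"}) == pytest.approx(
            math.exp(-1), rel=1e-9
        )

    def test_summary_renders(self, cherry):
        res = pb.unconstrained_delimitation(cherry, 0.1)
        text = res.summary()
        assert "candidate partitions" in text
        tree, part = painted_dataset(20, 0.02, seed=300)
        rate_text = pb.estimate_sigma(tree, part).summary()
        assert "sigma_hat" in rate_text


class TestAverageOverTrees:
    def test_single_tree_identity(self, caterpillar5):
        avg = pb.average_over_trees([caterpillar5], None, 0.2)
        ref = pb.rank_partitions(caterpillar5, None, 0.2)
        assert avg.partitions == ref.partitions
        np.testing.assert_allclose(
            avg.conditional_probabilities,
            ref.conditional_probabilities,
            rtol=1e-12,
        )

    def test_copies_identity(self, caterpillar5):
        avg = pb.average_over_trees([caterpillar5] * 3, None, 0.2)
        ref = pb.rank_partitions(caterpillar5, None, 0.2)
        np.testing.assert_allclose(
            avg.conditional_probabilities,
            ref.conditional_probabilities,
            rtol=1e-10,
        )

    def test_mean_of_normalized_is_normalized(self):
        trees = [
            random_lineage_tree(np.random.default_rng(s), 5) for s in (1, 2, 3)
        ]
        # share one label set by construction (T0..T4)
        avg = pb.average_over_trees(trees, None, 0.3)
        with np.errstate(under="ignore"):
            uncond = np.exp(avg.log_probabilities)
        assert uncond.sum() == pytest.approx(1.0, abs=1e-8)

    def test_leaf_set_mismatch_rejected(self, cherry, balanced4):
        with pytest.raises(InputError):
            pb.average_over_trees([cherry, balanced4], None, 0.1)
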