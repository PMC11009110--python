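"""Decoy generation, empirical p-values, adaptive FDR, replicate combination."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from dipms.fdr import (
    adaptive_fdr,
    combine_replicates,
    empirical_pvalues,
    estimate_pi0,
    filter_network,
    generate_decoys,
    make_score_table,
)


class TestGenerateDecoys:
    def test_one_decoy_per_protein_disjoint_from_targets(self):
        proteins = [f"P{i}" for i in range(10)]
        targets = [("P0", "P1"), ("P2", "P3")]
        decoys = generate_decoys(proteins, targets, seed=0)
        assert len(decoys) == 10
        target_set = {frozenset(t) for t in targets}
        assert all(frozenset(d) not in target_set for d in decoys)
        assert len({frozenset(d) for d in decoys}) == len(decoys)

    def test_seeded_reproducibility(self):
        proteins = [f"P{i}" for i in range(8)]
        targets = [("P0", "P1")]
        assert generate_decoys(proteins, targets, seed=4) == generate_decoys(
            proteins, targets, seed=4
        )

    def test_fully_connected_target_set_yields_no_decoys(self):
        proteins = ["A", "B", "C"]
        targets = [("A", "B"), ("A", "C"), ("B", "C")]
        with pytest.warns(UserWarning):
            decoys = generate_decoys(proteins, targets, seed=0)
        assert decoys == []


class TestEmpiricalPvalues:
    def test_target_above_all_decoys(self):
        decoys = np.linspace(0.0, 0.5, 10)
        p = empirical_pvalues(np.array([0.9]), decoys)
        assert p[0] == pytest.approx(1 / 11)

    def test_target_below_all_decoys(self):
        decoys = np.linspace(0.5, 0.9, 7)
        p = empirical_pvalues(np.array([0.1]), decoys)
        assert p[0] == pytest.approx(1.0)

    def test_equal_targets_equal_pvalues(self):
        decoys = np.array([0.2, 0.4, 0.6])
        p = empirical_pvalues(np.array([0.5, 0.5]), decoys)
        assert p[0] == p[1]

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(0)
        decoys = rng.random(50)
        targets = np.sort(rng.random(30))
        p = empirical_pvalues(targets, decoys)
        assert np.all(np.diff(p) <= 0)

    def test_requires_decoys(self):
        with pytest.raises(ValueError):
            empirical_pvalues(np.array([0.5]), np.array([]))

    def test_matches_rank_rule_oracle(self):
        rng = np.random.default_rng(1)
        decoys = rng.random(40)
        targets = rng.random(25)
        p = empirical_pvalues(targets, decoys)
        oracle = np.array(
            [(1 + np.sum(decoys >= t)) / (1 + len(decoys)) for t in targets]
        )
        np.testing.assert_allclose(p, oracle)


class TestAdaptiveFdr:
    def test_worked_example_pi0_one(self):
        q = adaptive_fdr(np.array([0.01, 0.02, 0.03, 0.04]), pi0=1.0)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(adaptive_fdr(np.ones(5), pi0=1.0), np.ones(5))

    def test_reproduces_benjamini_hochberg_on_random_vectors(self):
        rng = np.random.default_rng(2)
        worst = 0.0
        for _ in range(1000):
            p = rng.random(rng.integers(3, 40))
            q = adaptive_fdr(p, pi0=1.0)
            bh = multipletests(p, method="fdr_bh")[1]
            worst = max(worst, np.abs(q - bh).max())
        assert worst < 1e-12

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(3)
        p = rng.random(100)
        q = adaptive_fdr(p, pi0=0.7)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(4)
        p = rng.random(50)
        perm = rng.permutation(50)
        q = adaptive_fdr(p)
        np.testing.assert_allclose(q[perm], adaptive_fdr(p[perm]))

    def test_pi0_scales_linearly(self):
        p = np.array([0.01, 0.2, 0.5])
        np.testing.assert_allclose(
            adaptive_fdr(p, pi0=0.5), np.clip(adaptive_fdr(p, pi0=1.0) * 0.5, 0, 1)
        )

    def test_invalid_pi0(self):
        with pytest.raises(ValueError):
            adaptive_fdr(np.array([0.5]), pi0=0.0)
        with pytest.raises(ValueError):
            adaptive_fdr(np.array([0.5]), pi0=1.5)


class TestEstimatePi0:
    def test_separated_scores_give_floor(self):
        targets = np.full(100, 0.9)
        decoys = np.full(50, 0.1)
        assert estimate_pi0(targets, decoys) == pytest.approx(0.05)

    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(5)
        scores = rng.random(4000)
        pi0 = estimate_pi0(scores[:2000], scores[2000:])
        assert 0.4 < pi0 < 0.6


class TestCombineReplicates:
    def test_single_replicate_passthrough(self):
        assert combine_replicates([0.7]) == pytest.approx(0.7)

    def test_absorbing_one(self):
        assert combine_replicates([1.0, 0.2]) == pytest.approx(1.0)

    def test_noisy_or_arithmetic(self):
        assert combine_replicates([0.9, 0.9]) == pytest.approx(0.99)

    def test_at_least_max_single_replicate(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            p = rng.random(4)
            assert combine_replicates(p) >= p.max() - 1e-12

    def test_monotone_in_each_replicate(self):
        base = [0.3, 0.4, 0.5]
        bumped = [0.35, 0.4, 0.5]
        assert combine_replicates(bumped) > combine_replicates(base)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            combine_replicates([0.5], weights=[1.5])
        with pytest.raises(ValueError):
            combine_replicates([1.2])


class TestFilterNetwork:
    def make_table(self):
        return pd.DataFrame(
            {
                "protein_a": ["A", "C", "E", "G"],
                "protein_b": ["B", "D", "F", "H"],
                "combined_p": [0.95, 0.6, 0.8, 0.3],
                "q_value": [0.05, 0.2, 0.08, 0.5],
                "is_decoy": [False, False, False, True],
            }
        )

    def test_q_cutoff_and_confidence_flag(self):
        out = filter_network(self.make_table(), fdr_alpha=0.10, confidence_cut=0.9)
        kept = set(zip(out["protein_a"], out["protein_b"]))
        assert kept == {("A", "B"), ("E", "F")}
        flags = dict(zip(out["protein_a"], out["high_confidence"]))
        assert flags["A"] and not flags["E"]

    def test_decoys_removed(self):
        out = filter_network(self.make_table(), fdr_alpha=1.0)
        assert not out["is_decoy"].any()


class TestScoreTable:
    def test_assembly_and_ordering(self):
        targets = [("A", "B"), ("C", "D")]
        decoys = [("E", "F")]
        tp = np.array([[0.9, 0.8], [0.2, np.nan]])
        dp = np.array([[0.1, 0.2]])
        table = make_score_table(targets, tp, decoys, dp, pi0=1.0)
        assert set(table.columns) >= {
            "protein_a", "protein_b", "p_rep1", "p_rep2",
            "combined_p", "empirical_p", "q_value", "is_decoy",
        }
        top = table.iloc[0]
        assert (top["protein_a"], top["protein_b"]) == ("A", "B")
        # NaN replicate skipped in combination
        cd = table.set_index(["protein_a", "protein_b"]).loc[("C", "D"), "combined_p"]
        assert cd == pytest.approx(0.2)
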