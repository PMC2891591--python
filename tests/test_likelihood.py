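"""Pruning likelihoods against exhaustive oracles; helix-score properties."""

from types import SimpleNamespace

import numpy as np
import pytest

from transat import (
    AlignmentScorer,
    MultipleAlignment,
    SubstitutionModel,
    column_likelihood,
    tree_from_newick_string,
)
from transat.helices import ConservedHelix
from transat.likelihood import TreeLikelihood
from transat.models import (
    PAIRED_STATES,
    UNPAIRED_STATES,
    leaf_vector_paired,
    leaf_vector_unpaired,
)
from transat.tree import PhyloTree

from .conftest import exhaustive_likelihood, random_newick, reroot_newick


def single_leaf_tree(label="A"):
    return PhyloTree([None], np.array([0.0]), [label], root=0)


class TestColumnLikelihood:
    def test_single_leaf_reduces_to_equilibrium(self, unpaired_model):
        lik = column_likelihood(
            "G", single_leaf_tree(), unpaired_model, {"A": 0}
        )
        assert lik == pytest.approx(unpaired_model.freqs[2], abs=1e-15)

    def test_two_leaf_paired_matches_root_sum(self, paired_model, two_leaf_tree):
        # brute force: sum over 16 root states of pi_r P[r->GC](t1) P[r->GC](t2)
        gc = PAIRED_STATES.index("GC")
        p1 = paired_model.transition_matrix(0.3)
        p2 = paired_model.transition_matrix(0.7)
        expected = float(
            (paired_model.freqs * p1[:, gc] * p2[:, gc]).sum()
        )
        lik = column_likelihood(
            ("GG", "CC"), two_leaf_tree, paired_model, {"A": 0, "B": 1}
        )
        assert lik == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "newick",
        ["(A:0.4,B:0.9);", "((A:0.2,B:0.5):0.3,C:0.8);"],
    )
    def test_pruning_equals_exhaustive_sum_both_alphabets(
        self, models, newick
    ):
        tree = tree_from_newick_string(newick)
        labels = tree.leaf_labels
        rng = np.random.default_rng(17)
        unpaired, paired = models
        for model, leaf_fn, chars in (
            (unpaired, leaf_vector_unpaired, "ACGUN-"),
            (paired, leaf_vector_paired, "ACGUN-"),
        ):
            for _ in range(5):
                if model is unpaired:
                    obs = {
                        lab: leaf_fn(rng.choice(list(chars))) for lab in labels
                    }
                else:
                    obs = {
                        lab: leaf_fn(
                            rng.choice(list(chars)), rng.choice(list(chars))
                        )
                        for lab in labels
                    }
                oracle = exhaustive_likelihood(tree, model, obs)
                data = np.stack([obs[lab][None, :] for lab in labels])
                engine = TreeLikelihood(
                    tree, model, {lab: i for i, lab in enumerate(labels)}
                )
                got = float(np.exp(engine.log_likelihood(data)[0]))
                assert got == pytest.approx(oracle, abs=1e-12)

    def test_fully_observed_single_leaf_likelihoods_sum_to_one(self, models):
        tree = single_leaf_tree()
        for model, states in zip(models, (UNPAIRED_STATES, PAIRED_STATES)):
            total = 0.0
            for s in states:
                cols = s if len(s) == 1 else (s[0], s[1])
                total += column_likelihood(cols, tree, model, {"A": 0})
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_root_placement_invariance(self, models):
        rng = np.random.default_rng(23)
        unpaired, paired = models
        for trial in range(20):
            newick = random_newick(5, rng)
            tree_a = tree_from_newick_string(newick)
            tree_b = tree_from_newick_string(reroot_newick(newick, rng))
            labels = tree_a.leaf_labels
            chars = [rng.choice(list("ACGU-")) for _ in labels]
            chars2 = [rng.choice(list("ACGU-")) for _ in labels]
            for model, obs in (
                (unpaired, [leaf_vector_unpaired(c) for c in chars]),
                (
                    paired,
                    [leaf_vector_paired(c, d) for c, d in zip(chars, chars2)],
                ),
            ):
                liks = []
                for tree in (tree_a, tree_b):
                    order = {lab: i for i, lab in enumerate(labels)}
                    data = np.stack([v[None, :] for v in obs])
                    engine = TreeLikelihood(tree, model, order)
                    liks.append(engine.log_likelihood(data)[0])
                assert liks[0] == pytest.approx(liks[1], abs=1e-10)

    def test_deep_tree_no_underflow(self, unpaired_model):
        # 64 leaves: per-node rescaling must keep the log-likelihood finite
        n = 64
        newick = "A0:0.1"
        for i in range(1, n):
            newick = f"({newick},A{i}:0.1):0.1"
        tree = tree_from_newick_string(newick + ";")
        labels = tree.leaf_labels
        data = np.stack(
            [leaf_vector_unpaired("G")[None, :] for _ in labels]
        )
        engine = TreeLikelihood(
            tree, unpaired_model, {lab: i for i, lab in enumerate(labels)}
        )
        ll = engine.log_likelihood(data)[0]
        assert np.isfinite(ll) and ll < 0


def kronecker_paired_model(unpaired: SubstitutionModel) -> SubstitutionModel:
    """Paired model whose halves evolve independently (no covariation)."""
    q4, pi4 = unpaired.rates, unpaired.freqs
    eye = np.eye(4)
    q16 = np.kron(q4, eye) + np.kron(eye, q4)
    pi16 = np.kron(pi4, pi4)
    return SubstitutionModel(PAIRED_STATES, q16, pi16, name="kronecker")


class TestHelixScore:
    def make_scorer(self, models, rows, newick=None):
        aln = MultipleAlignment([f"s{i}" for i in range(len(rows))], rows)
        if newick is None:
            newick = "(" + ",".join(f"s{i}:0.4" for i in range(len(rows))) + ");"
        tree = tree_from_newick_string(newick)
        return AlignmentScorer(aln, tree, models), aln, tree

    def test_independent_halves_model_scores_zero(self, unpaired_model):
        models = (unpaired_model, kronecker_paired_model(unpaired_model))
        scorer, _, _ = self.make_scorer(
            models, ["GGGGAAAACCCC", "GGCGAAAACGCC"]
        )
        h = ConservedHelix(column_pairs=((0, 11), (1, 10), (2, 9), (3, 8)))
        assert scorer.score_helix(h) == pytest.approx(0.0, abs=1e-10)

    def test_length_normalization_duplication_invariant(self, models):
        scorer, _, _ = self.make_scorer(models, ["GGGGAAAACCCC", "GGGGAAAACCCC"])
        pairs = ((0, 11), (1, 10), (2, 9), (3, 8))
        h = ConservedHelix(column_pairs=pairs)
        s1 = scorer.score_helix(h)
        doubled = SimpleNamespace(column_pairs=pairs * 2, score=None)
        s2 = scorer.score_helix(doubled)
        assert s2 == pytest.approx(s1, abs=1e-12)

    def test_two_by_two_toy_matches_brute_force(self, models):
        unpaired, paired = models
        scorer, aln, tree = self.make_scorer(
            models, ["GC", "GU"], newick="(s0:0.2,s1:0.6);"
        )
        h = ConservedHelix(column_pairs=((0, 1),))
        got = scorer.score_helix(h)
        # oracle: explicit sums over root states for both hypotheses
        p_pair = [paired.transition_matrix(t) for t in (0.2, 0.6)]
        p_un = [unpaired.transition_matrix(t) for t in (0.2, 0.6)]
        gc, gu = PAIRED_STATES.index("GC"), PAIRED_STATES.index("GU")
        lik_paired = float(
            (paired.freqs * p_pair[0][:, gc] * p_pair[1][:, gu]).sum()
        )
        g, c, u = 2, 1, 3
        lik_i = float((unpaired.freqs * p_un[0][:, g] * p_un[1][:, g]).sum())
        lik_j = float((unpaired.freqs * p_un[0][:, c] * p_un[1][:, u]).sum())
        expected = np.log(lik_paired) - np.log(lik_i) - np.log(lik_j)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_row_and_leaf_permutation(self, models):
        rows = ["GGGGAAAACCCC", "GGCGAAAACGCC", "GGGGAAUACCCC"]
        aln = MultipleAlignment(["a", "b", "c"], rows)
        tree = tree_from_newick_string("((a:0.3,b:0.5):0.2,c:0.9);")
        aln2 = MultipleAlignment(["c", "a", "b"], [rows[2], rows[0], rows[1]])
        h1 = ConservedHelix(column_pairs=((0, 11), (1, 10), (2, 9), (3, 8)))
        h2 = ConservedHelix(column_pairs=((0, 11), (1, 10), (2, 9), (3, 8)))
        s1 = AlignmentScorer(aln, tree, models).score_helix(h1)
        s2 = AlignmentScorer(aln2, tree, models).score_helix(h2)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_one_sided_gap_lowers_paired_support(self, models):
        # a gap opposite a nucleotide is evidence against pairing
        scorer_full, _, _ = self.make_scorer(
            models, ["GGGGAAAACCCC", "GGGGAAAACCCC"]
        )
        scorer_gap, _, _ = self.make_scorer(
            models, ["GGGGAAAACCCC", "GGGGAAAACCC-"]
        )
        h = lambda: ConservedHelix(column_pairs=((0, 11), (1, 10), (2, 9), (3, 8)))
        assert scorer_gap.score_helix(h()) < scorer_full.score_helix(h())
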