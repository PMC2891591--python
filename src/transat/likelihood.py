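"""Felsenstein pruning and the length-normalized helix log-likelihood score.

The score of a conserved helix h with column pairs (i_k, j_k), k = 1..L, is

    S(h) = (1/L) * [ sum_k log P(col i_k, col j_k | paired model)
                     - sum_k ( log P(col i_k | unpaired model)
                             + log P(col j_k | unpaired model) ) ]

with natural logarithms.  Both hypotheses are evaluated with the pruning
algorithm on the same input tree; the division by L makes scores of helices
of different lengths comparable.

Numerics: likelihoods are propagated with per-node rescaling (the maximum
entry of each partial vector is divided out and accumulated in log space),
so the returned log-likelihood does not underflow on deep trees.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alignment import MultipleAlignment, match_leaves
from .errors import ValidationError
from .models import (
    PAIRED_LEAF_TABLE,
    UNPAIRED_LEAF_TABLE,
    SubstitutionModel,
)
from .tree import PhyloTree


class TreeLikelihood:
    """Pruning engine for one (tree, model) pair.

    Evaluates the log-likelihood of many independent observation columns at
    once: ``leaf_data`` has shape ``(n_leaves, n_items, n_states)`` where
    leaves are indexed in the order of ``leaf_row_order`` (a list mapping
    each tree leaf to its row in ``leaf_data``).
    """

    def __init__(self, tree: PhyloTree, model: SubstitutionModel,
                 row_of_label: dict[str, int]):
        self.tree = tree
        self.model = model
        self.row_of_node = {
            k: row_of_label[tree.labels[k]] for k in tree.leaf_indices()
        }

    def log_likelihood(self, leaf_data: np.ndarray) -> np.ndarray:
        """Return log-likelihoods, shape ``(n_items,)``."""
        tree, model = self.tree, self.model
        n_items = leaf_data.shape[1]
        partial: dict[int, np.ndarray] = {}
        log_scale = np.zeros(n_items)
        for node in tree.postorder():
            kids = tree.children[node]
            if kids is None:
                partial[node] = leaf_data[self.row_of_node[node]]
                continue
            prod = None
            for kid in kids:
                p = model.transition_matrix(tree.branch_lengths[kid])
                msg = partial.pop(kid) @ p.T
                prod = msg if prod is None else prod * msg
            scale = prod.max(axis=1)
            ok = scale > 0
            safe = np.where(ok, scale, 1.0)
            prod = prod / safe[:, None]
            with np.errstate(divide="ignore"):
                log_scale += np.where(ok, np.log(safe), -np.inf)
            partial[node] = prod
        root_lik = partial[tree.root] @ model.freqs
        with np.errstate(divide="ignore"):
            out = np.log(root_lik) + log_scale
        if np.any(~np.isfinite(out)):
            warnings.warn("zero likelihood encountered in pruning")
        return out


def column_likelihood(
    columns: str | tuple[str, str],
    tree: PhyloTree,
    model: SubstitutionModel,
    row_of_label: dict[str, int],
) -> float:
    """Likelihood of one unpaired column (a string, one character per row)
    or one ordered pair of columns (a 2-tuple of such strings).

    ``row_of_label`` maps tree leaf labels to string positions.  This is the
    scalar convenience entry point; bulk scoring goes through
    :class:`AlignmentScorer`.
    """
    from .models import leaf_vector_paired, leaf_vector_unpaired

    if isinstance(columns, tuple):
        col_i, col_j = columns
        data = np.stack(
            [
                leaf_vector_paired(ci, cj)[None, :]
                for ci, cj in zip(col_i, col_j)
            ]
        )
    else:
        data = np.stack(
            [leaf_vector_unpaired(c)[None, :] for c in columns]
        )
    engine = TreeLikelihood(tree, model, row_of_label)
    return float(np.exp(engine.log_likelihood(data)[0]))


class AlignmentScorer:
    """Caches column likelihoods of one alignment under both models.

    Unpaired log-likelihoods are computed for every column in a single
    vectorized pruning pass on first use; paired log-likelihoods are
    computed in batches for the distinct column pairs requested and cached.
    """

    def __init__(
        self,
        aln: MultipleAlignment,
        tree: PhyloTree,
        models: tuple[SubstitutionModel, SubstitutionModel],
    ):
        self.aln = aln
        self.tree = tree
        self.unpaired_model, self.paired_model = models
        row_of_label = match_leaves(aln, tree)
        self._unpaired_engine = TreeLikelihood(
            tree, self.unpaired_model, row_of_label
        )
        self._paired_engine = TreeLikelihood(
            tree, self.paired_model, row_of_label
        )
        self._unpaired_ll: np.ndarray | None = None
        self._paired_ll: dict[tuple[int, int], float] = {}

    @property
    def unpaired_loglik(self) -> np.ndarray:
        """Per-column unpaired log-likelihoods, shape ``(n_cols,)``."""
        if self._unpaired_ll is None:
            leaf_data = UNPAIRED_LEAF_TABLE[self.aln.codes]
            self._unpaired_ll = self._unpaired_engine.log_likelihood(leaf_data)
        return self._unpaired_ll

    def paired_loglik(self, pairs) -> np.ndarray:
        """Paired log-likelihoods for a sequence of column pairs ``(i, j)``."""
        pairs = list(pairs)
        missing = sorted({p for p in pairs if p not in self._paired_ll})
        if missing:
            codes = self.aln.codes
            ii = np.array([i for i, _ in missing])
            jj = np.array([j for _, j in missing])
            leaf_data = PAIRED_LEAF_TABLE[codes[:, ii], codes[:, jj]]
            ll = self._paired_engine.log_likelihood(leaf_data)
            self._paired_ll.update(zip(missing, ll))
        return np.array([self._paired_ll[p] for p in pairs])

    def score_helix(self, helix) -> float:
        """Length-normalized paired-vs-unpaired log-likelihood ratio.

        The score is stored on the helix and returned.
        """
        pairs = helix.column_pairs
        if len(pairs) < 1:
            raise ValidationError("cannot score an empty helix")
        paired = self.paired_loglik(pairs).sum()
        cols = [c for pair in pairs for c in pair]
        unpaired = self.unpaired_loglik[cols].sum()
        score = (paired - unpaired) / len(pairs)
        if not np.isfinite(score):
            raise ValidationError("helix score undefined (zero likelihood)")
        helix.score = float(score)
        return helix.score

    def score_all(self, helices) -> None:
        """Score a list of helices, batching the paired-column pruning."""
        all_pairs = sorted({p for h in helices for p in h.column_pairs})
        if all_pairs:
            self.paired_loglik(all_pairs)  # warm the cache in one batch
        for h in helices:
            self.score_helix(h)


def helix_score(
    helix,
    aln: MultipleAlignment,
    tree: PhyloTree,
    models: tuple[SubstitutionModel, SubstitutionModel],
) -> float:
    """Score a single conserved helix (see :class:`AlignmentScorer`)."""
    return AlignmentScorer(aln, tree, models).score_helix(helix)
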