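"""Self-contained benchmark experiments on simulated alignments.

Two reduced-scale experiments used for validation and reporting:

* :func:`recovery_sensitivity` — simulate structured alignments at a given
  total tree length, run the full prediction pipeline and measure the
  helix-level sensitivity at a p-value threshold.  Comparing tree lengths
  (e.g. 0.5 vs 4) exhibits the dependence of performance on evolutionary
  diversity: covariation, the signal the score detects, accumulates with
  total tree length.

* :func:`null_pvalue_uniformity` — run the pipeline on *structure-free*
  alignments (a structured simulation destroyed by one within-bin column
  shuffle) and test the resulting helix p-values against Uniform(0, 1]
  with a Kolmogorov-Smirnov statistic.  On structure-free input the
  p-values should be calibrated.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .evaluate import classify_helices
from .helices import collect_conserved_helices
from .likelihood import AlignmentScorer
from .models import load_default_models
from .null import (
    ShuffleConfig,
    assign_pvalues,
    bin_columns,
    build_null_distribution,
    shuffle_alignment,
)
from .simulate import SimulationSpec, evolve_alignment, random_structure


def _predict_on(aln, tree, models, n_shuffles, null_seed):
    helices = collect_conserved_helices(aln)
    if not helices:
        return []
    AlignmentScorer(aln, tree, models).score_all(helices)
    null = build_null_distribution(
        aln, tree, models, ShuffleConfig(n_shuffles=n_shuffles, seed=null_seed)
    )
    assign_pvalues(helices, null)
    return helices


def recovery_sensitivity(
    total_tree_length: float,
    n_replicates: int = 10,
    seed: int = 0,
    n_seqs: int = 10,
    length_range: tuple[int, int] = (100, 200),
    n_shuffles: int = 100,
    p_hat: float = 0.05,
    models=None,
) -> tuple[float, int]:
    """Helix-level sensitivity on simulated structured alignments.

    Counts are pooled over replicates; returns ``(sensitivity, n_matching)``
    where ``n_matching = TP + FN`` is the number of candidate helices that
    match the generating structure (70% rule).  Deterministic given ``seed``.
    """
    if models is None:
        models = load_default_models()
    tp = fn = 0
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        structure = random_structure(length, rng)
        spec = SimulationSpec(
            structure=structure,
            length=length,
            n_seqs=n_seqs,
            total_tree_length=total_tree_length,
            seed=int(rng.integers(2**31)),
        )
        aln, tree = evolve_alignment(spec, models)
        helices = _predict_on(
            aln, tree, models, n_shuffles, int(rng.integers(2**31))
        )
        counts = classify_helices(helices, structure, p_hat)
        tp += counts.tp
        fn += counts.fn
    n_matching = tp + fn
    return (tp / n_matching if n_matching else float("nan")), n_matching


def null_pvalue_uniformity(
    seed: int = 0,
    n_alignments: int = 3,
    length: int = 120,
    n_seqs: int = 8,
    total_tree_length: float = 2.0,
    n_shuffles: int = 100,
    models=None,
) -> tuple[float, float, int]:
    """KS test of helix p-values on structure-free alignments.

    Returns ``(ks_statistic, ks_pvalue, n_pvalues)``.  Under a calibrated
    null the p-values are approximately Uniform(0, 1] (approximately:
    helices overlapping in columns are not independent).
    """
    if models is None:
        models = load_default_models()
    pvals: list[float] = []
    for r in range(n_alignments):
        rng = np.random.default_rng([seed, r])
        structure = random_structure(length, rng)
        spec = SimulationSpec(
            structure=structure,
            length=length,
            n_seqs=n_seqs,
            total_tree_length=total_tree_length,
            seed=int(rng.integers(2**31)),
        )
        aln, tree = evolve_alignment(spec, models)
        # destroy covariation between columns: the input itself becomes a
        # structure-free (pre-shuffled) alignment
        aln0 = shuffle_alignment(
            aln, bin_columns(aln), np.random.default_rng([seed, r, 1])
        )
        helices = _predict_on(
            aln0, tree, models, n_shuffles, int(rng.integers(2**31))
        )
        pvals.extend(h.p_value for h in helices)
    result = stats.kstest(pvals, "uniform")
    return float(result.statistic), float(result.pvalue), len(pvals)
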