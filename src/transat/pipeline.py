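"""End-to-end prediction pipeline (library entry point behind the CLI)."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from .alignment import MultipleAlignment, match_leaves, write_predictions
from .helices import ConservedHelix, collect_conserved_helices
from .likelihood import AlignmentScorer
from .models import load_default_models
from .null import ShuffleConfig, assign_pvalues, build_null_distribution
from .tree import PhyloTree

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Prediction-run parameters; defaults mirror the method description."""

    min_helix_len: int = 4
    min_loop: int = 3
    shuffles: int = 500
    seed: int = 0
    conservation_bins: int = 10
    realign_command: str | None = None
    model_dir: str | None = None
    extra_header: list[str] = field(default_factory=list)


def run_predict(
    aln: MultipleAlignment,
    tree: PhyloTree,
    config: RunConfig | None = None,
    out_path: str | None = None,
) -> list[ConservedHelix]:
    """Detect, score and p-value conserved helices of one alignment.

    Pipeline: leaf/row check -> helix collection -> log-likelihood scoring
    -> shuffled-alignment null -> empirical p-values; optionally writes the
    predictions TSV (header records seed, model provenance and stage
    statistics).  Returns the scored helices (possibly empty).
    """
    config = config or RunConfig()
    match_leaves(aln, tree)
    models = load_default_models(config.model_dir)

    t0 = time.perf_counter()
    helices = collect_conserved_helices(
        aln, min_len=config.min_helix_len, min_loop=config.min_loop
    )
    logger.info("detected %d conserved helices", len(helices))
    null_size = 0
    if helices:
        scorer = AlignmentScorer(aln, tree, models)
        scorer.score_all(helices)
        null = build_null_distribution(
            aln,
            tree,
            models,
            ShuffleConfig(
                n_shuffles=config.shuffles,
                seed=config.seed,
                conservation_bins=config.conservation_bins,
                realign_command=config.realign_command,
            ),
            min_len=config.min_helix_len,
            min_loop=config.min_loop,
        )
        null_size = null.n_scores
        assign_pvalues(helices, null)
    else:
        logger.warning("no candidate helices found; writing an empty result")
    elapsed = time.perf_counter() - t0

    if out_path is not None:
        header = [
            "transat predictions",
            f"n_rows={aln.n_rows} n_cols={aln.n_cols} "
            f"total_tree_length={tree.total_length():.6g}",
            f"seed={config.seed} shuffles={config.shuffles} "
            f"min_helix_len={config.min_helix_len} min_loop={config.min_loop} "
            f"conservation_bins={config.conservation_bins}",
            f"models={'packaged synthetic defaults' if config.model_dir is None else config.model_dir}",
            f"n_helices={len(helices)} null_scores={null_size} "
            f"wall_seconds={elapsed:.2f}",
            *config.extra_header,
        ]
        write_predictions(helices, out_path, header_lines=header)
    return helices
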