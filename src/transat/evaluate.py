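"""Benchmark protocol: confusion counts, metrics, sweeps, arc-diagram export.

Two granularities are evaluated against a reference structure.  At the
base-pair level each predicted column pair inherits the minimum p-value of
all predicted helices containing it; at a threshold p-hat, known pairs with
min-p <= p-hat are TP, predicted-unknown significant pairs FP, known pairs
that are insignificant or never predicted FN, and predicted-but-
insignificant unknown pairs TN.  Note the TN universe is the set of
*predicted* pairs, not all O(n^2) possible pairs — the false positive rate
depends on this choice.  At the helix level a prediction "matches" when at
least 70% of its pairs are identical to reference pairs; matching and
significance define TP/FP/FN/TN as in the base-pair case.

Metrics: Sens = TP/(TP+FN), FPR = FP/(FP+TN), PPV = TP/(TP+FP), the
F-measure (harmonic mean of Sens and PPV) and the Matthews correlation
coefficient.  0/0 is reported as undefined (None), never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .alignment import CONSENSUS_PAIRS, MultipleAlignment, ReferenceStructure
from .errors import ValidationError

METRIC_NAMES = ("sens", "fpr", "ppv", "f", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def basepair_min_pvalue(predictions) -> dict[tuple[int, int], float]:
    """Map each predicted column pair to the minimum p over its helices."""
    best: dict[tuple[int, int], float] = {}
    for h in predictions:
        if h.p_value is None:
            raise ValidationError("helix without a p-value in predictions")
        for pair in h.column_pairs:
            p = best.get(pair)
            if p is None or h.p_value < p:
                best[pair] = h.p_value
    return best


def classify_basepairs(
    predictions, reference: ReferenceStructure, p_hat: float
) -> ConfusionCounts:
    """Base-pair confusion counts at threshold ``p_hat``.

    The universe is the union of known and predicted pairs.
    """
    min_p = basepair_min_pvalue(predictions)
    known = set(reference.pairs)
    predicted = set(min_p)
    tp = sum(1 for pair in known & predicted if min_p[pair] <= p_hat)
    fp = sum(1 for pair in predicted - known if min_p[pair] <= p_hat)
    tn = sum(1 for pair in predicted - known if min_p[pair] > p_hat)
    fn = len(known) - tp  # insignificant or never predicted
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def helix_matches(helix, reference: ReferenceStructure,
                  match_fraction: float = 0.7) -> bool:
    """True when >= ``match_fraction`` of the helix pairs are known pairs
    (exact column identity; ties at the threshold count as matching)."""
    hits = sum(1 for pair in helix.column_pairs if pair in reference.pairs)
    return hits >= match_fraction * len(helix.column_pairs)


def classify_helices(
    predictions,
    reference: ReferenceStructure,
    p_hat: float,
    match_fraction: float = 0.7,
) -> ConfusionCounts:
    """Helix confusion counts at threshold ``p_hat`` (70% match rule)."""
    tp = fp = tn = fn = 0
    for h in predictions:
        if h.p_value is None:
            raise ValidationError("helix without a p-value in predictions")
        match = helix_matches(h, reference, match_fraction)
        significant = h.p_value <= p_hat
        if match and significant:
            tp += 1
        elif match:
            fn += 1
        elif significant:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sens, FPR, PPV, F-measure and MCC from confusion counts.

    Any 0/0 is reported as ``None`` (undefined), not coerced to 0.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sens = _ratio(tp, tp + fn)
    fpr = _ratio(fp, fp + tn)
    ppv = _ratio(tp, tp + fp)
    if sens is None or ppv is None or sens + ppv == 0:
        f = None
    else:
        f = 2 * sens * ppv / (sens + ppv)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = None if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return {"sens": sens, "fpr": fpr, "ppv": ppv, "f": f, "mcc": mcc}


def threshold_sweep(
    evaluations: list[tuple[list, ReferenceStructure]],
    thresholds: list[float],
    match_fraction: float = 0.7,
) -> pd.DataFrame:
    """Metrics at each p-value threshold, macro-averaged over alignments.

    ``evaluations`` is a list of (predictions, reference) pairs, one per
    alignment.  Undefined per-alignment metrics are excluded from the mean;
    the number of alignments that contributed is reported alongside.
    """
    if sorted(thresholds) != list(thresholds):
        raise ValidationError("thresholds must be sorted ascending")
    rows = []
    for p_hat in thresholds:
        for level, classify in (
            ("basepair", classify_basepairs),
            ("helix", classify_helices),
        ):
            row: dict[str, object] = {"p_hat": p_hat, "level": level}
            for name in METRIC_NAMES:
                values = []
                for predictions, reference in evaluations:
                    if level == "helix":
                        counts = classify(
                            predictions, reference, p_hat, match_fraction
                        )
                    else:
                        counts = classify(predictions, reference, p_hat)
                    value = compute_metrics(counts)[name]
                    if value is not None:
                        values.append(value)
                row[name] = sum(values) / len(values) if values else None
                row[f"n_{name}"] = len(values)
            rows.append(row)
    return pd.DataFrame(rows)


_CODE_PAIR_OK = {(a, b) for a, b in CONSENSUS_PAIRS}


def alignment_quality(
    aln: MultipleAlignment, reference: ReferenceStructure
) -> dict[str, float]:
    """Dataset-quality measures of an alignment against its reference.

    ``canonical_fraction``: of all (row, reference pair) cells in which both
    characters are non-gap nucleotides, the fraction forming a consensus
    pair.  ``covariation``: the fraction of reference pairs at which at
    least two distinct consensus pair types occur across the rows, i.e.
    pairs supported by base-pairing-preserving mutations.
    """
    if not reference.pairs:
        raise ValidationError("alignment_quality needs a non-empty reference")
    codes = aln.codes
    consensus_cells = 0
    total_cells = 0
    covarying = 0
    for i, j in sorted(reference.pairs):
        types = set()
        for r in range(aln.n_rows):
            a, b = int(codes[r, i]), int(codes[r, j])
            if a >= 4 or b >= 4:  # gap or N on either side: excluded
                continue
            total_cells += 1
            if (a, b) in _CODE_PAIR_OK:
                consensus_cells += 1
                types.add((a, b))
        if len(types) >= 2:
            covarying += 1
    canonical_fraction = consensus_cells / total_cells if total_cells else 0.0
    return {
        "canonical_fraction": canonical_fraction,
        "covariation": covarying / len(reference.pairs),
    }


ARC_CLASSES = ((1e-3, "<=1e-3"), (1e-2, "<=1e-2"))


def arc_data(
    predictions, reference: ReferenceStructure, p_hat: float
) -> pd.DataFrame:
    """Arc-diagram table: one row per drawn base pair.

    Known pairs sit above the axis, novel significant predictions below.
    Predicted pairs carry their minimum p-value and a significance class
    (binned at 1e-3, 1e-2 and the threshold); known pairs never predicted
    get the class ``known-only``.  Novel pairs above the threshold are
    excluded.  Columns are 1-based.
    """
    min_p = basepair_min_pvalue(predictions)
    rows = []

    def significance_class(p: float) -> str:
        for cut, label in ARC_CLASSES:
            if p <= cut:
                return label
        return f"<=p_hat({p_hat:g})"

    for pair in sorted(set(reference.pairs) | set(min_p)):
        known = pair in reference.pairs
        p = min_p.get(pair)
        if known:
            cls = "known-only" if p is None or p > p_hat else significance_class(p)
            rows.append(
                {
                    "i": pair[0] + 1,
                    "j": pair[1] + 1,
                    "side": "above",
                    "min_p": p,
                    "class": cls,
                }
            )
        elif p is not None and p <= p_hat:
            rows.append(
                {
                    "i": pair[0] + 1,
                    "j": pair[1] + 1,
                    "side": "below",
                    "min_p": p,
                    "class": significance_class(p),
                }
            )
    return pd.DataFrame(rows, columns=["i", "j", "side", "min_p", "class"])


def arc_data_export(
    predictions,
    reference: ReferenceStructure,
    p_hat: float,
    path: str,
    svg_path: str | None = None,
) -> pd.DataFrame:
    """Write the arc table as TSV; optionally render an SVG arc plot."""
    table = arc_data(predictions, reference, p_hat)
    table.to_csv(path, sep="\t", index=False)
    if svg_path is not None:
        render_arc_plot(table, svg_path)
    return table


def render_arc_plot(table: pd.DataFrame, svg_path: str) -> None:
    """Minimal arc rendering (semicircles above/below the alignment axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Arc

    colors = {
        "<=1e-3": "green",
        "<=1e-2": "blue",
        "known-only": "black",
    }
    fig, ax = plt.subplots(figsize=(10, 4))
    span = 1
    for _, row in table.iterrows():
        i, j = row["i"], row["j"]
        width = j - i
        span = max(span, int(j))
        center = (i + j) / 2
        color = colors.get(row["class"], "orange" if row["class"].startswith("<=") else "red")
        theta = (0, 180) if row["side"] == "above" else (180, 360)
        ax.add_patch(
            Arc((center, 0), width, width / 2, theta1=theta[0], theta2=theta[1],
                color=color, linewidth=0.8)
        )
    ax.set_xlim(0, span + 1)
    ax.set_ylim(-span / 3, span / 3)
    ax.axhline(0, color="grey", linewidth=0.5)
    ax.set_yticks([])
    ax.set_xlabel("alignment column")
    fig.savefig(svg_path, format="svg", bbox_inches="tight")
    plt.close(fig)
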