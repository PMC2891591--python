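"""Confusion-count semantics, metric formulas, sweeps and arc export."""

import numpy as np
import pytest

from transat import (
    ConfusionCounts,
    MultipleAlignment,
    classify_basepairs,
    classify_helices,
    compute_metrics,
    threshold_sweep,
)
from transat.alignment import ReferenceStructure
from transat.errors import ValidationError
from transat.evaluate import (
    alignment_quality,
    arc_data,
    arc_data_export,
    basepair_min_pvalue,
    helix_matches,
)
from transat.helices import ConservedHelix


def helix(pairs, p):
    return ConservedHelix(column_pairs=tuple(pairs), support=1, score=0.0, p_value=p)


class TestMinPvalue:
    def test_single_helix(self):
        best = basepair_min_pvalue([helix([(0, 9), (1, 8)], 0.03)])
        assert best[(0, 9)] == 0.03

    def test_minimum_over_helices(self):
        helices = [helix([(0, 9)], 0.2), helix([(0, 9), (1, 8)], 0.01)]
        # same pair cannot repeat within one helix, but can across helices
        best = basepair_min_pvalue(helices)
        assert best[(0, 9)] == 0.01
        assert best[(1, 8)] == 0.01

    def test_unpredicted_pair_absent(self):
        best = basepair_min_pvalue([helix([(0, 9)], 0.5)])
        assert (3, 6) not in best


class TestClassifyBasepairs:
    def test_perfect_prediction(self):
        ref = ReferenceStructure(frozenset({(0, 9), (1, 8)}))
        counts = classify_basepairs(
            [helix([(0, 9), (1, 8)], 0.01)], ref, p_hat=0.05
        )
        assert (counts.fp, counts.fn) == (0, 0)
        assert counts.tp == 2

    def test_known_never_predicted_is_fn(self):
        ref = ReferenceStructure(frozenset({(0, 9), (2, 7)}))
        counts = classify_basepairs([helix([(0, 9)], 0.01)], ref, p_hat=0.05)
        assert counts.fn == 1 and counts.tp == 1

    def test_toy_set_arithmetic(self):
        # 3 known & significant, 1 significant-only, 1 known-only,
        # 5 predicted-insignificant-unknown
        known = {(0, 50), (1, 49), (2, 48), (30, 40)}
        helices = [
            helix([(0, 50), (1, 49), (2, 48), (3, 47)], 0.01),
            helix([(10, 20), (11, 19), (12, 18), (13, 17), (14, 16)], 0.9),
        ]
        counts = classify_basepairs(
            helices, ReferenceStructure(frozenset(known)), p_hat=0.05
        )
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (3, 1, 1, 5)

    def test_universe_is_known_union_predicted(self):
        ref = ReferenceStructure(frozenset({(0, 9)}))
        helices = [helix([(1, 8), (2, 7)], 0.5)]
        counts = classify_basepairs(helices, ref, p_hat=0.05)
        assert counts.total == 3

    def test_agrees_with_set_arithmetic_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = 50
            all_pairs = [(i, n - i) for i in range(1, 25)]
            known = {p for p in all_pairs if rng.random() < 0.4}
            predicted = {p: float(rng.random()) for p in all_pairs if rng.random() < 0.6}
            p_hat = 0.3
            helices = [helix([p], pv) for p, pv in predicted.items()]
            counts = classify_basepairs(
                helices, ReferenceStructure(frozenset(known)), p_hat
            )
            sig = {p for p, pv in predicted.items() if pv <= p_hat}
            tp = len(known & sig)
            fp = len(sig - known)
            tn = len(set(predicted) - sig - known)
            fn = len(known) - tp
            assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)


class TestClassifyHelices:
    def ref(self):
        return ReferenceStructure(
            frozenset({(i, 100 - i) for i in range(1, 20)})
        )

    def test_seventy_percent_match_is_tp(self):
        pairs = [(i, 100 - i) for i in range(1, 8)] + [(30, 60), (31, 59), (32, 58)]
        counts = classify_helices([helix(pairs, 0.01)], self.ref(), p_hat=0.05)
        assert counts.tp == 1  # 7/10 = 0.7 matches, ties count

    def test_just_below_seventy_percent_is_fp(self):
        pairs = [(i, 100 - i) for i in range(1, 10)] + [
            (30, 60), (31, 59), (32, 58), (33, 57),
        ]
        assert 9 / 13 < 0.7
        counts = classify_helices([helix(pairs, 0.01)], self.ref(), p_hat=0.05)
        assert counts.fp == 1 and counts.tp == 0

    def test_nonmatching_insignificant_is_tn(self):
        pairs = [(30, 60), (31, 59), (32, 58), (33, 57)]
        counts = classify_helices([helix(pairs, 0.9)], self.ref(), p_hat=0.05)
        assert counts.tn == 1

    def test_matching_insignificant_is_fn(self):
        pairs = [(i, 100 - i) for i in range(1, 6)]
        counts = classify_helices([helix(pairs, 0.5)], self.ref(), p_hat=0.05)
        assert counts.fn == 1

    def test_match_fraction_configurable(self):
        pairs = [(1, 99), (30, 60), (31, 59), (32, 58)]
        assert helix_matches(helix(pairs, 0.1), self.ref(), match_fraction=0.25)
        assert not helix_matches(helix(pairs, 0.1), self.ref(), match_fraction=0.3)


class TestComputeMetrics:
    def test_toy_confusion_all_metrics(self):
        m = compute_metrics(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        assert m["sens"] == pytest.approx(0.75)
        assert m["fpr"] == pytest.approx(1 / 6)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["f"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(14 / 24)

    def test_perfect_confusion(self):
        m = compute_metrics(ConfusionCounts(tp=4, fp=0, tn=6, fn=0))
        assert m["sens"] == m["ppv"] == m["f"] == m["mcc"] == 1.0
        assert m["fpr"] == 0.0

    def test_zero_over_zero_is_undefined(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=2))
        assert m["ppv"] is None
        assert m["f"] is None
        assert m["mcc"] is None
        assert m["sens"] == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestThresholdSweep:
    def predictions(self):
        ref = ReferenceStructure(frozenset({(i, 50 - i) for i in range(1, 11)}))
        helices = [
            helix([(i, 50 - i) for i in range(1, 6)], 0.01),
            helix([(i, 50 - i) for i in range(6, 11)], 0.2),
            helix([(20, 30), (21, 29), (22, 28), (23, 27)], 0.04),
        ]
        return helices, ref

    def test_zero_threshold_zero_sensitivity(self):
        helices, ref = self.predictions()
        table = threshold_sweep([(helices, ref)], [0.0])
        assert (table["sens"] == 0).all()

    def test_threshold_one_catches_all_predicted(self):
        helices, ref = self.predictions()
        table = threshold_sweep([(helices, ref)], [1.0])
        bp = table[table.level == "basepair"].iloc[0]
        assert bp["sens"] == pytest.approx(1.0)  # every known pair predicted

    def test_sens_and_fpr_monotone_in_threshold(self):
        helices, ref = self.predictions()
        cuts = [0.0, 0.02, 0.05, 0.3, 1.0]
        table = threshold_sweep([(helices, ref)], cuts)
        for level in ("basepair", "helix"):
            sub = table[table.level == level]
            sens = sub["sens"].tolist()
            assert sens == sorted(sens)
            fpr = [x for x in sub["fpr"] if x is not None]
            assert fpr == sorted(fpr)

    def test_macro_average_excludes_undefined(self):
        helices, ref = self.predictions()
        # second alignment with no significant helix: PPV undefined at 0.02
        other = [helix([(20, 30), (21, 29), (22, 28), (23, 27)], 0.9)]
        ref2 = ReferenceStructure(frozenset({(1, 40)}))
        table = threshold_sweep([(helices, ref), (other, ref2)], [0.02])
        bp = table[table.level == "basepair"].iloc[0]
        assert bp["n_ppv"] == 1  # only the first alignment defines PPV
        assert bp["n_sens"] == 2

    def test_unsorted_thresholds_rejected(self):
        helices, ref = self.predictions()
        with pytest.raises(ValidationError):
            threshold_sweep([(helices, ref)], [0.5, 0.1])


class TestAlignmentQuality:
    def test_all_consensus(self):
        aln = MultipleAlignment(["a", "b"], ["GGCC", "GGCC"])
        ref = ReferenceStructure(frozenset({(0, 3), (1, 2)}))
        q = alignment_quality(aln, ref)
        assert q["canonical_fraction"] == 1.0

    def test_half_consensus(self):
        aln = MultipleAlignment(["a", "b"], ["GC", "GA"])
        ref = ReferenceStructure(frozenset({(0, 1)}))
        q = alignment_quality(aln, ref)
        assert q["canonical_fraction"] == 0.5

    def test_no_covariation_without_compensatory_change(self):
        aln = MultipleAlignment(["a", "b", "c"], ["GC", "GC", "GC"])
        ref = ReferenceStructure(frozenset({(0, 1)}))
        assert alignment_quality(aln, ref)["covariation"] == 0.0

    def test_covariation_counts_two_pair_types(self):
        aln = MultipleAlignment(["a", "b", "c"], ["GCAU", "GCGC", "GCGC"])
        ref = ReferenceStructure(frozenset({(0, 1), (2, 3)}))
        assert alignment_quality(aln, ref)["covariation"] == 0.5

    def test_gapped_cells_excluded(self):
        aln = MultipleAlignment(["a", "b"], ["GC", "-C"])
        ref = ReferenceStructure(frozenset({(0, 1)}))
        assert alignment_quality(aln, ref)["canonical_fraction"] == 1.0

    def test_empty_reference_rejected(self):
        aln = MultipleAlignment(["a", "b"], ["GC", "GC"])
        with pytest.raises(ValidationError):
            alignment_quality(aln, ReferenceStructure(frozenset()))


class TestArcExport:
    def test_known_pair_class_and_side(self):
        ref = ReferenceStructure(frozenset({(0, 9)}))
        table = arc_data([helix([(0, 9)], 5e-4)], ref, p_hat=0.05)
        row = table.iloc[0]
        assert row["side"] == "above" and row["class"] == "<=1e-3"
        assert (row["i"], row["j"]) == (1, 10)

    def test_insignificant_novel_pair_excluded(self):
        ref = ReferenceStructure(frozenset({(0, 9)}))
        table = arc_data([helix([(2, 7)], 0.5)], ref, p_hat=0.05)
        assert not (table["side"] == "below").any()

    def test_known_only_pair_kept(self):
        ref = ReferenceStructure(frozenset({(0, 9)}))
        table = arc_data([helix([(2, 7)], 0.01)], ref, p_hat=0.05)
        above = table[table["side"] == "above"].iloc[0]
        assert above["class"] == "known-only"
        below = table[table["side"] == "below"].iloc[0]
        assert (below["i"], below["j"]) == (3, 8)

    def test_export_writes_tsv_and_svg(self, tmp_path):
        ref = ReferenceStructure(frozenset({(0, 9), (1, 8)}))
        helices = [helix([(0, 9), (1, 8)], 0.004), helix([(3, 6)], 0.02)]
        tsv = tmp_path / "arcs.tsv"
        svg = tmp_path / "arcs.svg"
        table = arc_data_export(helices, ref, 0.05, str(tsv), svg_path=str(svg))
        assert tsv.exists() and svg.exists()
        assert len(table) == 3
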