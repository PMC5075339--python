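"""Metric formulas, the paired t-test, aggregation, and the
leave-one-out protocol's bookkeeping and determinism."""

import numpy as np
import pandas as pd
import pytest

from cmiphmm.evaluation import (ConfusionCounts, PipelineParams,
                                _fold_indices, aggregate_report,
                                compute_metrics, confusion_from_frame,
                                crossval_family, loocv_family,
                                paired_t_test, per_sequence_metrics)
from cmiphmm.msa_io import SiteLabel


class TestComputeMetrics:
    def test_worked_confusion_matrix(self):
        m = compute_metrics(ConfusionCounts(TP=3, TN=5, FP=1, FN=1))
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.accuracy == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.75)
        assert m.mcc == pytest.approx(14 / 24)

    def test_perfect_prediction(self):
        m = compute_metrics(ConfusionCounts(TP=4, TN=6, FP=0, FN=0))
        assert (m.accuracy, m.precision, m.recall, m.f1, m.mcc) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_ratios_become_null_markers(self):
        m = compute_metrics(ConfusionCounts(TP=0, TN=5, FP=0, FN=0))
        assert m.recall is None       # TP+FN = 0
        assert m.precision is None    # TP+FP = 0
        assert m.f1 is None
        assert m.mcc is None
        assert m.accuracy == 1.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_sklearn_on_random_labels(self):
        # independent route: sklearn.metrics on the same vectors
        from sklearn.metrics import (accuracy_score, f1_score,
                                     matthews_corrcoef, precision_score,
                                     recall_score)
        rng = np.random.default_rng(0)
        t = rng.integers(0, 2, size=200)
        p = rng.integers(0, 2, size=200)
        df = pd.DataFrame({"label_true": t, "label_pred": p})
        m = compute_metrics(confusion_from_frame(df))
        assert m.accuracy == pytest.approx(accuracy_score(t, p))
        assert m.precision == pytest.approx(precision_score(t, p))
        assert m.recall == pytest.approx(recall_score(t, p))
        assert m.f1 == pytest.approx(f1_score(t, p))
        assert m.mcc == pytest.approx(matthews_corrcoef(t, p))


class TestPairedT:
    def test_textbook_example(self):
        res = paired_t_test([0.1, 0.2, 0.3], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(0.2 / (0.1 / np.sqrt(3)), rel=1e-6)
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-3)
        assert res.mean_diff == pytest.approx(0.2)

    def test_identical_vectors(self):
        res = paired_t_test([0.4, 0.5], [0.4, 0.5])
        assert res.t == 0.0 and res.p == 1.0 and not res.degenerate

    def test_constant_nonzero_difference_is_degenerate(self):
        res = paired_t_test([1.0, 1.0, 1.0], [0.5, 0.5, 0.5])
        assert res.degenerate and np.isinf(res.t) and res.t > 0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [0.5])


def frame(method, seq, tp, tn, fp, fn):
    rows = []
    for true, pred, n in ((1, 1, tp), (0, 0, tn), (0, 1, fp), (1, 0, fn)):
        rows += [dict(method=method, family_id="f", pair_id=seq,
                      domain_role="A", seq_id=seq, match_index=i,
                      label_true=true, label_pred=pred, score=0.5)
                 for i in range(n)]
    return pd.DataFrame(rows)


class TestAggregation:
    def test_mean_of_per_sequence_metrics(self):
        # MCC 0.4 is not trivially constructible; use two perfect/mixed
        # sequences with known MCCs and check the average
        f1 = frame("m", "s1", 3, 5, 1, 1)     # mcc 14/24
        f2 = frame("m", "s2", 4, 6, 0, 0)     # mcc 1.0
        rep = aggregate_report([pd.concat([f1, f2])], test_pairs=())
        overall = rep.overall.set_index("method")
        assert overall.loc["m", "mcc"] == pytest.approx((14 / 24 + 1) / 2)

    def test_null_markers_excluded_with_count(self):
        f1 = frame("m", "s1", 0, 5, 0, 0)     # recall undefined
        f2 = frame("m", "s2", 4, 4, 0, 0)
        f3 = frame("m", "s3", 2, 2, 1, 1)
        rep = aggregate_report([pd.concat([f1, f2, f3])], test_pairs=())
        assert rep.excluded["m"]["recall"] == 1
        overall = rep.overall.set_index("method")
        assert overall.loc["m", "recall"] == pytest.approx((1.0 + 2 / 3) / 2)

    def test_single_family_mean_equals_overall(self):
        f1 = frame("m", "s1", 3, 5, 1, 1)
        rep = aggregate_report([f1], test_pairs=())
        fam = rep.per_family.set_index("method")
        overall = rep.overall.set_index("method")
        assert fam.loc["m", "mcc"] == overall.loc["m", "mcc"]

    def test_per_sequence_counts_residues(self):
        per_seq = per_sequence_metrics(frame("m", "s1", 3, 5, 1, 1))
        assert per_seq.loc[0, "n_residues"] == 10


class TestProtocol:
    def test_loocv_fold_structure(self):
        folds = _fold_indices(7, "loocv", seed=0)
        assert folds == [[k] for k in range(7)]

    def test_tenfold_requires_ten_pairs(self):
        with pytest.raises(ValueError, match="tenfold"):
            _fold_indices(5, "tenfold", seed=0)
        folds = _fold_indices(12, "tenfold", seed=0)
        assert len(folds) == 10
        assert sorted(i for f in folds for i in f) == list(range(12))

    def test_leakage_guard_row_counts(self, small_family):
        """Dropping the held-out pair removes exactly one row from each
        domain's training alignment."""
        n = len(small_family.pairs)
        for _, sa, sb in small_family.pairs:
            keep_a = [x for _, x, _ in small_family.pairs if x != sa]
            sub = small_family.aln_A.subset(keep_a)
            assert len(sub.rows) == n - 1
            assert sa not in sub.seq_ids
            keep_b = [x for _, _, x in small_family.pairs if x != sb]
            assert len(small_family.aln_B.subset(keep_b).rows) == n - 1

    def test_evaluated_residues_are_non_deleted_match_columns(
            self, small_family, aaindex):
        res = loocv_family(small_family, aaindex,
                           PipelineParams(seed=3), methods=["iphmm"])
        preds = res.predictions
        aln = {"A": small_family.aln_A, "B": small_family.aln_B}
        for (role, sid), grp in preds.groupby(["domain_role", "seq_id"]):
            a = aln[role]
            expected = sum(
                a.site_labels[(sid, c)] is not SiteLabel.GAP
                for c in a.match_columns)
            assert len(grp) == expected

    def test_bitwise_determinism(self, small_family, aaindex):
        p = PipelineParams(seed=11)
        r1 = crossval_family(small_family, aaindex, p)
        r2 = crossval_family(small_family, aaindex, p)
        pd.testing.assert_frame_equal(r1.predictions, r2.predictions)
        for pid in r1.contact_predictions:
            np.testing.assert_array_equal(
                r1.contact_predictions[pid][1].cells,
                r2.contact_predictions[pid][1].cells)

    def test_family_of_one_pair_rejected(self, small_family, aaindex):
        from cmiphmm.evaluation import FamilyData
        pid, sa, sb = small_family.pairs[0]
        tiny = FamilyData(
            aln_A=small_family.aln_A.subset([sa]),
            aln_B=small_family.aln_B.subset([sb]),
            contact_matrices={pid: small_family.contact_matrices[pid]},
            pairs=[small_family.pairs[0]])
        with pytest.raises(ValueError, match="at least 2"):
            crossval_family(tiny, aaindex)

    def test_every_method_covers_every_pair(self, small_family, aaindex):
        res = loocv_family(small_family, aaindex, PipelineParams(seed=3))
        preds = res.predictions
        for method, grp in preds.groupby("method"):
            assert set(grp.pair_id) == set(small_family.pair_ids)
        # metrics computable for the whole frame
        rep = aggregate_report([preds])
        assert set(rep.overall.method) == {"iphmm", "cm_iphmm", "cm_only",
                                           "ground_truth_cm"}
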