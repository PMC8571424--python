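"""Confusion counts, Sn/Sp/Acc/MCC, ROC, and the validation protocols."""

import numpy as np
import pytest

from stressprot import (
    ConfusionMatrix,
    ModelSpec,
    ProtocolSpec,
    confusion,
    extract_feature_matrix,
    metrics,
    roc_points,
    run_protocol,
)
from stressprot.evaluation import round_half_away, stratified_folds
from stressprot.synthetic import generate, strong_signal_spec


class TestConfusion:
    def test_hand_count(self):
        cm = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (1, 1, 1, 1)

    def test_perfect_prediction(self):
        cm = confusion([1, 0, 1], [1, 0, 1])
        assert cm.fn == cm.fp == 0

    def test_total_inversion(self):
        t = np.array([1, 1, 0, 0])
        cm = confusion(t, 1 - t)
        assert cm.tp == cm.tn == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [1, 0])


class TestMetrics:
    def test_perfect_classifier(self):
        r = metrics(ConfusionMatrix(tp=5, fn=0, fp=0, tn=5))
        assert r.acc == 100 and r.mcc == 1

    def test_zero_denominator_convention(self):
        r = metrics(ConfusionMatrix(tp=0, fn=0, fp=0, tn=10))
        assert r.sn == 0 and r.sp == 100 and r.mcc == 0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(0, 0, 0, 0))

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(79.35, 1) == 79.4
        assert round_half_away(0.915, 2) == 0.92
        assert round_half_away(-0.915, 2) == -0.92


class TestRoc:
    def test_perfect_separation(self):
        _, auc = roc_points([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1

    def test_reversal_symmetry(self):
        y = np.array([0, 1, 0, 1, 1, 0, 1])
        s = np.array([0.2, 0.6, 0.4, 0.9, 0.5, 0.55, 0.3])
        _, auc = roc_points(y, s)
        _, auc_rev = roc_points(y, 1 - s)
        assert auc_rev == pytest.approx(1 - auc)

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=2000)
        s = rng.random(2000)
        _, auc = roc_points(y, s)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points([1, 1], [0.2, 0.9])


class TestFolds:
    @pytest.mark.parametrize("n,k", [(10, 5), (30, 5), (47, 10), (20, 2)])
    def test_disjoint_covering_stratified(self, n, k, rng):
        y = rng.permutation(np.arange(n) % 2)
        folds = stratified_folds(y, k, seed=0)
        assert len(folds) == k
        all_idx = np.concatenate(folds)
        assert len(all_idx) == n and len(set(all_idx)) == n  # disjoint cover
        for cls in (0, 1):
            sizes = [int(np.sum(y[f] == cls)) for f in folds]
            assert max(sizes) - min(sizes) <= 1  # stratified within +/-1

    def test_k_exceeding_minority_count_rejected(self):
        y = np.array([1, 1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            stratified_folds(y, 3, seed=0)


@pytest.fixture(scope="module")
def small_dataset():
    seqs, y = generate(strong_signal_spec(n=15, seed=21))
    x, _ = extract_feature_matrix(seqs)
    return x, y


class TestProtocols:
    rf = ModelSpec(kind="random_forest", seed=0)

    def test_self_consistency_separable(self, small_dataset):
        x, y = small_dataset
        rep = run_protocol(x, y, self.rf, ProtocolSpec(kind="self_consistency"))
        assert rep.acc >= 99
        assert rep.protocol == "self_consistency"

    def test_jackknife_iteration_count_and_cells(self, small_dataset):
        x, y = small_dataset
        rep = run_protocol(x, y, self.rf, ProtocolSpec(kind="jackknife"))
        assert rep.cells.total == len(y)  # one pooled cell per sample

    def test_jackknife_row_order_invariance(self, small_dataset):
        x, y = small_dataset
        sub = np.r_[0:8, 15:23]  # balanced 8 + 8 subset
        xs, ys = x[sub], y[sub]
        spec = ModelSpec(kind="random_forest", n_trees=25, seed=0)
        rep = run_protocol(xs, ys, spec, ProtocolSpec(kind="jackknife"))
        perm = np.random.default_rng(4).permutation(len(ys))
        rep_p = run_protocol(xs[perm], ys[perm], spec,
                             ProtocolSpec(kind="jackknife"))
        assert rep.cells == rep_p.cells

    def test_independent_split_sizes(self, small_dataset):
        x, y = small_dataset
        rep = run_protocol(x, y, self.rf,
                           ProtocolSpec(kind="independent_split", seed=1))
        assert rep.cells.total == round(0.30 * len(y))

    def test_k_fold_reports_per_fold(self, small_dataset):
        x, y = small_dataset
        rep = run_protocol(x, y, self.rf, ProtocolSpec(kind="k_fold", k=5, seed=1))
        assert len(rep.per_fold) == 5
        assert rep.k == 5
        assert rep.cells.total == len(y)  # pooled over all folds
        assert rep.acc == pytest.approx(
            np.mean([f["Acc"] for f in rep.per_fold]))

    def test_report_json_round_trip(self, small_dataset, tmp_path):
        import json
        x, y = small_dataset
        rep = run_protocol(x, y, self.rf, ProtocolSpec(kind="k_fold", k=3, seed=2))
        doc = json.loads(rep.to_json(tmp_path / "report.json"))
        assert doc["protocol"] == "k_fold" and len(doc["per_fold"]) == 3
        assert doc["cells"]["TP"] + doc["cells"]["FN"] == int(np.sum(y == 1))

    def test_single_class_dataset_rejected(self, small_dataset):
        x, _ = small_dataset
        with pytest.raises(ValueError):
            run_protocol(x, np.ones(len(x), dtype=int), self.rf,
                         ProtocolSpec(kind="k_fold"))
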