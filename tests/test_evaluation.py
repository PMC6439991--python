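"""Metric formulas, AUPR/AUC, and cross-validation orchestration."""

import math

import numpy as np
import pytest

import pathrx as px
from pathrx.evaluation import ConfusionCounts


class TestConfusionCounts:
    def test_simple_tally(self):
        c = px.confusion_counts([0.9, 0.1], [1, 0], threshold=0.5)
        assert c == ConfusionCounts(TP=1, FP=0, TN=1, FN=0)

    def test_threshold_above_max_predicts_nothing(self):
        c = px.confusion_counts([0.2, 0.6], [1, 0], threshold=0.99)
        assert c.TP == 0 and c.FP == 0
        assert c.FN == 1 and c.TN == 1

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            scores = rng.random(30)
            labels = rng.integers(0, 2, 30)
            thr = float(rng.random())
            c = px.confusion_counts(scores, labels, thr)
            tally = [(s > thr, y) for s, y in zip(scores, labels)]
            assert c.TP == sum(p and y for p, y in tally)
            assert c.FP == sum(p and not y for p, y in tally)
            assert c.TN == sum(not p and not y for p, y in tally)
            assert c.FN == sum(not p and y for p, y in tally)
            assert c.total == 30

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            px.confusion_counts([], [], 0.5)


class TestMetrics:
    def test_symmetric_confusion_matrix_has_zero_mcc(self):
        m = px.metrics(ConfusionCounts(TP=1, FP=1, TN=1, FN=1))
        assert m.MCC == pytest.approx(0.0)

    def test_hand_computed_values(self):
        m = px.metrics(ConfusionCounts(TP=2, FP=1, TN=3, FN=2))
        assert m.PRE == pytest.approx(2 / 3)
        assert m.REC == pytest.approx(1 / 2)
        assert m.ACC == pytest.approx(5 / 8)
        assert m.F1 == pytest.approx(4 / 7)
        assert m.MCC == pytest.approx(4 / math.sqrt(240))

    def test_perfect_classifier_scores_one_everywhere(self):
        m = px.metrics(ConfusionCounts(TP=5, FP=0, TN=7, FN=0))
        assert m == pytest.approx((1.0, 1.0, 1.0, 1.0, 1.0))

    def test_undefined_ratios_are_nan_not_zero(self):
        m = px.metrics(ConfusionCounts(TP=0, FP=0, TN=4, FN=2))
        assert math.isnan(m.PRE)       # no predicted positives
        assert m.REC == 0.0            # positives exist but none found
        assert math.isnan(m.F1)
        assert math.isnan(m.MCC)       # TP+FP = 0 zeroes the denominator
        assert m.ACC == pytest.approx(4 / 6)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            px.metrics(ConfusionCounts(0, 0, 0, 0))


class TestAuprAuc:
    def test_perfect_ranking(self):
        aupr, auc = px.aupr_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert aupr == pytest.approx(1.0)
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_chance_auc(self):
        aupr, auc = px.aupr_auc([0.5] * 6, [0, 1, 0, 1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_auc_equals_pairwise_concordance(self):
        # oracle: fraction of concordant positive-negative pairs, ties = 1/2
        rng = np.random.default_rng(13)
        for _ in range(20):
            scores = np.round(rng.random(12), 1)
            labels = rng.integers(0, 2, 12)
            if labels.sum() in (0, 12):
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            _, auc = px.aupr_auc(scores, labels)
            assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        _, auc1 = px.aupr_auc(scores, labels)
        _, auc2 = px.aupr_auc(np.exp(3 * scores) - 1, labels)
        assert auc1 == pytest.approx(auc2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            px.aupr_auc([0.1, 0.9], [1, 1])


class TestCrossValidate:
    def test_fold_partition_covers_each_pair_once(self, planted_network):
        net, _ = planted_network
        report = px.cross_validate(net, seed=3, n_trees=8)
        sizes = [row["test_pos"] for row in report.fold_sizes]
        assert sum(sizes) == report.config["n_positives"]
        assert max(sizes) - min(sizes) <= 1
        neg_sizes = [row["test_neg"] for row in report.fold_sizes]
        assert sum(neg_sizes) == report.config["n_positives"]
        assert max(neg_sizes) - min(neg_sizes) <= 1

    def test_no_signal_network_scores_at_chance(self):
        net, _ = px.generate_network(
            px.SyntheticConfig(overlap_boost=0.0, base_treat_rate=0.02, seed=5))
        report = px.cross_validate(net, seed=5, n_trees=64)
        assert abs(report.pooled["ensemble"]["AUC"] - 0.5) < 0.1

    def test_metric_ranges_and_threshold_presence(self, planted_network):
        net, _ = planted_network
        report = px.cross_validate(net, seed=7, n_trees=8)
        for name, row in report.pooled.items():
            assert 0.0 <= row["AUPR"] <= 1.0
            assert 0.0 <= row["AUC"] <= 1.0
            # MCC is NaN when the F1-optimal cut predicts a single class
            assert math.isnan(row["MCC"]) or -1.0 <= row["MCC"] <= 1.0
            assert row["F1"] == row["F1"]  # defined on balanced pooled folds

    def test_deterministic_given_seed(self, planted_network):
        net, _ = planted_network
        r1 = px.cross_validate(net, seed=9, n_trees=8)
        r2 = px.cross_validate(net, seed=9, n_trees=8)
        assert r1.to_json() == r2.to_json()

    def test_too_few_positives_rejected(self):
        a_dp = px.InteractionMatrix.from_edges([("d1", "p1"), ("d2", "p2")],
                                               "Drug", "Protein")
        a_sp = px.InteractionMatrix.from_edges([("s1", "p1"), ("s2", "p2")],
                                               "Disease", "Protein")
        a_ds = px.InteractionMatrix.from_edges([("d1", "s1"), ("d2", "s2")],
                                               "Drug", "Disease")
        net = px.build_network(a_dp, a_sp, a_ds)
        with pytest.raises(ValueError, match="at least 5"):
            px.cross_validate(net, seed=1, n_trees=8)

    def test_report_serialises_to_tsv_and_json(self, tmp_path, planted_network):
        net, _ = planted_network
        report = px.cross_validate(net, seed=2, n_trees=8)
        report.to_tsv(tmp_path / "report.tsv")
        report.to_json(tmp_path / "report.json")
        lines = (tmp_path / "report.tsv").read_text().splitlines()
        assert lines[0].startswith("classifier\t")
        assert len(lines) == 7  # five base classifiers + ensemble


def test_f1_at_chosen_threshold_is_maximal():
    """metrics() evaluated at choose_threshold's cut must reproduce the best
    achievable F1 over all cut positions of the score vector."""
    def exhaustive_best_f1(scores, labels):
        uniq = np.unique(scores)
        cuts = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                               [uniq[-1] + 1]])
        best = 0.0
        for c in cuts:
            m = px.metrics(px.confusion_counts(scores, labels, c))
            if m.F1 == m.F1:  # skip undefined
                best = max(best, m.F1)
        return best

    rng = np.random.default_rng(31)
    for _ in range(15):
        scores = np.round(rng.random(25), 1)
        labels = rng.integers(0, 2, 25)
        if labels.sum() in (0, 25):
            labels[0] = 1 - labels[0]
        thr = px.choose_threshold(scores, labels)
        achieved = px.metrics(px.confusion_counts(scores, labels, thr)).F1
        assert achieved == pytest.approx(exhaustive_best_f1(scores, labels))


def test_negative_strategy_comparison(planted_network):
    """Both negative-selection arms run under identical folds, and swapping
    uniformly sampled negatives for filtered ones shifts pooled ensemble
    AUPR only marginally -- the filter changes which pairs are trained on,
    not the bulk of the signal, when protein layers are sparse."""
    net, _ = planted_network
    for seed in (0, 1, 2):
        reduced, _ = px.hide_positives(net, fraction=0.25, seed=seed)
        rel = px.cross_validate(reduced, strategy="reliable", seed=seed,
                                n_trees=48, mask_test_edges=False)
        rnd = px.cross_validate(reduced, strategy="random", seed=seed,
                                n_trees=48, mask_test_edges=False)
        assert rel.config["strategy"] == "reliable"
        assert rnd.config["strategy"] == "random"
        diff = (rel.pooled["ensemble"]["AUPR"]
                - rnd.pooled["ensemble"]["AUPR"])
        assert abs(diff) < 0.08
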