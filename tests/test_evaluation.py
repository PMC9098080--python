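"""Tests for metrics, pooling, detection evaluation, IOR and exemplars."""

import itertools

import numpy as np
import pandas as pd
import pytest

from usvpipe.errors import EmptyInputError, InvalidClassLabelError, ShapeMismatchError
from usvpipe.evaluation import (
    PoolingScheme,
    bootstrap_metric_sd,
    class_exemplars,
    confusion_and_recall,
    detection_eval,
    f1_scores,
    ior,
    macro_f1,
    match_intervals,
    novel_class_distribution,
    pool_labels,
)


class TestConfusion:
    def test_perfect_identity(self):
        y = np.array(["a", "b", "c", "a"])
        cm, norm = confusion_and_recall(y, y, ["a", "b", "c"])
        assert np.array_equal(norm, np.eye(3))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(["a", "b", "c"], 100)
        y_pred = rng.choice(["a", "b", "c"], 100)
        _, norm = confusion_and_recall(y_true, y_pred, ["a", "b", "c"])
        assert np.allclose(norm.sum(axis=1), 1.0, atol=1e-9)

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(1)
        labels = ["x", "y", "z"]
        y_true = rng.choice(labels, 60)
        y_pred = rng.choice(labels, 60)
        cm, _ = confusion_and_recall(y_true, y_pred, labels)
        for i, t in enumerate(labels):
            for j, p in enumerate(labels):
                tally = sum(1 for a, b in zip(y_true, y_pred) if a == t and b == p)
                assert cm.counts[i, j] == tally

    def test_unknown_label_rejected(self):
        with pytest.raises(InvalidClassLabelError):
            confusion_and_recall(["a"], ["q"], ["a", "b"])


class TestF1:
    def test_perfect_all_ones(self):
        y = np.array(["a", "b"] * 5)
        per_class, macro = f1_scores(y, y)
        assert all(v == 1.0 for v in per_class.values())
        assert macro == 1.0

    def test_hand_computed_binary(self):
        # TP=8, FP=2, FN=2 -> F1 = 0.8
        y_true = ["p"] * 10 + ["n"] * 10
        y_pred = ["p"] * 8 + ["n"] * 2 + ["p"] * 2 + ["n"] * 8
        per_class, _ = f1_scores(np.array(y_true), np.array(y_pred))
        assert per_class["p"] == pytest.approx(0.8)

    def test_macro_is_mean_of_classwise(self):
        rng = np.random.default_rng(2)
        y_true = rng.choice(["a", "b", "c"], 90)
        y_pred = rng.choice(["a", "b", "c"], 90)
        per_class, macro = f1_scores(y_true, y_pred)
        assert macro == pytest.approx(np.mean(list(per_class.values())))

    def test_macro_ignores_absent_true_classes(self):
        y_true = np.array(["a", "a", "b", "b"])
        y_pred = np.array(["a", "a", "b", "c"])
        per_class, macro = f1_scores(y_true, y_pred, labels=["a", "b", "c"])
        assert macro == pytest.approx((per_class["a"] + per_class["b"]) / 2)


class TestBootstrapSd:
    def test_constant_metric_zero_sd(self):
        y = np.array(["a"] * 50)
        sd = bootstrap_metric_sd(y, y, macro_f1, b=100, seed=0)
        assert sd == 0.0

    def test_sd_shrinks_with_n(self):
        rng = np.random.default_rng(3)

        def accuracy(t, p):
            return float(np.mean(t == p))

        def make(n):
            t = rng.choice(["a", "b"], n)
            p = t.copy()
            flip = rng.uniform(size=n) < 0.2
            p[flip] = np.where(p[flip] == "a", "b", "a")
            return t, p

        sd1 = bootstrap_metric_sd(*make(200), accuracy, b=400, seed=1)
        sd2 = bootstrap_metric_sd(*make(800), accuracy, b=400, seed=2)
        assert sd2 < sd1
        assert sd2 == pytest.approx(sd1 / 2, rel=0.5)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        t = rng.choice(["a", "b"], 100)
        p = rng.choice(["a", "b"], 100)
        a = bootstrap_metric_sd(t, p, macro_f1, b=50, seed=7)
        b = bootstrap_metric_sd(t, p, macro_f1, b=50, seed=7)
        assert a == b


class TestPooling:
    def test_two_class_everything_usv(self):
        labels = ["up", "d", "c", "c2", "h", "us"]
        pooled = pool_labels(labels, "2")
        assert all(p == "USV" for p in pooled)
        assert pool_labels(["FP"], "2")[0] == "FP"

    def test_six_class_d_to_rise(self):
        assert pool_labels(["d"], "6")[0] == "Rise"
        assert pool_labels(["c3"], "6")[0] == "split"
        assert pool_labels(["h"], "6")[0] == "split"

    def test_identity_noop(self):
        labels = ["c", "up", "FP"]
        assert list(pool_labels(labels, "12")) == labels

    def test_eleven_pools_short(self):
        assert list(pool_labels(["s", "us", "f"], "11")) == ["short", "short", "f"]

    def test_five_and_three(self):
        assert pool_labels(["ui"], "5")[0] == "no-jump"
        assert pool_labels(["c2"], "3")[0] == "jumps and harmonics"

    def test_ev6_maps_novel_classes(self):
        assert pool_labels(["c4", "c5"], "EV6").tolist() == ["split", "split"]
        with pytest.raises(InvalidClassLabelError):
            pool_labels(["c4"], "6")

    def test_fp_always_fp(self):
        for name in ("12", "11", "6", "5", "3", "2", "EV6"):
            assert pool_labels(["FP"], name)[0] == "FP"

    def test_aggregation_consistency(self):
        """F1 of pooled predictions equals F1 from the pooled confusion matrix."""
        rng = np.random.default_rng(5)
        classes = ["FP", "up", "d", "f", "s", "us", "u", "ui", "c", "c2", "c3", "h"]
        y_true = rng.choice(classes, 400)
        y_pred = rng.choice(classes, 400)
        pt, pp = pool_labels(y_true, "2"), pool_labels(y_pred, "2")
        direct = f1_scores(pt, pp, labels=["FP", "USV"])[0]
        cm, _ = confusion_and_recall(pt, pp, ["FP", "USV"])
        # recompute F1 from matrix entries
        for i, label in enumerate(["FP", "USV"]):
            tp = cm.counts[i, i]
            fp = cm.counts[:, i].sum() - tp
            fn = cm.counts[i, :].sum() - tp
            from_matrix = 2 * tp / (2 * tp + fp + fn)
            assert direct[label] == pytest.approx(from_matrix)


def brute_force_max_matching(detected, manual, overlap_frac=0.5):
    """Oracle: exhaustive maximum bipartite matching size (<= 12 intervals)."""
    edges = []
    for i, d in enumerate(detected):
        for j, m in enumerate(manual):
            shorter = min(d[1] - d[0], m[1] - m[0])
            ov = max(0.0, min(d[1], m[1]) - max(d[0], m[0]))
            if shorter > 0 and ov > overlap_frac * shorter:
                edges.append((i, j))
    best = 0
    for r in range(min(len(detected), len(manual)), 0, -1):
        for combo in itertools.combinations(edges, r):
            if (len({e[0] for e in combo}) == r and len({e[1] for e in combo}) == r):
                return r
    return best


class TestDetectionEval:
    def test_identical_sets(self):
        iv = [(0.0, 0.1), (0.2, 0.3)]
        res = detection_eval(iv, iv, b=10)
        assert res.tpr == 100.0 and res.fdr == 0.0

    def test_arithmetic_example(self):
        """95 of 100 manual matched, 120 detections -> TPR 95, FDR 20.83."""
        manual = [(i * 1.0, i * 1.0 + 0.5) for i in range(100)]
        detected = [(i * 1.0, i * 1.0 + 0.5) for i in range(95)]
        detected += [(200.0 + i, 200.0 + i + 0.3) for i in range(25)]
        res = detection_eval(detected, manual, b=10)
        assert res.tpr == pytest.approx(95.0)
        assert res.fdr == pytest.approx(100 * 25 / 120, abs=0.01)

    def test_greedy_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(6)
        for trial in range(30):
            n_m = rng.integers(1, 7)
            n_d = rng.integers(1, 7)
            starts = np.cumsum(rng.uniform(0.05, 0.2, n_m))
            manual = [(s, s + rng.uniform(0.02, 0.08)) for s in starts]
            detected = []
            for _ in range(n_d):
                s = rng.uniform(0, starts[-1] + 0.2)
                detected.append((s, s + rng.uniform(0.02, 0.08)))
            greedy = len(match_intervals(detected, manual))
            oracle = brute_force_max_matching(detected, manual)
            assert greedy == oracle

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        starts = np.cumsum(rng.uniform(0.05, 0.2, 10))
        manual = [(s, s + 0.04) for s in starts]
        detected = [(s + 0.005, s + 0.05) for s in starts[:8]]
        r1 = detection_eval(detected, manual, b=10, seed=0)
        shift = 123.456
        r2 = detection_eval([(a + shift, b + shift) for a, b in detected],
                            [(a + shift, b + shift) for a, b in manual],
                            b=10, seed=0)
        assert r1.tpr == r2.tpr and r1.fdr == r2.fdr


class TestIor:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["start_s", "label"])

    def test_identical_tables_100(self):
        t = self.table([(0.1, "up"), (0.5, "d"), (0.9, "FP")])
        res = ior(t, t)
        assert res.ior_incl_missed == 100.0
        assert res.ior_excl_missed == 100.0

    def test_arithmetic_example(self):
        """8 agree, 1 disagree, 1 missed -> incl 80.0%, excl 88.89%."""
        rows_a = [(i * 1.0, "up") for i in range(9)] + [(9.0, "d")]
        rows_b = [(i * 1.0, "up") for i in range(8)] + [(8.0, "c")]
        res = ior(self.table(rows_a), self.table(rows_b))
        assert res.n_compared == 9
        assert res.n_agree == 8
        assert res.n_missed == 1
        assert res.ior_incl_missed == pytest.approx(80.0)
        assert res.ior_excl_missed == pytest.approx(100 * 8 / 9, abs=0.01)

    def test_uc_rows_excluded(self):
        rows_a = [(0.0, "up"), (1.0, "uc"), (2.0, "d")]
        rows_b = [(0.0, "up"), (1.0, "uc"), (2.0, "d")]
        res = ior(self.table(rows_a), self.table(rows_b))
        res_clean = ior(self.table([(0.0, "up"), (2.0, "d")]),
                        self.table([(0.0, "up"), (2.0, "d")]))
        assert res.n_uc_excluded == 2
        assert res.n_compared == res_clean.n_compared
        assert res.ior_excl_missed == res_clean.ior_excl_missed

    def test_pooling_applied_before_comparison(self):
        rows_a = [(0.0, "s")]
        rows_b = [(0.0, "us")]
        assert ior(self.table(rows_a), self.table(rows_b)).n_agree == 0
        assert ior(self.table(rows_a), self.table(rows_b), scheme="11").n_agree == 1

    def test_incl_never_exceeds_excl(self):
        rng = np.random.default_rng(8)
        for trial in range(10):
            n = rng.integers(3, 12)
            rows_a = [(i + rng.uniform(0, 0.002), str(rng.choice(["up", "d", "FP"])))
                      for i in range(n)]
            rows_b = [(i + rng.uniform(0, 0.002), str(rng.choice(["up", "d", "FP"])))
                      for i in range(int(n - rng.integers(0, 2)))]
            res = ior(self.table(rows_a), self.table(rows_b))
            assert res.ior_incl_missed <= res.ior_excl_missed + 1e-9


class TestExemplars:
    def test_singleton_class(self):
        x = np.random.default_rng(9).uniform(size=(3, 4, 4))
        out = class_exemplars(x, ["a", "b", "b"], k=5)
        assert out["a"] == [0]

    def test_k_at_least_class_size_returns_all(self):
        x = np.random.default_rng(10).uniform(size=(4, 2, 2))
        out = class_exemplars(x, ["a"] * 4, k=10)
        assert sorted(out["a"]) == [0, 1, 2, 3]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(size=(10, 3, 3))
        labels = ["a"] * 10
        out = class_exemplars(x, labels, k=3)
        flat = x.reshape(10, -1)
        totals = [sum(np.abs(flat[i] - flat[j]).sum() for j in range(10) if j != i)
                  for i in range(10)]
        # include self-distance (0): same ordering as implementation
        expect = list(np.argsort(totals, kind="stable")[:3])
        assert out["a"] == expect


class TestNovelClassDistribution:
    def test_all_one_class(self):
        out = novel_class_distribution(["c4"] * 5, ["c2"] * 5)
        assert out == {"c2": 1.0}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(12)
        preds = rng.choice(["c2", "c3", "ui"], 40)
        out = novel_class_distribution(["c4"] * 40, preds)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-9)

    def test_counting_example(self):
        preds = ["c2"] * 17 + ["c3"] * 8
        out = novel_class_distribution(["c4"] * 25, preds)
        assert out["c2"] == pytest.approx(0.68)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            novel_class_distribution([], [])
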