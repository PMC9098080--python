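"""Tests for resampling, snapshot combination and the bagged predictor."""

import numpy as np
import pytest

from usvpipe.ensemble import (
    BaggedEnsemble,
    bootstrap_datasets,
    bootstrap_indices,
    bootsnap_predict,
    combine_predictions,
    fit_stacker,
    mode_across_folds,
    oversample_smoteenn,
    train_bagged_ensemble,
    undersample,
)
from usvpipe.errors import ConfigError, EmptyInputError, UntrainedModelError
from usvpipe.model import ClassifierConfig, train_snapshots


def _labelled(counts: dict, dim: int = 6, seed: int = 0):
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for label, n in counts.items():
        center = rng.normal(size=dim) * 5
        xs.append(center + rng.normal(size=(n, dim)))
        ys.extend([label] * n)
    return np.concatenate(xs), np.asarray(ys, dtype=object)


class TestBootstrap:
    def test_replicate_count_and_size(self):
        x, y = _labelled({"a": 30, "b": 20})
        reps = bootstrap_datasets((x, y), b=10, seed=0)
        assert len(reps) == 10
        for xr, yr in reps:
            assert len(xr) == 50 and len(yr) == 50

    def test_unique_fraction_632(self):
        """Expected unique-sample fraction per replicate ~ 1 - 1/e."""
        fracs = [len(np.unique(idx)) / 1000
                 for idx in bootstrap_indices(1000, 100, seed=1)]
        assert abs(np.mean(fracs) - 0.632) < 0.02

    def test_different_seeds_differ(self):
        a = bootstrap_indices(100, 1, seed=1)[0]
        b = bootstrap_indices(100, 1, seed=2)[0]
        assert not np.array_equal(a, b)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            bootstrap_datasets((np.empty((0, 2)), np.empty(0)), b=2, seed=0)

    def test_class_proportions_preserved_in_expectation(self):
        x, y = _labelled({"a": 700, "b": 300})
        reps = bootstrap_datasets((x, y), b=50, seed=3)
        frac_a = np.mean([np.mean(yr == "a") for _, yr in reps])
        assert abs(frac_a - 0.7) < 0.02


class TestUndersample:
    def test_large_class_capped(self):
        x, y = _labelled({"up": 4343, "c3": 69})
        xr, yr = undersample((x, y), cap=124)
        assert np.sum(yr == "up") == 124
        assert np.sum(yr == "c3") == 69  # exempt class untouched

    def test_exempt_classes_unchanged(self):
        x, y = _labelled({"c3": 69, "us": 74, "d": 300})
        xr, yr = undersample((x, y))
        assert np.sum(yr == "c3") == 69
        assert np.sum(yr == "us") == 74
        assert np.sum(yr == "d") == 124

    def test_total_counting_oracle(self):
        counts = {"a": 500, "b": 80, "c3": 200, "us": 10}
        x, y = _labelled(counts)
        _, yr = undersample((x, y), cap=124)
        expected = sum(c if lbl in ("c3", "us") else min(c, 124)
                       for lbl, c in counts.items())
        assert len(yr) == expected


class TestSmoteenn:
    def test_exempt_pass_through(self):
        x, y = _labelled({"FP": 50, "up": 40, "d": 10}, seed=2)
        xr, yr = oversample_smoteenn((x, y), seed=0)
        assert np.sum(yr == "FP") == 50
        assert np.sum(yr == "up") == 40

    def test_synthetic_on_neighbor_segments(self):
        """Every synthetic vector lies between a seed and a same-class
        neighbour (convexity oracle on a well-separated toy set)."""
        x, y = _labelled({"FP": 40, "d": 8}, dim=2, seed=3)
        xr, yr = oversample_smoteenn((x, y), k_neighbors=3, target=20, seed=1)
        originals = x[y == "d"]
        new = [v for v, lbl in zip(xr, yr) if lbl == "d"
               and not any(np.allclose(v, o) for o in originals)]
        for v in new:
            on_segment = False
            for i in range(len(originals)):
                for j in range(len(originals)):
                    if i == j:
                        continue
                    a, b = originals[i], originals[j]
                    t = np.dot(v - a, b - a) / max(np.dot(b - a, b - a), 1e-12)
                    if 0 <= t <= 1 and np.allclose(a + t * (b - a), v, atol=1e-5):
                        on_segment = True
            assert on_segment

    def test_post_cleaning_counts_bounded(self):
        x, y = _labelled({"FP": 60, "d": 10, "u": 12}, seed=4)
        xr, yr = oversample_smoteenn((x, y), target=30, seed=2)
        assert np.sum(yr == "d") <= 30
        assert np.sum(yr == "u") <= 30

    def test_tiny_class_rejected(self):
        x, y = _labelled({"FP": 30, "d": 3}, seed=5)
        with pytest.raises(ValueError):
            oversample_smoteenn((x, y), k_neighbors=3)


@pytest.fixture(scope="module")
def toy_snapshots():
    rng = np.random.default_rng(0)
    xs, ys = [], []
    for label in (0, 1):
        for _ in range(25):
            img = rng.uniform(0, 0.05, size=(64, 401)).astype(np.float32)
            rows = slice(10, 20) if label == 0 else slice(40, 50)
            img[rows, 50:150] += 0.9
            xs.append(img)
            ys.append(label)
    x = np.stack(xs)
    y = np.asarray(ys)
    config = ClassifierConfig(n_conv_layers=3, filters_per_layer=(16, 16, 16),
                              dense_size=32, first_stride=(2, 4), cycle_len=2,
                              n_cycles=5, n_classes=2, batch_size=16,
                              lr_max=3e-3, seed=0, augment=False)
    return train_snapshots((x, y), None, config), x, y


class TestCombinePredictions:
    def test_mode_sn_is_last_checkpoint(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        assert np.allclose(combine_predictions(ss, x[:5], "sn"),
                           ss.predict_proba(x[:5], checkpoint=-1))

    def test_avg3_of_identical_checkpoints(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        import copy

        clone = copy.deepcopy(ss)
        clone.checkpoints = [clone.checkpoints[-1]] * 5
        assert np.allclose(combine_predictions(clone, x[:5], "sn_avg_3"),
                           clone.predict_proba(x[:5], checkpoint=-1), atol=1e-6)

    def test_xgb_requires_stacker(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        with pytest.raises(UntrainedModelError):
            combine_predictions(ss, x[:5], "sn_xgb3")

    def test_stacker_reproduces_majority_on_toy(self, toy_snapshots):
        ss, x, y = toy_snapshots
        stacker = fit_stacker(ss, x, y, last_k=3, seed=0)
        probs = combine_predictions(ss, x, "sn_xgb3", stacker=stacker)
        assert (probs.argmax(1) == y).mean() >= 0.95

    def test_invalid_mode(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        with pytest.raises(ConfigError):
            combine_predictions(ss, x[:2], "vote")


class TestBootsnapPredict:
    def test_single_member_degenerate(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        bag = BaggedEnsemble(members=[ss])
        labels, probs = bootsnap_predict(bag, x[:5])
        assert np.allclose(probs, combine_predictions(ss, x[:5], "sn"))

    def test_member_permutation_invariant(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        import copy

        ss2 = copy.deepcopy(ss)
        ss2.checkpoints = ss.checkpoints[::-1]
        b1 = BaggedEnsemble(members=[ss, ss2])
        b2 = BaggedEnsemble(members=[ss2, ss])
        _, p1 = bootsnap_predict(b1, x[:5])
        _, p2 = bootsnap_predict(b2, x[:5])
        assert np.allclose(p1, p2)

    def test_probabilities_valid(self, toy_snapshots):
        ss, x, _ = toy_snapshots
        _, probs = bootsnap_predict(BaggedEnsemble(members=[ss, ss]), x[:8])
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_empty_bag_rejected(self):
        with pytest.raises(EmptyInputError):
            bootsnap_predict(BaggedEnsemble(members=[]), np.zeros((1, 64, 401)))


class TestModeAcrossFolds:
    def test_unanimous(self):
        preds = np.zeros((8, 4), dtype=int)
        assert np.array_equal(mode_across_folds(preds), np.zeros(4, dtype=int))

    def test_majority(self):
        preds = np.array([[1]] * 5 + [[2]] * 3).reshape(8, 1)
        assert mode_across_folds(preds)[0] == 1

    def test_tie_broken_by_mean_probability(self):
        preds = np.array([[0]] * 4 + [[1]] * 4).reshape(8, 1)
        probs = np.zeros((8, 1, 2))
        probs[:, 0, 0] = 0.6
        probs[:, 0, 1] = 0.4
        assert mode_across_folds(preds, probs)[0] == 0
        probs[:, 0, 0] = 0.3
        probs[:, 0, 1] = 0.7
        assert mode_across_folds(preds, probs)[0] == 1

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        preds = rng.integers(0, 3, size=(8, 50))
        probs = rng.dirichlet(np.ones(3), size=(8, 50))
        got = mode_across_folds(preds, probs)
        for i in range(50):
            counts = {}
            for f in range(8):
                counts[preds[f, i]] = counts.get(preds[f, i], 0) + 1
            best = max(counts.values())
            tied = [l for l, c in counts.items() if c == best]
            expect = max(tied, key=lambda l: probs[:, i, l].mean())
            assert got[i] == expect


def test_train_bagged_ensemble_smoke(toy_snapshots):
    _, x, y = toy_snapshots
    config = ClassifierConfig(n_conv_layers=3, filters_per_layer=(16, 16, 16),
                              dense_size=32, first_stride=(2, 4), cycle_len=2,
                              n_cycles=1, n_classes=2, batch_size=16,
                              lr_max=3e-3, seed=1, augment=False)
    bag = train_bagged_ensemble((x, y), None, config, b=2, seed=0)
    labels, probs = bootsnap_predict(bag, x)
    assert probs.shape == (len(x), 2)
    assert (labels == y).mean() > 0.9
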