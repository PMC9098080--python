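"""Resampling strategies, snapshot combination and the bagged predictor.

The headline predictor trains one snapshot set per bootstrap replicate
(default B = 10) and averages the last-snapshot probabilities across the
bag.  Alternative combiners use the mean of the last three snapshots or a
gradient-boosted stacker over the concatenated snapshot probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.neighbors import NearestNeighbors

from usvpipe.errors import (
    ConfigError,
    EmptyInputError,
    ShapeMismatchError,
    UntrainedModelError,
)
from usvpipe.model import ClassifierConfig, SnapshotSet, class_weights, train_snapshots

COMBINATION_MODES = ("sn", "sn_avg_3", "sn_xgb3", "sn_xgb5")


def bootstrap_indices(n: int, b: int, seed: int) -> list[np.ndarray]:
    """``b`` with-replacement index resamples of size ``n``, seeded."""
    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2 ** 31, size=b)
    return [np.random.default_rng(int(s)).integers(0, n, size=n) for s in seeds]


def balanced_bootstrap_indices(labels: np.ndarray, b: int, seed: int) -> list[np.ndarray]:
    """Class-balanced bootstrap: equal draws per class, total size preserved."""
    labels = np.asarray(labels)
    n = len(labels)
    classes = np.unique(labels)
    per_class = [np.flatnonzero(labels == c) for c in classes]
    master = np.random.default_rng(seed)
    out = []
    quota = np.full(len(classes), n // len(classes))
    quota[: n - quota.sum()] += 1
    for _ in range(b):
        rng = np.random.default_rng(int(master.integers(0, 2 ** 31)))
        idx = np.concatenate([
            pool[rng.integers(0, len(pool), size=q)]
            for pool, q in zip(per_class, quota)
        ])
        out.append(rng.permutation(idx))
    return out


def bootstrap_datasets(train_set, b: int, seed: int,
                       balanced: bool = False) -> list[tuple]:
    """``b`` with-replacement replicates of ``(x, y)``, each of original size."""
    x, y = train_set
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) == 0:
        raise EmptyInputError("empty training set")
    if b < 1:
        raise ValueError("b must be >= 1")
    if balanced:
        index_sets = balanced_bootstrap_indices(y, b, seed)
    else:
        index_sets = bootstrap_indices(len(x), b, seed)
    return [(x[idx], y[idx]) for idx in index_sets]


def undersample(train_set, cap: int = 124, exempt=("c3", "us"),
                seed: int = 0) -> tuple:
    """Reduce every non-exempt class to at most ``cap`` samples."""
    if cap <= 0:
        raise ValueError("cap must be positive")
    x, y = train_set
    x = np.asarray(x)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    keep = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if c not in exempt and len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(np.sort(idx))
    keep = np.concatenate(keep)
    keep.sort()
    return x[keep], y[keep]


def oversample_smoteenn(train_set, k_neighbors: int = 3, target: int | None = None,
                        exempt=("FP", "up"), seed: int = 0) -> tuple:
    """SMOTE oversampling toward the majority count, then ENN cleaning.

    Synthetic samples are convex combinations of a seed sample and one of its
    ``k_neighbors`` nearest same-class neighbors on flattened vectors.
    Edited-nearest-neighbour cleaning then removes non-exempt samples whose
    3 nearest neighbours disagree with their label.  Exempt classes pass
    through untouched.
    """
    x, y = train_set
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y)
    flat = x.reshape(len(x), -1)
    classes, counts = np.unique(y, return_counts=True)
    if target is None:
        target = int(counts.max())
    rng = np.random.default_rng(seed)
    new_x = [x]
    new_y = [y]
    for c in classes:
        if c in exempt:
            continue
        idx = np.flatnonzero(y == c)
        if len(idx) <= k_neighbors:
            raise ValueError(
                f"class {c!r} has {len(idx)} samples, need > {k_neighbors} for SMOTE")
        n_new = target - len(idx)
        if n_new <= 0:
            continue
        nn_model = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(flat[idx])
        _, nbrs = nn_model.kneighbors(flat[idx])
        seeds = rng.integers(0, len(idx), size=n_new)
        picks = rng.integers(1, k_neighbors + 1, size=n_new)
        lams = rng.uniform(0.0, 1.0, size=n_new).astype(np.float32)
        a = flat[idx[seeds]]
        bvec = flat[idx[nbrs[seeds, picks]]]
        synth = a + lams[:, None] * (bvec - a)
        new_x.append(synth.reshape((n_new,) + x.shape[1:]))
        new_y.append(np.full(n_new, c, dtype=y.dtype))
    x_all = np.concatenate(new_x)
    y_all = np.concatenate(new_y)
    # ENN cleaning on the augmented set
    flat_all = x_all.reshape(len(x_all), -1)
    nn_all = NearestNeighbors(n_neighbors=4).fit(flat_all)
    _, nbrs = nn_all.kneighbors(flat_all)
    keep = np.ones(len(x_all), dtype=bool)
    for i in range(len(x_all)):
        if y_all[i] in exempt:
            continue
        votes = y_all[nbrs[i, 1:]]
        if np.sum(votes == y_all[i]) < 2:  # majority of 3 neighbours disagrees
            keep[i] = False
    return x_all[keep], y_all[keep]


def fit_stacker(snapshots: SnapshotSet, x_val: np.ndarray, y_val: np.ndarray,
                last_k: int, seed: int = 0) -> HistGradientBoostingClassifier:
    """Train the gradient-boosted stacker on validation-set snapshot outputs."""
    feats = np.concatenate(
        [snapshots.predict_proba(x_val, checkpoint=-(i + 1)) for i in range(last_k)],
        axis=1)
    stacker = HistGradientBoostingClassifier(
        max_iter=100, max_depth=3, learning_rate=0.1, random_state=seed)
    stacker.fit(feats, np.asarray(y_val))
    return stacker


def combine_predictions(snapshots: SnapshotSet, x: np.ndarray, mode: str = "sn",
                        stacker=None) -> np.ndarray:
    """Probability matrix from one snapshot set under a combination mode."""
    if mode not in COMBINATION_MODES:
        raise ConfigError(f"mode must be one of {COMBINATION_MODES}")
    if mode == "sn":
        return snapshots.predict_proba(x, checkpoint=-1)
    if mode == "sn_avg_3":
        probs = [snapshots.predict_proba(x, checkpoint=-(i + 1)) for i in range(3)]
        return np.mean(probs, axis=0)
    last_k = 3 if mode == "sn_xgb3" else 5
    if stacker is None:
        raise UntrainedModelError(f"mode {mode!r} requires a trained stacker")
    feats = np.concatenate(
        [snapshots.predict_proba(x, checkpoint=-(i + 1)) for i in range(last_k)],
        axis=1)
    raw = stacker.predict_proba(feats)
    n_classes = snapshots.config.n_classes
    out = np.zeros((len(x), n_classes))
    for j, c in enumerate(stacker.classes_):
        out[:, int(c)] = raw[:, j]
    row_sums = out.sum(axis=1, keepdims=True)
    return out / np.maximum(row_sums, 1e-12)


@dataclass
class BaggedEnsemble:
    """B snapshot sets trained on bootstrap replicates, plus a combiner mode."""

    members: list[SnapshotSet]
    mode: str = "sn"
    stackers: list | None = None
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.mode not in COMBINATION_MODES:
            raise ConfigError(f"mode must be one of {COMBINATION_MODES}")
        if self.mode in ("sn_xgb3", "sn_xgb5") and not self.stackers:
            raise UntrainedModelError("xgb modes require per-member stackers")
        if self.class_names is None and self.members:
            self.class_names = self.members[0].class_names

    @property
    def b(self) -> int:
        return len(self.members)


def bootsnap_predict(bag: BaggedEnsemble, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average member probabilities; label = argmax of the bag mean."""
    if not bag.members:
        raise EmptyInputError("empty ensemble bag")
    acc = None
    for i, member in enumerate(bag.members):
        stacker = bag.stackers[i] if bag.stackers else None
        probs = combine_predictions(member, x, mode=bag.mode, stacker=stacker)
        acc = probs if acc is None else acc + probs
    mean_probs = acc / bag.b
    return mean_probs.argmax(axis=1), mean_probs


def train_bagged_ensemble(train_set, val_set, config: ClassifierConfig,
                          b: int = 10, seed: int = 0, mode: str = "sn",
                          balanced: bool = False,
                          class_names: list[str] | None = None,
                          reweight_per_replicate: bool = True,
                          verbose: bool = False) -> BaggedEnsemble:
    """Train ``b`` snapshot sets on bootstrap replicates of ``train_set``.

    Class weights are recomputed on each replicate (classes absent from a
    replicate get weight zero).  Stackers for the xgb modes are fitted on
    the validation set per member.
    """
    x, y = train_set
    x = np.asarray(x)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise EmptyInputError("empty training set")
    if balanced:
        index_sets = balanced_bootstrap_indices(y, b, seed)
    else:
        index_sets = bootstrap_indices(len(x), b, seed)
    members = []
    stackers = [] if mode in ("sn_xgb3", "sn_xgb5") else None
    for i, idx in enumerate(index_sets):
        xb, yb = x[idx], y[idx]
        cw = np.zeros(config.n_classes, dtype=np.float32)
        present, counts = np.unique(yb, return_counts=True)
        if reweight_per_replicate:
            cw[present] = class_weights(counts)
        else:
            cw[:] = 1.0
        member_config = ClassifierConfig(**{**_config_dict(config),
                                            "seed": config.seed + 1000 * (i + 1)})
        member = train_snapshots((xb, yb), val_set, member_config, weights=cw,
                                 class_names=class_names, verbose=verbose)
        members.append(member)
        if stackers is not None:
            last_k = 3 if mode == "sn_xgb3" else 5
            stackers.append(fit_stacker(member, np.asarray(val_set[0]),
                                        np.asarray(val_set[1]), last_k,
                                        seed=seed + i))
    return BaggedEnsemble(members=members, mode=mode, stackers=stackers,
                          class_names=class_names)


def _config_dict(config: ClassifierConfig) -> dict:
    from dataclasses import asdict

    return asdict(config)


def mode_across_folds(fold_predictions: np.ndarray,
                      fold_probabilities: np.ndarray | None = None) -> np.ndarray:
    """Per-element majority label across folds; ties broken by mean probability."""
    preds = np.asarray(fold_predictions)
    if preds.ndim != 2:
        raise ShapeMismatchError("fold_predictions must be (n_folds, n_elements)")
    n_folds, n = preds.shape
    if fold_probabilities is not None:
        fold_probabilities = np.asarray(fold_probabilities)
        if fold_probabilities.shape[:2] != (n_folds, n):
            raise ShapeMismatchError("fold_probabilities shape mismatch")
    out = np.empty(n, dtype=preds.dtype)
    for i in range(n):
        labels, counts = np.unique(preds[:, i], return_counts=True)
        best = labels[counts == counts.max()]
        if len(best) == 1 or fold_probabilities is None:
            out[i] = best[0]
        else:
            mean_p = [float(fold_probabilities[:, i, int(l)].mean()) for l in best]
            out[i] = best[int(np.argmax(mean_p))]
    return out
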