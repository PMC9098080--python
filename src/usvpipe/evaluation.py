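"""Evaluation: confusion matrices, F1 with bootstrap variance, class pooling,
detection TPR/FDR, inter-observer reliability and exemplar selection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from usvpipe.errors import (
    ConfigError,
    EmptyInputError,
    InvalidClassLabelError,
    ShapeMismatchError,
)

# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

_RISE = ("up", "d", "f", "s", "us", "u")
_TWELVE = ("FP", "up", "d", "f", "s", "us", "u", "ui", "c", "c2", "c3", "h")


def _build_scheme(name: str) -> dict:
    if name == "12":
        return {c: c for c in _TWELVE + ("c4", "c5")}
    if name == "11":
        m = {c: c for c in _TWELVE + ("c4", "c5")}
        m["s"] = m["us"] = "short"
        return m
    if name in ("6", "EV6"):
        m = {"FP": "FP", "ui": "ui", "c": "c", "c2": "c2",
             "c3": "split", "h": "split"}
        m.update({c: "Rise" for c in _RISE})
        if name == "EV6":
            m["c4"] = m["c5"] = "split"
        return m
    if name == "5":
        m = {"FP": "FP", "c2": "c2", "c3": "c3", "h": "h"}
        m.update({c: "no-jump" for c in _RISE + ("ui", "c")})
        return m
    if name == "3":
        m = {"FP": "FP"}
        m.update({c: "no-jump" for c in _RISE + ("ui", "c")})
        m.update({c: "jumps and harmonics" for c in ("c2", "c3", "h", "c4", "c5")})
        return m
    if name == "2":
        return {c: ("FP" if c == "FP" else "USV")
                for c in _TWELVE + ("c4", "c5")}
    raise ConfigError(f"unknown pooling scheme {name!r}")


@dataclass(frozen=True)
class PoolingScheme:
    """Many-to-one label merge applied before scoring; FP always maps to FP."""

    name: str
    mapping: dict

    @staticmethod
    def builtin(name: str) -> "PoolingScheme":
        return PoolingScheme(name=name, mapping=_build_scheme(name))

    @property
    def pooled_labels(self) -> list[str]:
        seen = []
        for v in self.mapping.values():
            if v not in seen:
                seen.append(v)
        return seen


def pool_labels(labels, scheme: PoolingScheme | str):
    """Map every label through the pooling scheme; unmapped labels are errors."""
    if isinstance(scheme, str):
        scheme = PoolingScheme.builtin(scheme)
    out = []
    for label in labels:
        if label not in scheme.mapping:
            raise InvalidClassLabelError(
                f"label {label!r} is not covered by scheme {scheme.name!r}")
        out.append(scheme.mapping[label])
    return np.asarray(out, dtype=object)


# ---------------------------------------------------------------------------
# confusion / F1
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    labels: list

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        out = np.zeros_like(self.counts, dtype=float)
        nz = sums[:, 0] > 0
        out[nz] = self.counts[nz] / sums[nz]
        return out


def confusion_and_recall(y_true, y_pred, labels) -> tuple[ConfusionMatrix, np.ndarray]:
    """Count matrix indexed (true, predicted) plus its row-normalized form."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ShapeMismatchError("y_true and y_pred lengths differ")
    index = {l: i for i, l in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise InvalidClassLabelError(f"label {t if t not in index else p!r} "
                                         "not in the provided label list")
        counts[index[t], index[p]] += 1
    cm = ConfusionMatrix(counts=counts, labels=list(labels))
    return cm, cm.row_normalized()


def f1_scores(y_true, y_pred, labels=None) -> tuple[dict, float]:
    """Class-wise F1 and macro F1 over classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ShapeMismatchError("y_true and y_pred lengths differ")
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred), key=str)
    per_class = {}
    macro_terms = []
    for label in labels:
        tp = int(np.sum((y_true == label) & (y_pred == label)))
        fp = int(np.sum((y_true != label) & (y_pred == label)))
        fn = int(np.sum((y_true == label) & (y_pred != label)))
        denom = 2 * tp + fp + fn
        f1 = 2 * tp / denom if denom > 0 else 0.0
        per_class[label] = f1
        if np.any(y_true == label):
            macro_terms.append(f1)
    macro = float(np.mean(macro_terms)) if macro_terms else 0.0
    return per_class, macro


def macro_f1(y_true, y_pred, labels=None) -> float:
    return f1_scores(y_true, y_pred, labels)[1]


def bootstrap_metric_sd(y_true, y_pred, metric, b: int = 1000,
                        seed: int = 0) -> float:
    """SD of ``metric(y_true, y_pred)`` over ``b`` index resamples."""
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    values = np.empty(b)
    for i in range(b):
        idx = rng.integers(0, n, size=n)
        values[i] = metric(y_true[idx], y_pred[idx])
    return float(np.std(values, ddof=1))


# ---------------------------------------------------------------------------
# detection evaluation
# ---------------------------------------------------------------------------

@dataclass
class DetectionEvalResult:
    tpr: float
    fdr: float
    tpr_sd: float
    fdr_sd: float
    n_manual: int
    n_detected: int
    n_matched: int
    n_false: int


def _overlap(a: tuple, b: tuple) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def match_intervals(detected, manual, overlap_frac: float = 0.5) -> list[tuple[int, int]]:
    """Greedy one-to-one matching in start-time order.

    A detection matches a manual interval when their overlap exceeds
    ``overlap_frac`` of the shorter interval's length.
    """
    det_order = np.argsort([d[0] for d in detected]) if len(detected) else []
    man_order = np.argsort([m[0] for m in manual]) if len(manual) else []
    used = np.zeros(len(manual), dtype=bool)
    pairs = []
    for di in det_order:
        d = detected[di]
        for mi in man_order:
            if used[mi]:
                continue
            m = manual[mi]
            shorter = min(d[1] - d[0], m[1] - m[0])
            if shorter <= 0:
                continue
            if _overlap(d, m) > overlap_frac * shorter:
                used[mi] = True
                pairs.append((int(di), int(mi)))
                break
    return pairs


def detection_eval(detected, manual, overlap_frac: float = 0.5,
                   b: int = 1000, seed: int = 0) -> DetectionEvalResult:
    """TPR/FDR of detected vs manual intervals, with bootstrap SDs."""
    detected = [tuple(d[:2]) for d in detected]
    manual = [tuple(m[:2]) for m in manual]
    pairs = match_intervals(detected, manual, overlap_frac)
    n_matched = len(pairs)
    n_manual = len(manual)
    n_detected = len(detected)
    n_false = n_detected - n_matched
    tpr = 100.0 * n_matched / n_manual if n_manual else 0.0
    fdr = 100.0 * n_false / n_detected if n_detected else 0.0
    rng = np.random.default_rng(seed)
    matched_flags = np.zeros(n_manual, dtype=float)
    matched_flags[[mi for _, mi in pairs]] = 1.0
    false_flags = np.ones(n_detected, dtype=float)
    false_flags[[di for di, _ in pairs]] = 0.0
    tpr_sd = fdr_sd = 0.0
    if n_manual and b >= 2:
        samples = [100.0 * matched_flags[rng.integers(0, n_manual, n_manual)].mean()
                   for _ in range(b)]
        tpr_sd = float(np.std(samples, ddof=1))
    if n_detected and b >= 2:
        samples = [100.0 * false_flags[rng.integers(0, n_detected, n_detected)].mean()
                   for _ in range(b)]
        fdr_sd = float(np.std(samples, ddof=1))
    return DetectionEvalResult(tpr=tpr, fdr=fdr, tpr_sd=tpr_sd, fdr_sd=fdr_sd,
                               n_manual=n_manual, n_detected=n_detected,
                               n_matched=n_matched, n_false=n_false)


# ---------------------------------------------------------------------------
# inter-observer reliability
# ---------------------------------------------------------------------------

@dataclass
class IORResult:
    n_compared: int
    n_agree: int
    n_missed: int
    n_uc_excluded: int
    ior_incl_missed: float
    ior_excl_missed: float
    scheme: str = "12"


def _as_rows(table) -> list[tuple[float, str]]:
    if isinstance(table, pd.DataFrame):
        cols = {c.lower(): c for c in table.columns}
        start_col = cols.get("start_s", cols.get("start"))
        label_col = cols.get("label", cols.get("class"))
        return [(float(s), str(l)) for s, l in
                zip(table[start_col], table[label_col])]
    return [(float(r[0]), str(r[1])) for r in table]


def ior(table_a, table_b, start_tolerance: float = 0.005,
        scheme: PoolingScheme | str | None = None,
        uc_label: str = "uc") -> IORResult:
    """Inter-observer agreement between two (start_s, label) tables.

    Rows are aligned when their start times agree within ``start_tolerance``
    (first match wins); ``uc`` rows are dropped before scoring; unmatched
    rows count as 'missed'.  Both the including- and excluding-missed
    percentages are returned.
    """
    rows_a = sorted(_as_rows(table_a))
    rows_b = sorted(_as_rows(table_b))
    n_uc = sum(1 for _, l in rows_a if l == uc_label)
    n_uc += sum(1 for _, l in rows_b if l == uc_label)
    rows_a = [r for r in rows_a if r[1] != uc_label]
    rows_b = [r for r in rows_b if r[1] != uc_label]
    used_b = [False] * len(rows_b)
    pairs = []
    j0 = 0
    for sa, la in rows_a:
        match = None
        for j in range(j0, len(rows_b)):
            sb, lb = rows_b[j]
            if sb > sa + start_tolerance:
                break
            if not used_b[j] and abs(sb - sa) <= start_tolerance:
                match = j
                break
        if match is not None:
            used_b[match] = True
            pairs.append((la, rows_b[match][1]))
    n_compared = len(pairs)
    n_missed = (len(rows_a) - n_compared) + (len(rows_b) - n_compared)
    if scheme is not None:
        a_lab = pool_labels([p[0] for p in pairs], scheme)
        b_lab = pool_labels([p[1] for p in pairs], scheme)
        scheme_name = scheme if isinstance(scheme, str) else scheme.name
    else:
        a_lab = np.asarray([p[0] for p in pairs], dtype=object)
        b_lab = np.asarray([p[1] for p in pairs], dtype=object)
        scheme_name = "12"
    n_agree = int(np.sum(a_lab == b_lab)) if n_compared else 0
    excl = 100.0 * n_agree / n_compared if n_compared else 0.0
    denom = n_compared + n_missed
    incl = 100.0 * n_agree / denom if denom else 0.0
    return IORResult(n_compared=n_compared, n_agree=n_agree, n_missed=n_missed,
                     n_uc_excluded=n_uc, ior_incl_missed=incl,
                     ior_excl_missed=excl, scheme=scheme_name)


# ---------------------------------------------------------------------------
# exemplars & novel classes
# ---------------------------------------------------------------------------

def class_exemplars(gs_set, labels, k: int = 5) -> dict:
    """Per class, the k members with minimum summed Manhattan distance to
    all other same-class members."""
    x = np.asarray(gs_set)
    flat = x.reshape(len(x), -1)
    labels = np.asarray(labels)
    out = {}
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 1:
            out[c] = [int(idx[0])]
            continue
        d = cdist(flat[idx], flat[idx], metric="cityblock")
        totals = d.sum(axis=1)
        order = np.argsort(totals, kind="stable")[: min(k, len(idx))]
        out[c] = [int(idx[i]) for i in order]
    return out


def novel_class_distribution(y_true_novel, y_pred) -> dict:
    """Fraction of novel-class elements assigned to each predicted class."""
    y_true_novel = np.asarray(y_true_novel)
    y_pred = np.asarray(y_pred)
    if len(y_true_novel) == 0:
        raise EmptyInputError("no novel-class elements")
    if len(y_true_novel) != len(y_pred):
        raise ShapeMismatchError("length mismatch")
    labels, counts = np.unique(y_pred, return_counts=True)
    total = counts.sum()
    return {l: float(cnt) / total for l, cnt in zip(labels, counts)}
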