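"""Published per-class element counts of the development and evaluation
datasets, used for dataset bookkeeping checks and as default class priors.

The development (DEV) rows use the 14-label scheme (13 syllable classes plus
``FP``); the evaluation (EV) rows use the pooled 6-label scheme.
"""

from __future__ import annotations

DEV_CLASS_ORDER = ("c", "c2", "c3", "c4", "c5", "h", "d", "up", "u", "f",
                   "us", "s", "ui", "FP")
EV_CLASS_ORDER = ("c", "c2", "split", "Rise", "ui", "FP")

DEV_TRAIN_COUNTS = {
    "c": 308, "c2": 241, "c3": 69, "c4": 0, "c5": 0, "h": 124, "d": 299,
    "up": 4343, "u": 298, "f": 1277, "us": 74, "s": 291, "ui": 543,
    "FP": 4849,
}
DEV_VALIDATION_COUNTS = {
    "c": 53, "c2": 42, "c3": 12, "c4": 0, "c5": 0, "h": 21, "d": 52,
    "up": 753, "u": 52, "f": 221, "us": 13, "s": 51, "ui": 94, "FP": 840,
}
DEV_TEST_COUNTS = {
    "c": 50, "c2": 39, "c3": 11, "c4": 0, "c5": 0, "h": 20, "d": 48,
    "up": 695, "u": 48, "f": 205, "us": 12, "s": 47, "ui": 87, "FP": 776,
}
EV_WILD_COUNTS = {
    "c": 20, "c2": 224, "split": 334, "Rise": 1025, "ui": 110, "FP": 234,
}
EV_LAB_COUNTS = {
    "c": 61, "c2": 404, "split": 739, "Rise": 819, "ui": 200, "FP": 389,
}

DEV_SUBSETS = {
    "DEV_train": DEV_TRAIN_COUNTS,
    "DEV_validation": DEV_VALIDATION_COUNTS,
    "DEV_test": DEV_TEST_COUNTS,
}


def dev_total_elements() -> int:
    """Total number of detected elements across the three DEV subsets."""
    return sum(sum(counts.values()) for counts in DEV_SUBSETS.values())


def dev_total_false_positives() -> int:
    """Total FP elements across the three DEV subsets."""
    return sum(counts["FP"] for counts in DEV_SUBSETS.values())


def ev_wild_total_elements() -> int:
    """Total elements in the EV_wild subset."""
    return sum(EV_WILD_COUNTS.values())


def ev_lab_total_elements() -> int:
    return sum(EV_LAB_COUNTS.values())
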