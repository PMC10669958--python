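"""Published contingency counts of the three-observer CBCT caries reader study.

These are the per-observer, per-arm TP/TN/FP/FN counts against the consensus
ground truth (19,936 approximal surfaces; 6,008 'presence of caries' and
13,928 'absence of caries') reported for the reader study this package's
evaluation machinery targets.  They are *input data*: the metric and kappa
implementations are validated by recomputing the study's printed
sensitivity, specificity, accuracy and kappa values from these counts.

:func:`build_rating_fixture` expands the counts into a full synthetic rating
table + ground-truth table whose per-observer confusion counts reproduce all
six rows exactly (which observer errs on which individual surface is not
identifiable from marginal counts, so the assignment is conventional).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reader_stats import ABSENCE, PRESENCE, ConfusionCounts

__all__ = [
    "OBSERVER_ARM_COUNTS",
    "GROUND_TRUTH_COUNTS",
    "PUBLISHED_METRICS",
    "build_rating_fixture",
]

OBSERVER_ARM_COUNTS: dict[tuple[str, str], ConfusionCounts] = {
    ("observer1", "unaided"): ConfusionCounts(TP=4377, TN=13671, FP=257, FN=1631),
    ("observer1", "aided"): ConfusionCounts(TP=5248, TN=13465, FP=463, FN=760),
    ("observer2", "unaided"): ConfusionCounts(TP=4609, TN=13357, FP=571, FN=1399),
    ("observer2", "aided"): ConfusionCounts(TP=5210, TN=13455, FP=473, FN=798),
    ("observer3", "unaided"): ConfusionCounts(TP=4588, TN=10184, FP=3744, FN=1420),
    ("observer3", "aided"): ConfusionCounts(TP=5299, TN=12875, FP=1053, FN=709),
}

GROUND_TRUTH_COUNTS = {ABSENCE: 13928, PRESENCE: 6008}

# The study's printed sensitivity/specificity/accuracy/kappa per observer x arm
# (3 decimal places) — the reference values the implementations must reproduce.
PUBLISHED_METRICS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("observer1", "unaided"): (0.729, 0.982, 0.905, 0.759),
    ("observer1", "aided"): (0.874, 0.967, 0.939, 0.852),
    ("observer2", "unaided"): (0.767, 0.959, 0.901, 0.756),
    ("observer2", "aided"): (0.867, 0.966, 0.936, 0.846),
    ("observer3", "unaided"): (0.764, 0.731, 0.741, 0.446),
    ("observer3", "aided"): (0.882, 0.924, 0.912, 0.793),
}

# Published binarized absence/presence distribution per observer x arm.
PUBLISHED_DISTRIBUTION: dict[tuple[str, str], tuple[int, int]] = {
    ("observer1", "unaided"): (15302, 4634),
    ("observer1", "aided"): (14225, 5711),
    ("observer2", "unaided"): (14756, 5180),
    ("observer2", "aided"): (14253, 5683),
    ("observer3", "unaided"): (11604, 8332),
    ("observer3", "aided"): (13584, 6352),
}


def build_rating_fixture():
    """Build a rating table + ground truth reproducing the published counts.

    Surfaces are ordered with all ground-truth positives first.  For each
    observer x arm, the first TP positives are rated 'caries definitely
    present' (score 5) and the remaining FN positives score 1; the first FP
    negatives score 5 and the remaining TN negatives score 1.  This fixes the
    per-surface assignment by convention while reproducing every marginal
    count exactly.

    Returns ``(table, ground_truth)`` in the package's standard schemas.
    """
    n_pos = GROUND_TRUTH_COUNTS[PRESENCE]
    n_neg = GROUND_TRUTH_COUNTS[ABSENCE]
    n = n_pos + n_neg
    # two surfaces per tooth, cases of up to 28 teeth
    surface_index = np.arange(n)
    tooth_index = surface_index // 2
    case_id = np.array([f"case{t // 28:04d}" for t in tooth_index])
    quadrant_tooth = tooth_index % 28
    fdi = 10 * (quadrant_tooth // 7 + 1) + (quadrant_tooth % 7 + 1)
    surface = np.where(surface_index % 2 == 0, "mesial", "distal")
    truth = np.array([PRESENCE] * n_pos + [ABSENCE] * n_neg)

    ground_truth = pd.DataFrame({
        "case_id": case_id,
        "tooth_fdi": fdi,
        "surface": surface,
        "label": truth,
        "provenance": "unanimous",
    })

    frames = []
    for (obs, arm), c in OBSERVER_ARM_COUNTS.items():
        assert c.TP + c.FN == n_pos and c.TN + c.FP == n_neg
        scores = np.empty(n, int)
        scores[:c.TP] = 5                # true positives
        scores[c.TP:n_pos] = 1           # false negatives
        scores[n_pos:n_pos + c.FP] = 5   # false positives
        scores[n_pos + c.FP:] = 1        # true negatives
        frames.append(pd.DataFrame({
            "case_id": case_id,
            "tooth_fdi": fdi,
            "surface": surface,
            "condition": "intact",
            "observer_id": obs,
            "arm": arm,
            "score": scores,
            "session": 1,
        }))
    return pd.concat(frames, ignore_index=True), ground_truth
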