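"""Reader-study evaluation statistics.

Implements the complete evaluation machinery of a multi-observer,
two-arm (unaided vs software-aided) caries reading study: binarization of
five-point confidence scores, consensus ground truth with adjudication of
conflicting surfaces, sensitivity/specificity/accuracy from confusion
counts, the kappa family (Cohen's, weighted, Fleiss with per-category
components), ROC/AUC over the ordinal confidence scale, intra-observer
repeatability, and the assembled report tables.

Conventions
-----------
* Scores 1-3 binarize to 'absence', 4-5 to 'presence'.
* Accuracy = (TP + TN) / (TP + FP + TN + FN).
* Weighted kappa uses disagreement weights ``(|i - j| / (k - 1)) ** q``
  (q = 1 linear, q = 2 quadratic; quadratic is the default).
* Kappa confidence intervals use the large-sample standard error
  ``sqrt(p_o (1 - p_o) / (n (1 - p_e)^2))``.
* Data cleaning drops surfaces whose tooth condition is 'missing' or
  'excluded' in any observer's record; 'restorated' and 'support' teeth keep
  their surface scores.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError

__all__ = [
    "RATING_COLUMNS",
    "ConfusionCounts",
    "MetricSet",
    "binarize",
    "load_rating_table",
    "validate_rating_table",
    "clean_table",
    "consensus_ground_truth",
    "merge_adjudication",
    "confusion",
    "metrics",
    "cohens_kappa",
    "cohens_kappa_paired",
    "kappa_confidence_interval",
    "weighted_kappa",
    "fleiss_kappa",
    "rating_count_matrix",
    "roc_auc",
    "intra_observer",
    "full_report",
    "save_report",
]

RATING_COLUMNS = ["case_id", "tooth_fdi", "surface", "condition",
                  "observer_id", "arm", "score", "session"]
SURFACE_KEY = ["case_id", "tooth_fdi", "surface"]
ABSENCE, PRESENCE = "absence", "presence"


# ---------------------------------------------------------------------------
# Rating table
# ---------------------------------------------------------------------------

def binarize(score: int) -> str:
    """Scores 1-3 -> 'absence', 4-5 -> 'presence'."""
    score = int(score)
    if not 1 <= score <= 5:
        raise ValueError(f"score must be in 1..5, got {score}")
    return PRESENCE if score >= 4 else ABSENCE


def validate_rating_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RATING_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError([f"rating table missing column {c!r}" for c in missing])
    bad = ~table["score"].isin([1, 2, 3, 4, 5])
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} rating rows have scores outside 1..5")
    dup = table.duplicated(subset=SURFACE_KEY + ["observer_id", "arm", "session"])
    if dup.any():
        raise ValidationError(
            f"{int(dup.sum())} duplicate (surface, observer, arm, session) records"
        )
    return table


def load_rating_table(path: str) -> pd.DataFrame:
    return validate_rating_table(pd.read_csv(path))


def clean_table(table: pd.DataFrame):
    """Drop surfaces of missing/excluded teeth; returns (clean, dropped_keys)."""
    flagged = table.loc[table["condition"].isin(["missing", "excluded"]), SURFACE_KEY]
    dropped = flagged.drop_duplicates()
    if len(dropped):
        idx = table.set_index(SURFACE_KEY).index
        bad = pd.MultiIndex.from_frame(dropped)
        clean = table[~idx.isin(bad)].copy()
    else:
        clean = table.copy()
    return clean, dropped.reset_index(drop=True)


def _binarized(table: pd.DataFrame) -> pd.Series:
    return table["score"].astype(int).ge(4).map({True: PRESENCE, False: ABSENCE})


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def consensus_ground_truth(table: pd.DataFrame, arm: str):
    """Unanimous binarized consensus per surface; the rest become conflicts.

    Returns ``(ground_truth, conflicts)``: a DataFrame with columns
    case_id, tooth_fdi, surface, label, provenance for surfaces on which all
    observers of the chosen arm agree after binarization, and a DataFrame of
    conflicting surfaces with a reason ('split' or 'incomplete').
    """
    sub = table[(table["arm"] == arm) & (table["session"] == 1)].copy()
    if sub.empty:
        raise DomainError(f"no session-1 records for arm {arm!r}")
    sub["binary"] = _binarized(sub)
    pivot = sub.pivot_table(index=SURFACE_KEY, columns="observer_id",
                            values="binary", aggfunc="first")
    complete = pivot.notna().all(axis=1)
    n_distinct = pivot.nunique(axis=1, dropna=True)
    unanimous = complete & (n_distinct == 1)
    gt = pivot[unanimous].index.to_frame(index=False)
    gt["label"] = pivot[unanimous].iloc[:, 0].to_numpy()
    gt["provenance"] = "unanimous"
    conflicts = pivot[~unanimous].index.to_frame(index=False)
    conflicts["reason"] = np.where(complete[~unanimous], "split", "incomplete")
    gt = gt.reset_index(drop=True) if len(gt) else pd.DataFrame(
        columns=SURFACE_KEY + ["label", "provenance"])
    conflicts = conflicts.reset_index(drop=True) if len(conflicts) else pd.DataFrame(
        columns=SURFACE_KEY + ["reason"])
    return gt, conflicts


def merge_adjudication(ground_truth: pd.DataFrame, conflicts: pd.DataFrame,
                       decisions: pd.DataFrame) -> pd.DataFrame:
    """Fold adjudicated labels for conflicting surfaces into the ground truth.

    ``decisions`` needs columns case_id, tooth_fdi, surface, label.  Every
    conflict must be covered; a decision for a non-conflict surface is
    ignored with a warning (unanimity wins).
    """
    if conflicts.empty:
        return ground_truth.copy()
    dec = decisions.set_index(SURFACE_KEY)
    conf_idx = pd.MultiIndex.from_frame(conflicts[SURFACE_KEY])
    uncovered = conf_idx[~conf_idx.isin(dec.index)]
    if len(uncovered):
        raise ValidationError(
            [f"no adjudication decision for surface {tuple(k)}" for k in uncovered]
        )
    extraneous = dec.index[~dec.index.isin(conf_idx)]
    if len(extraneous):
        warnings.warn(
            f"{len(extraneous)} adjudication decisions target non-conflict "
            "surfaces and are ignored (unanimous consensus wins)",
            stacklevel=2,
        )
    adjudicated = dec.loc[conf_idx, ["label"]].reset_index()
    bad = ~adjudicated["label"].isin([ABSENCE, PRESENCE])
    if bad.any():
        raise ValidationError(f"{int(bad.sum())} adjudication labels are not "
                              f"'{ABSENCE}'/'{PRESENCE}'")
    adjudicated["provenance"] = "adjudicated"
    return pd.concat([ground_truth, adjudicated], ignore_index=True)


# ---------------------------------------------------------------------------
# Confusion counts and Eq.-style metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts against ground truth; positives are 'presence of caries'."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float


def confusion(table: pd.DataFrame, ground_truth: pd.DataFrame,
              observer_id: str, arm: str, session: int = 1) -> ConfusionCounts:
    """Confusion counts of one observer x arm against the ground truth."""
    sub = table[(table["observer_id"] == observer_id) & (table["arm"] == arm)
                & (table["session"] == session)].copy()
    sub["binary"] = _binarized(sub)
    merged = sub.merge(ground_truth, on=SURFACE_KEY, how="inner",
                       validate="one_to_one")
    pred = merged["binary"] == PRESENCE
    truth = merged["label"] == PRESENCE
    return ConfusionCounts(
        TP=int((pred & truth).sum()),
        FP=int((pred & ~truth).sum()),
        TN=int((~pred & ~truth).sum()),
        FN=int((~pred & truth).sum()),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/total."""
    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); returning NaN",
                          stacklevel=3)
            return float("nan")
        return num / den

    return MetricSet(
        sensitivity=ratio(c.TP, c.TP + c.FN, "sensitivity"),
        specificity=ratio(c.TN, c.TN + c.FP, "specificity"),
        accuracy=ratio(c.TP + c.TN, c.total, "accuracy"),
    )


# ---------------------------------------------------------------------------
# Kappa family
# ---------------------------------------------------------------------------

def _kappa_from_table(table: np.ndarray, weights: np.ndarray) -> float:
    """Generic (weighted) kappa from a k x k contingency table.

    ``weights`` are disagreement weights (0 on the diagonal).  Returns 1.0
    for the degenerate case of perfect agreement with expected agreement 1
    (single-cell table).
    """
    n = table.sum()
    if n <= 0:
        raise ValueError("contingency table is empty")
    p = table / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    expected = np.outer(row, col)
    do = (weights * p).sum()
    de = (weights * expected).sum()
    if de == 0:
        return 1.0 if do == 0 else float("nan")
    return float(1.0 - do / de)


def cohens_kappa(c: ConfusionCounts) -> float:
    """Cohen's kappa of a 2x2 rater-vs-truth table."""
    table = np.array([[c.TP, c.FN], [c.FP, c.TN]], float)
    return _kappa_from_table(table, 1.0 - np.eye(2))


def _pair_table(a, b, categories) -> np.ndarray:
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired ratings must be 1D of equal length")
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((len(cats), len(cats)), float)
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    return table


def cohens_kappa_paired(a, b, categories=None) -> float:
    """Cohen's kappa of two paired categorical rating series."""
    if categories is None:
        categories = sorted(set(np.asarray(a)) | set(np.asarray(b)))
    table = _pair_table(a, b, categories)
    return _kappa_from_table(table, 1.0 - np.eye(len(table)))


def kappa_confidence_interval(kappa: float, p_o: float, p_e: float, n: int,
                              level: float = 0.95):
    """Large-sample (asymptotic) confidence interval for a kappa coefficient."""
    from scipy import stats
    if n <= 0 or p_e >= 1.0:
        return float("nan"), float("nan")
    se = np.sqrt(p_o * (1.0 - p_o) / (n * (1.0 - p_e) ** 2))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(kappa - z * se), float(min(1.0, kappa + z * se))


def weighted_kappa(a, b, weights: str = "quadratic", categories=None) -> float:
    """Weighted kappa for ordinal paired ratings.

    Agreement weights are ``1 - (|i - j| / (k - 1)) ** q`` with q = 1
    (linear) or 2 (quadratic).  On a binary scale any weighting reduces to
    Cohen's kappa.
    """
    q = {"linear": 1, "quadratic": 2}.get(weights)
    if q is None:
        raise ValueError(f"weights must be 'linear' or 'quadratic', got {weights!r}")
    if categories is None:
        categories = sorted(set(np.asarray(a)) | set(np.asarray(b)))
    k = len(categories)
    table = _pair_table(a, b, categories)
    if k == 1:
        return _kappa_from_table(table, np.zeros((1, 1)))
    i, j = np.indices((k, k))
    disagreement = (np.abs(i - j) / (k - 1.0)) ** q
    return _kappa_from_table(table, disagreement)


def rating_count_matrix(table: pd.DataFrame, arm: str, values: str = "binary",
                        session: int = 1):
    """n_items x k count matrix over observers, for Fleiss kappa.

    ``values`` is 'binary' (absence/presence) or 'score' (1..5).
    """
    sub = table[(table["arm"] == arm) & (table["session"] == session)].copy()
    if values == "binary":
        sub["cat"] = _binarized(sub)
        cats = [ABSENCE, PRESENCE]
    elif values == "score":
        sub["cat"] = sub["score"].astype(int)
        cats = [1, 2, 3, 4, 5]
    else:
        raise ValueError("values must be 'binary' or 'score'")
    counts = (sub.groupby(SURFACE_KEY)["cat"].value_counts().unstack(fill_value=0)
              .reindex(columns=cats, fill_value=0))
    return counts.to_numpy(float), cats


def fleiss_kappa(counts: np.ndarray):
    """Fleiss kappa for n items rated by exactly m raters into k categories.

    Returns ``(overall, per_category)`` where ``per_category[j]`` is the
    category-specific coefficient
    ``1 - sum_i n_ij (m - n_ij) / (n m (m-1) p_j (1-p_j))``.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2:
        raise ValueError("counts must be an n x k matrix")
    m_per_item = counts.sum(axis=1)
    m = m_per_item[0]
    if not np.all(m_per_item == m):
        raise ValidationError("every item must be rated by the same number of raters")
    if m < 2:
        raise ValueError("Fleiss kappa requires at least 2 raters per item")
    n, k = counts.shape
    p_j = counts.sum(axis=0) / (n * m)
    P_i = ((counts ** 2).sum(axis=1) - m) / (m * (m - 1))
    P_bar = P_i.mean()
    P_e = (p_j ** 2).sum()
    if P_e == 1.0:
        overall = 1.0 if P_bar == 1.0 else float("nan")
    else:
        overall = float((P_bar - P_e) / (1.0 - P_e))
    per_category = {}
    for j in range(k):
        denom = n * m * (m - 1) * p_j[j] * (1.0 - p_j[j])
        if denom == 0:
            per_category[j] = float("nan")
        else:
            num = (counts[:, j] * (m - counts[:, j])).sum()
            per_category[j] = float(1.0 - num / denom)
    return overall, per_category


# ---------------------------------------------------------------------------
# ROC over the ordinal confidence scale
# ---------------------------------------------------------------------------

def roc_auc(scores, labels):
    """Empirical ROC of five-point confidence ratings against binary truth.

    Operating points come from the four ordinal cutpoints (call positive when
    score >= c for c in 2..5) plus the trivial endpoints; the AUC is the
    trapezoidal area, which equals the tie-corrected concordance probability
    P(score_pos > score_neg) + 0.5 P(tie).
    """
    s = np.asarray(scores, int)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1D of equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("ROC requires both classes in the ground truth")
    points = [(1.0, 1.0)]  # cutpoint below the scale: everything positive
    for cut in (2, 3, 4, 5):
        called = s >= cut
        tpr = (called & y).sum() / n_pos
        fpr = (called & ~y).sum() / n_neg
        points.append((float(fpr), float(tpr)))
    points.append((0.0, 0.0))
    points = sorted(set(points))
    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return auc, points


# ---------------------------------------------------------------------------
# Intra-observer repeatability and the report bundle
# ---------------------------------------------------------------------------

def intra_observer(table: pd.DataFrame, repeat_session: int = 2) -> pd.DataFrame:
    """Repeatability (session 1 vs repeat session) per observer and arm.

    Surfaces present in only one session are excluded with a warning.
    Returns one row per observer x arm with Cohen's and weighted kappa on the
    five-point and binary scales.
    """
    repeats = table[table["session"] == repeat_session]
    if repeats.empty:
        raise ValidationError(f"no records with session == {repeat_session}")
    rows = []
    for (obs, arm), grp in repeats.groupby(["observer_id", "arm"]):
        first = table[(table["observer_id"] == obs) & (table["arm"] == arm)
                      & (table["session"] == 1)]
        merged = grp.merge(first, on=SURFACE_KEY, suffixes=("_2", "_1"))
        unmatched = len(grp) - len(merged)
        if unmatched:
            warnings.warn(
                f"{unmatched} repeat ratings of {obs}/{arm} have no session-1 "
                "pair and are excluded", stacklevel=2)
        if merged.empty:
            continue
        s1 = merged["score_1"].astype(int).to_numpy()
        s2 = merged["score_2"].astype(int).to_numpy()
        b1 = np.where(s1 >= 4, PRESENCE, ABSENCE)
        b2 = np.where(s2 >= 4, PRESENCE, ABSENCE)
        rows.append({
            "observer_id": obs, "arm": arm, "n_pairs": len(merged),
            "cohen_five_point": cohens_kappa_paired(s1, s2, [1, 2, 3, 4, 5]),
            "cohen_binary": cohens_kappa_paired(b1, b2, [ABSENCE, PRESENCE]),
            "weighted_five_point": weighted_kappa(s1, s2, "quadratic", [1, 2, 3, 4, 5]),
            "weighted_binary": weighted_kappa(b1, b2, "quadratic", [ABSENCE, PRESENCE]),
        })
    if not rows:
        raise ValidationError("no matched repeat pairs found")
    return pd.DataFrame(rows)


def full_report(table: pd.DataFrame, ground_truth: pd.DataFrame) -> dict:
    """Assemble the full evaluation bundle from a rating table + ground truth.

    Returns a dict of DataFrames: 'distribution' (absence/presence counts per
    observer x arm and for ground truth), 'performance' (confusion counts,
    sensitivity/specificity/accuracy, kappa with CI, AUC per observer x arm),
    'pairwise' (weighted/Cohen's kappa between observer pairs per arm),
    'fleiss_binary' and 'fleiss_five_point' (per-category + overall), and
    'intra_observer' when repeat-session records exist.
    """
    validate_rating_table(table)
    observers = sorted(table["observer_id"].unique())
    arms = sorted(table["arm"].unique())
    session1 = table[table["session"] == 1]

    dist_rows = []
    perf_rows = []
    for obs in observers:
        for arm in arms:
            sub = session1[(session1["observer_id"] == obs) & (session1["arm"] == arm)]
            if sub.empty:
                continue
            binary = _binarized(sub)
            dist_rows.append({
                "observer_id": obs, "arm": arm,
                "absence": int((binary == ABSENCE).sum()),
                "presence": int((binary == PRESENCE).sum()),
            })
            c = confusion(table, ground_truth, obs, arm)
            m = metrics(c)
            kappa = cohens_kappa(c)
            p_o = (c.TP + c.TN) / c.total
            marg = ((c.TP + c.FP) * (c.TP + c.FN)
                    + (c.TN + c.FN) * (c.TN + c.FP)) / c.total ** 2
            lo, hi = kappa_confidence_interval(kappa, p_o, marg, c.total)
            merged = sub.merge(ground_truth, on=SURFACE_KEY, how="inner")
            try:
                auc, _ = roc_auc(merged["score"].astype(int),
                                 merged["label"] == PRESENCE)
            except DomainError:  # single-class ground truth: AUC undefined
                auc = float("nan")
            perf_rows.append({
                "observer_id": obs, "arm": arm,
                "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "accuracy": m.accuracy, "kappa": kappa,
                "kappa_ci_low": lo, "kappa_ci_high": hi, "auc": auc,
            })
    gt_dist = {
        "observer_id": "ground_truth", "arm": "",
        "absence": int((ground_truth["label"] == ABSENCE).sum()),
        "presence": int((ground_truth["label"] == PRESENCE).sum()),
    }
    distribution = pd.DataFrame(dist_rows + [gt_dist])

    pair_rows = []
    for i, a in enumerate(observers):
        for b in observers[i + 1:]:
            for arm in arms:
                sa = session1[(session1["observer_id"] == a) & (session1["arm"] == arm)]
                sb = session1[(session1["observer_id"] == b) & (session1["arm"] == arm)]
                merged = sa.merge(sb, on=SURFACE_KEY, suffixes=("_a", "_b"))
                if merged.empty:
                    continue
                s_a = merged["score_a"].astype(int).to_numpy()
                s_b = merged["score_b"].astype(int).to_numpy()
                bin_a = np.where(s_a >= 4, PRESENCE, ABSENCE)
                bin_b = np.where(s_b >= 4, PRESENCE, ABSENCE)
                pair_rows.append({
                    "observer_a": a, "observer_b": b, "arm": arm,
                    "weighted_kappa_five_point": weighted_kappa(
                        s_a, s_b, "quadratic", [1, 2, 3, 4, 5]),
                    "cohen_kappa_five_point": cohens_kappa_paired(
                        s_a, s_b, [1, 2, 3, 4, 5]),
                    "cohen_kappa_binary": cohens_kappa_paired(
                        bin_a, bin_b, [ABSENCE, PRESENCE]),
                })
    pairwise = pd.DataFrame(pair_rows)

    fleiss_frames = {}
    for values, cats_name in (("binary", "fleiss_binary"), ("score", "fleiss_five_point")):
        rows = []
        for arm in arms:
            counts, cats = rating_count_matrix(table, arm, values)
            overall, per_cat = fleiss_kappa(counts)
            row = {"arm": arm, "overall": overall}
            for j, cat in enumerate(cats):
                row[f"category_{cat}"] = per_cat[j]
            rows.append(row)
        fleiss_frames[cats_name] = pd.DataFrame(rows)

    bundle = {
        "distribution": distribution,
        "performance": pd.DataFrame(perf_rows),
        "pairwise": pairwise,
        **fleiss_frames,
    }
    if (table["session"] > 1).any():
        bundle["intra_observer"] = intra_observer(table)
    return bundle


def save_report(bundle: dict, out_dir: str) -> str:
    """Write each table as CSV plus one JSON bundle; returns the JSON path."""
    os.makedirs(out_dir, exist_ok=True)
    payload = {}
    for name, frame in bundle.items():
        frame.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)
        payload[name] = json.loads(frame.to_json(orient="records"))
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return path
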