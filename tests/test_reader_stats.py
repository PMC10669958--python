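"""Rating-table machinery, Eq.-style metrics, the kappa family, and ROC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cariodet.errors import DomainError, ValidationError
from cariodet.reader_stats import (
    ABSENCE,
    PRESENCE,
    ConfusionCounts,
    binarize,
    clean_table,
    cohens_kappa,
    cohens_kappa_paired,
    confusion,
    consensus_ground_truth,
    fleiss_kappa,
    full_report,
    intra_observer,
    merge_adjudication,
    metrics,
    rating_count_matrix,
    roc_auc,
    save_report,
    weighted_kappa,
)
from cariodet.study_counts import (
    GROUND_TRUTH_COUNTS,
    OBSERVER_ARM_COUNTS,
    PUBLISHED_DISTRIBUTION,
    PUBLISHED_METRICS,
    build_rating_fixture,
)


def make_table(rows):
    frame = pd.DataFrame(rows, columns=["case_id", "tooth_fdi", "surface",
                                        "observer_id", "arm", "score"])
    frame["condition"] = "intact"
    frame["session"] = 1
    return frame


class TestBinarize:
    @pytest.mark.parametrize("score,expected", [
        (1, ABSENCE), (2, ABSENCE), (3, ABSENCE), (4, PRESENCE), (5, PRESENCE),
    ])
    def test_cutpoint(self, score, expected):
        assert binarize(score) == expected

    @pytest.mark.parametrize("score", [0, 6, -1])
    def test_out_of_range(self, score):
        with pytest.raises(ValueError):
            binarize(score)


class TestCleaning:
    def test_missing_and_excluded_surfaces_dropped(self):
        table = make_table([
            ("c1", 36, "mesial", "o1", "unaided", 4),
            ("c1", 36, "distal", "o1", "unaided", 2),
            ("c1", 37, "mesial", "o1", "unaided", 1),
        ])
        table.loc[table["tooth_fdi"] == 37, "condition"] = "missing"
        clean, dropped = clean_table(table)
        assert len(clean) == 2
        assert len(dropped) == 1
        assert dropped.iloc[0]["tooth_fdi"] == 37

    def test_restorated_surfaces_kept(self):
        table = make_table([("c1", 36, "mesial", "o1", "unaided", 4)])
        table["condition"] = "restorated"
        clean, dropped = clean_table(table)
        assert len(clean) == 1 and len(dropped) == 0


class TestConsensus:
    def _three_observer_table(self, scores_by_surface):
        rows = []
        for (case, tooth, surf), scores in scores_by_surface.items():
            for obs, score in zip(["o1", "o2", "o3"], scores):
                rows.append((case, tooth, surf, obs, "unaided", score))
        return make_table(rows)

    def test_unanimous_presence(self):
        table = self._three_observer_table({("c1", 36, "mesial"): (4, 5, 4)})
        gt, conflicts = consensus_ground_truth(table, "unaided")
        assert len(gt) == 1 and len(conflicts) == 0
        assert gt.iloc[0]["label"] == PRESENCE
        assert gt.iloc[0]["provenance"] == "unanimous"

    def test_split_vote_is_conflict(self):
        table = self._three_observer_table({("c1", 36, "mesial"): (4, 4, 2)})
        gt, conflicts = consensus_ground_truth(table, "unaided")
        assert len(gt) == 0 and len(conflicts) == 1
        assert conflicts.iloc[0]["reason"] == "split"

    def test_unanimous_absence(self):
        table = self._three_observer_table({("c1", 36, "mesial"): (1, 2, 3)})
        gt, _ = consensus_ground_truth(table, "unaided")
        assert gt.iloc[0]["label"] == ABSENCE

    def test_missing_observer_routes_to_incomplete(self):
        table = self._three_observer_table({("c1", 36, "mesial"): (1, 2, 3)})
        table = pd.concat([table, make_table(
            [("c1", 36, "distal", "o1", "unaided", 4)])], ignore_index=True)
        gt, conflicts = consensus_ground_truth(table, "unaided")
        assert len(gt) == 1
        assert conflicts.iloc[0]["reason"] == "incomplete"

    def test_counting_identity(self):
        """#ground-truth + #conflicts equals #surfaces, always."""
        rng = np.random.default_rng(0)
        surfaces = {(f"c{i}", 31, s): tuple(rng.integers(1, 6, 3))
                    for i in range(40) for s in ("mesial", "distal")}
        table = self._three_observer_table(surfaces)
        gt, conflicts = consensus_ground_truth(table, "unaided")
        assert len(gt) + len(conflicts) == len(surfaces)


class TestAdjudication:
    def _setup(self):
        rows = []
        for case, scores in [("c1", (4, 4, 4)), ("c2", (4, 4, 1)), ("c3", (1, 4, 5))]:
            for obs, s in zip(["o1", "o2", "o3"], scores):
                rows.append((case, 36, "mesial", obs, "unaided", s))
        table = make_table(rows)
        return consensus_ground_truth(table, "unaided")

    def test_zero_conflicts_passthrough(self):
        gt, _ = self._setup()
        out = merge_adjudication(gt, pd.DataFrame(columns=gt.columns), None)
        pd.testing.assert_frame_equal(out, gt)

    def test_decisions_complete_the_table(self):
        gt, conflicts = self._setup()
        decisions = conflicts[["case_id", "tooth_fdi", "surface"]].copy()
        decisions["label"] = [PRESENCE, ABSENCE]
        out = merge_adjudication(gt, conflicts, decisions)
        assert len(out) == 3
        assert (out["provenance"] == "adjudicated").sum() == 2

    def test_uncovered_conflict_raises(self):
        gt, conflicts = self._setup()
        with pytest.raises(ValidationError, match="no adjudication"):
            merge_adjudication(gt, conflicts, conflicts.head(1).assign(label=PRESENCE))

    def test_decision_for_unanimous_surface_warns_and_is_ignored(self):
        gt, conflicts = self._setup()
        decisions = pd.DataFrame({
            "case_id": ["c2", "c3", "c1"], "tooth_fdi": [36, 36, 36],
            "surface": ["mesial"] * 3,
            "label": [PRESENCE, ABSENCE, ABSENCE],  # c1 tries to flip unanimity
        })
        with pytest.warns(UserWarning, match="non-conflict"):
            out = merge_adjudication(gt, conflicts, decisions)
        row = out[(out["case_id"] == "c1")]
        assert row.iloc[0]["label"] == PRESENCE  # unanimity wins


class TestConfusionAndMetrics:
    def test_identical_ratings_give_clean_counts(self):
        table, gt = build_rating_fixture()
        small_gt = gt.head(100).copy()
        rows = [(r.case_id, r.tooth_fdi, r.surface, "obs", "unaided",
                 5 if r.label == PRESENCE else 1)
                for r in small_gt.itertuples()]
        c = confusion(make_table(rows), small_gt, "obs", "unaided")
        n_pos = int((small_gt["label"] == PRESENCE).sum())
        assert (c.TP, c.TN, c.FP, c.FN) == (n_pos, 100 - n_pos, 0, 0)

    def test_published_counts_reproduced_from_fixture(self):
        table, gt = build_rating_fixture()
        for (obs, arm), expected in OBSERVER_ARM_COUNTS.items():
            c = confusion(table, gt, obs, arm)
            assert c == expected

    def test_flipping_ratings_swaps_counts(self):
        table, gt = build_rating_fixture()
        sub = table[(table.observer_id == "observer1") & (table.arm == "unaided")]
        flipped = sub.copy()
        flipped["score"] = 6 - flipped["score"].clip(1, 5).where(
            flipped["score"].isin([1, 5]), flipped["score"])
        flipped["score"] = np.where(sub["score"] >= 4, 1, 5)
        c = confusion(sub, gt, "observer1", "unaided")
        f = confusion(flipped, gt, "observer1", "unaided")
        assert (f.TP, f.FN) == (c.FN, c.TP)
        assert (f.TN, f.FP) == (c.FP, c.TN)

    @pytest.mark.parametrize("key", sorted(OBSERVER_ARM_COUNTS))
    def test_published_metrics_to_three_decimals(self, key):
        c = OBSERVER_ARM_COUNTS[key]
        sens, spec, acc, kappa = PUBLISHED_METRICS[key]
        m = metrics(c)
        assert round(m.sensitivity, 3) == sens
        assert round(m.specificity, 3) == spec
        assert round(m.accuracy, 3) == acc
        assert round(cohens_kappa(c), 3) == kappa

    def test_perfect_counts_give_unit_metrics(self):
        m = metrics(ConfusionCounts(TP=40, FP=0, TN=60, FN=0))
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_zero_denominator_warns_nan(self):
        with pytest.warns(UserWarning, match="sensitivity"):
            m = metrics(ConfusionCounts(TP=0, FP=5, TN=5, FN=0))
        assert np.isnan(m.sensitivity)


class TestKappaFamily:
    def test_perfect_agreement_is_one(self):
        assert cohens_kappa(ConfusionCounts(TP=30, FP=0, TN=70, FN=0)) == 1.0

    def test_matches_sklearn_on_random_pairs(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.integers(1, 6, 80)
            b = np.where(rng.random(80) < 0.6, a, rng.integers(1, 6, 80))
            ours = cohens_kappa_paired(a, b, [1, 2, 3, 4, 5])
            assert ours == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_relabeling_invariance(self):
        c = ConfusionCounts(TP=4377, FP=257, TN=13671, FN=1631)
        swapped = ConfusionCounts(TP=c.TN, FP=c.FN, TN=c.TP, FN=c.FP)
        assert cohens_kappa(c) == pytest.approx(cohens_kappa(swapped))

    def test_weighted_kappa_identical_series_is_one(self):
        s = np.array([1, 3, 5, 2, 4, 4])
        assert weighted_kappa(s, s, "linear", [1, 2, 3, 4, 5]) == 1.0
        assert weighted_kappa(s, s, "quadratic", [1, 2, 3, 4, 5]) == 1.0

    def test_weighted_kappa_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(2)
        a = rng.integers(1, 6, 120)
        b = np.clip(a + rng.integers(-2, 3, 120), 1, 5)
        for q, name in ((1, "linear"), (2, "quadratic")):
            # direct double-sum oracle over the full 5x5 table
            table = np.zeros((5, 5))
            for x, y in zip(a, b):
                table[x - 1, y - 1] += 1
            p = table / table.sum()
            row, col = p.sum(1), p.sum(0)
            num = den = 0.0
            for i in range(5):
                for j in range(5):
                    v = (abs(i - j) / 4) ** q
                    num += v * p[i, j]
                    den += v * row[i] * col[j]
            expected = 1 - num / den
            assert weighted_kappa(a, b, name, [1, 2, 3, 4, 5]) == \
                pytest.approx(expected, abs=1e-12)

    def test_weighted_kappa_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(3)
        a = rng.integers(1, 6, 150)
        b = np.clip(a + rng.integers(-1, 2, 150), 1, 5)
        assert weighted_kappa(a, b, "quadratic", [1, 2, 3, 4, 5]) == pytest.approx(
            cohen_kappa_score(a, b, weights="quadratic"), abs=1e-12)
        assert weighted_kappa(a, b, "linear", [1, 2, 3, 4, 5]) == pytest.approx(
            cohen_kappa_score(a, b, weights="linear"), abs=1e-12)

    def test_binary_weighted_kappa_equals_cohens(self):
        rng = np.random.default_rng(4)
        a = rng.choice([ABSENCE, PRESENCE], 100)
        b = np.where(rng.random(100) < 0.7, a, rng.choice([ABSENCE, PRESENCE], 100))
        cats = [ABSENCE, PRESENCE]
        ck = cohens_kappa_paired(a, b, cats)
        assert weighted_kappa(a, b, "linear", cats) == pytest.approx(ck)
        assert weighted_kappa(a, b, "quadratic", cats) == pytest.approx(ck)


class TestFleissKappa:
    def test_unanimous_raters_give_one(self):
        counts = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        overall, per_cat = fleiss_kappa(counts)
        assert overall == pytest.approx(1.0)
        assert per_cat[0] == pytest.approx(1.0)
        assert per_cat[1] == pytest.approx(1.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss
        rng = np.random.default_rng(5)
        raw = rng.integers(0, 3, (50, 4))  # 50 items, 4 raters, 3 categories
        counts = np.stack([(raw == k).sum(1) for k in range(3)], axis=1)
        overall, _ = fleiss_kappa(counts)
        assert overall == pytest.approx(sm_fleiss(counts), abs=1e-12)

    def test_worked_example_matches_direct_double_sum(self):
        rng = np.random.default_rng(6)
        raw = rng.integers(0, 2, (10, 3))
        counts = np.stack([(raw == k).sum(1) for k in range(2)], axis=1)
        n, m, k = 10, 3, 2
        p_j = counts.sum(0) / (n * m)
        P_i = ((counts ** 2).sum(1) - m) / (m * (m - 1))
        expected = (P_i.mean() - (p_j ** 2).sum()) / (1 - (p_j ** 2).sum())
        overall, per_cat = fleiss_kappa(counts)
        assert overall == pytest.approx(expected)
        for j in range(k):
            num = (counts[:, j] * (m - counts[:, j])).sum()
            den = n * m * (m - 1) * p_j[j] * (1 - p_j[j])
            assert per_cat[j] == pytest.approx(1 - num / den)

    def test_uniform_random_ratings_near_zero(self):
        rng = np.random.default_rng(7)
        raw = rng.integers(0, 2, (5000, 3))
        counts = np.stack([(raw == k).sum(1) for k in range(2)], axis=1)
        overall, _ = fleiss_kappa(counts)
        assert abs(overall) <= 0.05

    def test_unequal_rater_counts_rejected(self):
        with pytest.raises(ValidationError):
            fleiss_kappa(np.array([[2, 1], [1, 1]]))

    def test_count_matrix_from_rating_table(self):
        table, _ = build_rating_fixture()
        counts, cats = rating_count_matrix(table, "unaided", "binary")
        assert counts.shape[1] == 2 and cats == [ABSENCE, PRESENCE]
        assert (counts.sum(axis=1) == 3).all()  # three observers per surface


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [5] * 10 + [1] * 20
        labels = [1] * 10 + [0] * 20
        auc, points = roc_auc(scores, labels)
        assert auc == 1.0
        assert (0.0, 0.0) in points and (1.0, 1.0) in points

    def test_matches_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = int(rng.integers(6, 50))
            scores = rng.integers(1, 6, n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            auc, _ = roc_auc(scores, labels)
            pos = scores[labels]
            neg = scores[~labels]
            wins = ties = 0
            for sp, sn in itertools.product(pos, neg):
                wins += sp > sn
                ties += sp == sn
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert auc == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(9)
        scores = rng.integers(1, 6, 400)
        labels = rng.random(400) < (scores / 6.0)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_independent_scores_near_half(self):
        rng = np.random.default_rng(10)
        scores = rng.integers(1, 6, 2000)
        labels = rng.random(2000) < 0.3
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.03)

    def test_four_item_fixture(self):
        auc, _ = roc_auc([5, 4, 4, 1], [1, 1, 0, 0])
        # pairs: (5,4)win (5,1)win (4,4)tie (4,1)win -> (3 + 0.5)/4
        assert auc == pytest.approx(3.5 / 4)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestIntraObserver:
    def _repeat_table(self, flip_one=False):
        rng = np.random.default_rng(11)
        scores = rng.integers(1, 6, 50)
        rows = []
        for sess in (1, 2):
            for i, s in enumerate(scores):
                rows.append({"case_id": f"c{i}", "tooth_fdi": 36,
                             "surface": "mesial", "condition": "intact",
                             "observer_id": "o1", "arm": "unaided",
                             "score": int(s), "session": sess})
        table = pd.DataFrame(rows)
        if flip_one:
            idx = table[(table.session == 2)].index[0]
            table.loc[idx, "score"] = 5 if table.loc[idx, "score"] < 4 else 1
        return table

    def test_identical_sessions_all_ones(self):
        rep = intra_observer(self._repeat_table())
        row = rep.iloc[0]
        assert row["cohen_five_point"] == pytest.approx(1.0)
        assert row["cohen_binary"] == pytest.approx(1.0)
        assert row["weighted_five_point"] == pytest.approx(1.0)

    def test_one_flipped_binary_rating_matches_hand_computed_kappa(self):
        table = self._repeat_table(flip_one=True)
        rep = intra_observer(table)
        s1 = table[table.session == 1].sort_values("case_id")["score"].to_numpy()
        s2 = table[table.session == 2].sort_values("case_id")["score"].to_numpy()
        b1 = s1 >= 4
        b2 = s2 >= 4
        n = len(b1)
        po = (b1 == b2).mean()
        pe = (b1.mean() * b2.mean()) + ((1 - b1.mean()) * (1 - b2.mean()))
        assert rep.iloc[0]["cohen_binary"] == pytest.approx((po - pe) / (1 - pe))

    def test_no_repeat_records_rejected(self):
        table = self._repeat_table()
        with pytest.raises(ValidationError):
            intra_observer(table[table.session == 1])


class TestFullReport:
    def test_distribution_matches_published_rows(self):
        table, gt = build_rating_fixture()
        report = full_report(table, gt)
        dist = report["distribution"].set_index(["observer_id", "arm"])
        for (obs, arm), (absence, presence) in PUBLISHED_DISTRIBUTION.items():
            row = dist.loc[(obs, arm)]
            assert (row["absence"], row["presence"]) == (absence, presence)
        gt_row = dist.loc[("ground_truth", "")]
        assert gt_row["absence"] == GROUND_TRUTH_COUNTS[ABSENCE]
        assert gt_row["presence"] == GROUND_TRUTH_COUNTS[PRESENCE]
        ratio = gt_row["absence"] / gt_row["presence"]
        assert ratio == pytest.approx(2.32, abs=0.005)

    def test_report_shape_and_determinism(self, tmp_path):
        from cariodet.phantom import ObserverModel, simulate_rating_study
        truth = pd.DataFrame({
            "case_id": [f"c{i:03d}" for i in range(60)],
            "tooth_fdi": [31 + i % 3 for i in range(60)],
            "surface": ["mesial", "distal"] * 30,
            "carious": np.random.default_rng(1).random(60) < 0.4,
        })
        panels = {
            arm: {f"o{k}": ObserverModel(sensitivity=0.85, specificity=0.9,
                                         seed=10 * j + k)
                  for k in range(3)}
            for j, arm in enumerate(["unaided", "aided"])
        }
        ratings = simulate_rating_study(truth, panels)
        gt = pd.DataFrame({
            "case_id": truth["case_id"], "tooth_fdi": truth["tooth_fdi"],
            "surface": truth["surface"],
            "label": np.where(truth["carious"], PRESENCE, ABSENCE),
            "provenance": "unanimous",
        })
        report = full_report(ratings, gt)
        assert len(report["performance"]) == 6  # 3 observers x 2 arms
        assert set(report) >= {"distribution", "performance", "pairwise",
                               "fleiss_binary", "fleiss_five_point"}
        assert len(report["pairwise"]) == 6  # 3 pairs x 2 arms

        path = save_report(report, str(tmp_path / "rep"))
        ratings2 = simulate_rating_study(truth, panels)
        report2 = full_report(ratings2, gt)
        path2 = save_report(report2, str(tmp_path / "rep2"))
        assert open(path).read() == open(path2).read()
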