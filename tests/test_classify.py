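"""Leave-one-out nested CV, AUC/threshold metrics, McNemar, Spearman."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from sitpipe.classify import (
    confusion_metrics,
    expert_comparison,
    loo_nested_cv,
    majority_vote_predictions,
    mcnemar_vs_baseline,
    roc_auc,
    roc_curve_points,
    severity_correlation,
)
from sitpipe.features import FeatureMatrix


def make_fm(X, labels, ids=None):
    n = len(labels)
    data = pd.DataFrame(X, columns=[f"f{i}" for i in range(np.shape(X)[1])])
    data["gender"] = [i % 2 for i in range(n)]
    meta = pd.DataFrame(
        {
            "subject_id": ids or [f"s{i}" for i in range(n)],
            "label": ["ASD" if l else "NT" for l in labels],
            "gender": [i % 2 for i in range(n)],
            "age": np.linspace(20, 50, n),
        }
    )
    return FeatureMatrix(data, meta)


SMALL_GRID = ((2, 8), (1, 4))


class TestAUC:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=8)
        labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
        # brute force over all (positive, negative) pairs
        pos = probs[labels == 1]
        neg = probs[labels == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(probs, labels) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        probs = rng.uniform(size=12)
        labels = rng.integers(0, 2, 12)
        labels[:2] = [0, 1]
        assert roc_auc(np.exp(3 * probs), labels) == pytest.approx(
            roc_auc(probs, labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestConfusion:
    def test_perfect(self):
        m = confusion_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert m == {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}

    def test_all_predicted_negative(self):
        m = confusion_metrics([0.2, 0.3, 0.1, 0.4], [1, 1, 0, 0])
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0

    def test_hand_counted_table(self):
        # preds: 1,1,0 | 1,0,0 ; labels: 1,1,1 | 0,0,0 -> TP=2 FN=1 FP=1 TN=2
        probs = [0.8, 0.6, 0.3, 0.7, 0.2, 0.4]
        labels = [1, 1, 1, 0, 0, 0]
        m = confusion_metrics(probs, labels)
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)

    def test_roc_points_end_at_corners(self):
        pts = roc_curve_points([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0])
        assert (pts.iloc[0].fpr, pts.iloc[0].tpr) == (0.0, 0.0)
        assert (pts.iloc[-1].fpr, pts.iloc[-1].tpr) == (1.0, 1.0)


class TestMcNemar:
    def test_identical_predictions(self):
        labels = [1, 0, 1, 0]
        out = mcnemar_vs_baseline([1, 0, 0, 0], [1, 0, 0, 0], labels)
        assert out["p"] == 1.0

    def test_eight_discordant_one_sided(self):
        labels = np.ones(8, int)
        preds_a = np.ones(8, int)   # all correct
        preds_b = np.zeros(8, int)  # all wrong
        out = mcnemar_vs_baseline(preds_a, preds_b, labels)
        assert out["p"] == pytest.approx(2 * 0.5**8)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 2, 20)
        a = rng.integers(0, 2, 20)
        b = rng.integers(0, 2, 20)
        s1 = mcnemar_vs_baseline(a, b, labels)
        s2 = mcnemar_vs_baseline(1 - a, 1 - b, 1 - labels)
        assert s1["statistic"] == pytest.approx(s2["statistic"])
        assert s1["p"] == pytest.approx(s2["p"])

    def test_majority_vote_baseline(self):
        assert majority_vote_predictions([1, 1, 1, 0]).tolist() == [1, 1, 1, 1]
        assert majority_vote_predictions([1, 0, 0, 0]).tolist() == [0, 0, 0, 0]


class TestSeverity:
    def test_perfectly_monotone(self):
        out = severity_correlation([0.1, 0.2, 0.5, 0.7, 0.9], [1, 2, 3, 4, 5])
        assert out["rho"] == pytest.approx(1.0)

    def test_reversed(self):
        out = severity_correlation([0.9, 0.7, 0.5, 0.2, 0.1], [1, 2, 3, 4, 5])
        assert out["rho"] == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(3)
        probs = rng.uniform(size=6)
        cov = rng.uniform(size=6)
        out = severity_correlation(probs, cov)
        # independent enumeration over all 6! pairings
        from scipy.stats import rankdata

        rp = rankdata(probs)
        obs = abs(np.corrcoef(rp, rankdata(cov))[0, 1])
        count = sum(
            abs(np.corrcoef(rp, rankdata(cov)[list(perm)])[0, 1]) >= obs - 1e-12
            for perm in permutations(range(6))
        )
        assert out["p"] == pytest.approx(count / 720)

    def test_constant_covariate_missing(self):
        out = severity_correlation([0.1, 0.2, 0.3, 0.4, 0.5], [1, 1, 1, 1, 1])
        assert np.isnan(out["rho"])


class TestExperts:
    def ratings_fixture(self):
        rows = []
        # rater A perfect, rater B always wrong on NT, rater C 50%
        for rater, exp, ratings in [
            ("A", 60, [(9, 1), (8, 1), (1, 0), (2, 0)]),
            ("B", 12, [(9, 1), (8, 1), (7, 0), (6, 0)]),
            ("C", 3, [(9, 1), (2, 1), (1, 0), (8, 0)]),
        ]:
            for i, (r, lab) in enumerate(ratings):
                rows.append(
                    {"rater": rater, "subject_id": f"{rater}{i}", "rating": r,
                     "label": lab, "experience": exp}
                )
        return pd.DataFrame(rows)

    def test_hand_computed_accuracies(self):
        out = expert_comparison(self.ratings_fixture())
        assert out["per_rater_accuracy"]["A"] == 1.0
        assert out["per_rater_accuracy"]["B"] == 0.5
        assert out["per_rater_accuracy"]["C"] == 0.5
        assert out["mean_accuracy"] == pytest.approx((1.0 + 0.5 + 0.5) / 3)

    def test_boundary_rating_counts_as_positive(self):
        df = pd.DataFrame(
            [{"rater": "A", "subject_id": "x", "rating": 5.0, "label": 1,
              "experience": 10}]
        )
        assert expert_comparison(df)["per_rater_accuracy"]["A"] == 1.0


class TestLOO:
    def test_perfect_feature_gives_auc_one(self):
        rng = np.random.default_rng(0)
        labels = [1] * 5 + [0] * 5
        X = np.column_stack([
            np.array(labels) * 2.0 + rng.normal(0, 0.05, 10),
            rng.normal(size=10),
        ])
        fm = make_fm(X, labels)
        cv = loo_nested_cv(fm, grid=SMALL_GRID, n_trees=60, seed=0)
        assert cv.auc == 1.0
        assert len(cv.probabilities) == 10

    def test_one_probability_per_subject(self):
        rng = np.random.default_rng(1)
        labels = [1] * 6 + [0] * 6
        fm = make_fm(rng.normal(size=(12, 4)), labels)
        cv = loo_nested_cv(fm, grid=((4,), (2,)), n_trees=40, seed=1)
        assert len(cv.probabilities) == 12
        assert len(cv.chosen_params) == 12
        assert cv.to_frame()["subject_id"].is_unique

    def test_null_features_auc_near_half(self):
        """Pure-noise features with random labels: AUC stays in a chance
        band across seeds."""
        aucs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            labels = np.array([1] * 20 + [0] * 20)
            rng.shuffle(labels)
            fm = make_fm(rng.normal(size=(40, 20)), labels)
            cv = loo_nested_cv(fm, grid=((8,), (4,)), n_trees=60, seed=seed)
            aucs.append(cv.auc)
        aucs = np.asarray(aucs)
        assert 0.40 <= aucs.mean() <= 0.60
        assert (np.abs(aucs - 0.5) <= 0.20).mean() >= 0.85

    def test_heldout_label_leakage_free(self):
        rng = np.random.default_rng(2)
        labels = [1] * 5 + [0] * 5
        X = rng.normal(size=(10, 6))
        fm = make_fm(X, labels)
        cv = loo_nested_cv(fm, grid=((4,), (2,)), n_trees=40, seed=3)
        flipped = list(labels)
        flipped[0] = 0  # flip the first held-out subject
        fm2 = make_fm(X, flipped)
        cv2 = loo_nested_cv(fm2, grid=((4,), (2,)), n_trees=40, seed=3)
        assert cv.probabilities[0] == cv2.probabilities[0]

    def test_fixed_seed_bit_identical(self):
        rng = np.random.default_rng(4)
        labels = [1] * 6 + [0] * 6
        fm = make_fm(rng.normal(size=(12, 5)), labels)
        a = loo_nested_cv(fm, grid=SMALL_GRID, n_trees=50, seed=7)
        b = loo_nested_cv(fm, grid=SMALL_GRID, n_trees=50, seed=7)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)
        assert a.chosen_params == b.chosen_params

    def test_median_imputation_handles_missing(self):
        rng = np.random.default_rng(5)
        labels = [1] * 5 + [0] * 5
        X = rng.normal(size=(10, 4))
        X[0, 0] = np.nan
        X[3, 2] = np.nan
        fm = make_fm(X, labels)
        cv = loo_nested_cv(fm, grid=((4,), (2,)), n_trees=40, seed=0)
        assert np.all(np.isfinite(cv.probabilities))

    def test_single_class_rejected(self):
        fm = make_fm(np.zeros((4, 2)), [1, 1, 1, 1])
        with pytest.raises(ValueError):
            loo_nested_cv(fm, grid=((2,), (1,)), n_trees=10, seed=0)
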