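"""Diagnostic classification under leave-one-out with nested model selection.

Each subject is held out in turn; on the remaining subjects an inner
stratified 3-fold cross-validation selects the random-forest
hyperparameters (maximum tree depth and minimum samples per leaf, both
searched over {1, 2, 4, 8, 16, 32, 64} by default) by mean inner AUC, with
ties broken toward the simpler model (smaller depth, then larger leaf).
A forest of 1000 trees is then refit on the full training fold — with
missing features imputed by the training-fold median — and produces the
held-out subject's out-of-sample class probability.  No information from
the held-out subject ever reaches its training fold.

Derived metrics: rank-based ROC AUC (identical to the Mann-Whitney
U/(n1·n2)), threshold accuracy/sensitivity/specificity, McNemar's test
against a majority-vote baseline, and Spearman correlation of class
probability with a severity covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

DEFAULT_GRID = (1, 2, 4, 8, 16, 32, 64)
DEFAULT_N_TREES = 1000


@dataclass
class CVResult:
    """Leave-one-out cross-validation output.

    One out-of-sample probability per subject, the hyperparameters chosen
    in each outer fold, and the global threshold metrics.
    """

    subject_ids: list
    probabilities: np.ndarray
    labels: np.ndarray
    chosen_params: list = field(repr=False)
    seed: int = 0
    threshold: float = 0.5

    @property
    def predictions(self) -> np.ndarray:
        return (self.probabilities >= self.threshold).astype(int)

    @property
    def auc(self) -> float:
        return roc_auc(self.probabilities, self.labels)

    def metrics(self) -> dict[str, float]:
        out = confusion_metrics(self.probabilities, self.labels, self.threshold)
        out["auc"] = self.auc
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "probability": self.probabilities,
                "label": self.labels,
                "prediction": self.predictions,
                "max_depth": [p[0] for p in self.chosen_params],
                "min_leaf": [p[1] for p in self.chosen_params],
            }
        )


def _median_impute(train: np.ndarray, test: np.ndarray):
    """Impute NaNs by the training-fold column median (0 where the whole
    training column is NaN)."""
    med = np.nanmedian(train, axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    tr = np.where(np.isnan(train), med[None, :], train)
    te = np.where(np.isnan(test), med[None, :], test)
    return tr, te


def _fit_forest(X, y, depth, leaf, n_trees, seed):
    # balanced per-bootstrap class weights counter the one-subject class
    # imbalance that leave-one-out induces in every training fold (without
    # them, LOO probabilities are systematically biased against the
    # held-out subject's class)
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=depth,
        min_samples_leaf=leaf,
        random_state=seed,
        class_weight="balanced_subsample",
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def _inner_select(X, y, grid, n_trees, seed) -> tuple[int, int]:
    """Stratified 3-fold selection of (depth, leaf) by mean AUC.

    Ties break toward smaller depth, then larger leaf.
    """
    depths, leaves = grid
    if len(depths) == 1 and len(leaves) == 1:
        return depths[0], leaves[0]
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    best_key = None
    best = (1, 1)
    for depth in depths:
        for leaf in leaves:
            aucs = []
            for tr, te in folds:
                if len(np.unique(y[te])) < 2:
                    continue
                Xtr, Xte = _median_impute(X[tr], X[te])
                rf = _fit_forest(Xtr, y[tr], depth, leaf, n_trees, seed)
                probs = rf.predict_proba(Xte)[:, 1]
                aucs.append(roc_auc(probs, y[te]))
            if not aucs:
                continue
            # tie-break: higher AUC, then simpler (smaller depth, larger leaf)
            key = (np.mean(aucs), -depth, leaf)
            if best_key is None or key > best_key:
                best_key = key
                best = (depth, leaf)
    return best


def loo_nested_cv(
    fm,
    grid=(DEFAULT_GRID, DEFAULT_GRID),
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    inner_n_trees: int | None = None,
) -> CVResult:
    """Leave-one-out evaluation with nested hyperparameter selection.

    ``fm`` is a :class:`~sitpipe.features.FeatureMatrix`.  ``inner_n_trees``
    optionally uses a smaller forest during inner selection (default: same
    as ``n_trees``).  Fully deterministic for a fixed seed.
    """
    X = fm.data.to_numpy(float)
    y = fm.labels
    ids = fm.meta["subject_id"].tolist()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    inner_n = inner_n_trees or n_trees
    n = len(y)
    probs = np.empty(n)
    chosen = []
    for i in range(n):
        mask = np.ones(n, bool)
        mask[i] = False
        Xtr_raw, ytr = X[mask], y[mask]
        depth, leaf = _inner_select(Xtr_raw, ytr, grid, inner_n, seed)
        Xtr, Xte = _median_impute(Xtr_raw, X[i : i + 1])
        rf = _fit_forest(Xtr, ytr, depth, leaf, n_trees, seed)
        probs[i] = rf.predict_proba(Xte)[0, 1]
        chosen.append((depth, leaf))
    return CVResult(
        subject_ids=ids,
        probabilities=probs,
        labels=y,
        chosen_params=chosen,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Metrics

def roc_auc(probs, labels) -> float:
    """Rank-based AUC with half credit for ties: U/(n1·n2)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(probs)
    U = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(U / (n1 * n0))


def confusion_metrics(probs, labels, threshold: float = 0.5) -> dict[str, float]:
    """Accuracy/sensitivity/specificity at a probability threshold
    (predict the positive class when prob >= threshold)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    return {
        "accuracy": (tp + tn) / len(labels),
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


def roc_curve_points(probs, labels) -> pd.DataFrame:
    """ROC curve as a (fpr, tpr) points table, thresholds descending."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    order = np.argsort(-probs, kind="stable")
    p, l = probs[order], labels[order]
    n1 = l.sum()
    n0 = len(l) - n1
    tps = np.cumsum(l)
    fps = np.cumsum(1 - l)
    # collapse tied thresholds
    keep = np.append(np.diff(p) != 0, True)
    tpr = np.concatenate([[0.0], tps[keep] / n1])
    fpr = np.concatenate([[0.0], fps[keep] / n0])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def majority_vote_predictions(labels) -> np.ndarray:
    """Baseline predictor: always the majority class (ties → class 0)."""
    labels = np.asarray(labels, int)
    maj = 1 if labels.sum() > len(labels) - labels.sum() else 0
    return np.full(len(labels), maj)


def mcnemar_vs_baseline(preds_a, preds_b, labels) -> dict[str, float]:
    """McNemar's test on paired correctness of two predictors.

    Returns the exact two-sided binomial p on discordant pairs plus the
    continuity-corrected chi-square variant.  No discordant pairs → p = 1.
    """
    preds_a = np.asarray(preds_a, int)
    preds_b = np.asarray(preds_b, int)
    labels = np.asarray(labels, int)
    correct_a = preds_a == labels
    correct_b = preds_b == labels
    b = int((correct_a & ~correct_b).sum())  # a right, b wrong
    c = int((~correct_a & correct_b).sum())
    n_disc = b + c
    if n_disc == 0:
        return {"statistic": 0.0, "p": 1.0, "p_chi2": 1.0, "b": b, "c": c}
    p_exact = sps.binomtest(b, n_disc, 0.5).pvalue
    chi2 = (abs(b - c) - 1) ** 2 / n_disc
    p_chi2 = float(sps.chi2.sf(chi2, df=1))
    return {"statistic": float(chi2), "p": float(p_exact), "p_chi2": p_chi2, "b": b, "c": c}


def spearman_rho(x, y) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def severity_correlation(probs, covariate, exact_n_max: int = 8) -> dict[str, float]:
    """Spearman correlation (average-rank ties) of class probability with a
    severity covariate; exact permutation p for n <= 8, else t-approximation."""
    probs = np.asarray(probs, float)
    cov = np.asarray(covariate, float)
    if len(probs) != len(cov) or len(probs) < 5:
        raise ValueError("need >= 5 paired values")
    rho = spearman_rho(probs, cov)
    if np.isnan(rho):
        return {"rho": np.nan, "p": np.nan}
    n = len(probs)
    if n <= exact_n_max:
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = spearman_rho(probs, cov[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1 - rho**2, 1e-12))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return {"rho": rho, "p": float(p)}


def expert_comparison(
    ratings: pd.DataFrame, threshold: float = 5.0
) -> dict:
    """Per-rater accuracy from visual-analog-scale ratings.

    ``ratings`` has columns rater, subject_id, rating (0-10), label (0/1
    or ASD/NT) and experience (months).  A rating at or above the
    threshold counts as an ASD prediction (the boundary value is ASD).
    Returns per-rater accuracies, their mean, and the Spearman correlation
    of accuracy with experience.
    """
    df = ratings.copy()
    if df["label"].dtype == object:
        df["label"] = (df["label"] == "ASD").astype(int)
    df["pred"] = (df["rating"] >= threshold).astype(int)
    df["correct"] = (df["pred"] == df["label"]).astype(float)
    acc = df.groupby("rater")["correct"].mean()
    exp = df.groupby("rater")["experience"].first()
    out = {
        "per_rater_accuracy": acc.to_dict(),
        "mean_accuracy": float(acc.mean()),
    }
    if len(acc) >= 5 and exp.nunique() > 1:
        out["experience_correlation"] = severity_correlation(
            acc.to_numpy(), exp.to_numpy()
        )
    else:
        out["experience_correlation"] = {"rho": np.nan, "p": np.nan}
    return out
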