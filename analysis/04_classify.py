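"""Diagnostic classification per modality and combined.

Reads the feature matrix written by 02_extract_biomarkers.py and runs the
leave-one-out random-forest evaluation for each modality (face, gaze,
voice) and for all features combined, reporting AUC, threshold metrics,
the McNemar comparison against a majority vote, and the Spearman
correlation of class probability with the synthetic severity score.
Writes ``results/cv_<modality>.csv`` and ``results/metrics.json``.
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from sitpipe import classify as clf
from sitpipe.features import FeatureMatrix

HERE = os.path.dirname(__file__)
RESULTS = os.path.join(HERE, "..", "results")
COHORT = os.path.join(HERE, "..", "scratch", "cohorts", "paper")


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--trees", type=int, default=300)
    args = ap.parse_args()

    df = pd.read_csv(os.path.join(RESULTS, "features.csv"))
    fm = FeatureMatrix.from_frame(df)
    meta = pd.read_csv(os.path.join(COHORT, "metadata.csv")).set_index("subject_id")

    all_metrics = {}
    for modality in ("face", "gaze", "voice", "combined"):
        sub = fm if modality == "combined" else fm.modality(modality)
        if modality != "combined" and sub.data.shape[1] <= 1:
            continue
        cv = clf.loo_nested_cv(sub, grid=((4, 16), (2, 8)),
                               n_trees=args.trees, seed=args.seed,
                               inner_n_trees=100)
        cv.to_frame().to_csv(
            os.path.join(RESULTS, f"cv_{modality}.csv"), index=False
        )
        m = cv.metrics()
        m["mcnemar_vs_majority"] = clf.mcnemar_vs_baseline(
            cv.predictions, clf.majority_vote_predictions(cv.labels), cv.labels
        )
        sev = meta.loc[cv.subject_ids, "severity"].to_numpy(float)
        if np.std(cv.probabilities) > 0:
            m["severity_correlation"] = clf.severity_correlation(
                cv.probabilities, sev
            )
        all_metrics[modality] = m
        print(f"{modality:>8}: AUC={m['auc']:.3f} acc={m['accuracy']:.2f} "
              f"sens={m['sensitivity']:.2f} spec={m['specificity']:.2f}")

    with open(os.path.join(RESULTS, "metrics.json"), "w") as fh:
        json.dump(all_metrics, fh, indent=2, sort_keys=True)
    comb = all_metrics["combined"]
    print(f"combined vs majority vote: McNemar p="
          f"{comb['mcnemar_vs_majority']['p']:.4f}")
    if "severity_correlation" in comb:
        sc = comb["severity_correlation"]
        print(f"probability ~ severity: rho={sc['rho']:.2f} p={sc['p']:.4f}")


if __name__ == "__main__":
    main()
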