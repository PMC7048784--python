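"""Univariate group comparisons on the extracted biomarkers.

Reads the tidy tables written by 02_extract_biomarkers.py, runs the
non-parametric group tests (Mann-Whitney between groups, Wilcoxon for the
positive-vs-neutral contrasts, group x gender ANOVA for F0 and HNR) with
Holm correction per feature family, and writes ``results/stats.csv``.
"""

import os

import pandas as pd

from sitpipe import pipeline as pl

HERE = os.path.dirname(__file__)
RESULTS = os.path.join(HERE, "..", "results")
COHORT = os.path.join(HERE, "..", "scratch", "cohorts", "paper")


def main():
    meta = pd.read_csv(os.path.join(COHORT, "metadata.csv"))
    summ = pd.read_csv(os.path.join(RESULTS, "facial_biomarkers.csv"))
    mim = pd.read_csv(os.path.join(RESULTS, "mimicry.csv"))
    gz = pd.read_csv(os.path.join(RESULTS, "gaze_biomarkers.csv"))
    vt_path = os.path.join(RESULTS, "voice_features.csv")
    vt = pd.read_csv(vt_path) if os.path.exists(vt_path) else None

    stats_df = pl.group_statistics(summ, mim, gz, vt, meta)
    stats_df.to_csv(os.path.join(RESULTS, "stats.csv"), index=False)

    sig = stats_df[stats_df.adjusted_p < 0.05]
    print(f"{len(stats_df)} tests; {len(sig)} significant after Holm correction:")
    cols = ["family", "feature", "test", "statistic", "p", "adjusted_p", "effect_size"]
    with pd.option_context("display.width", 120):
        print(sig[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
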