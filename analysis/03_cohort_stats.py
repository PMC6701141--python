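#!/usr/bin/env python
"""Group statistics on the template cohort (unstable vs stable arousal).

Runs the full cohort analysis -- t-tests (Welch when the variance ratio
triggers), Pearson chi-square for nominal variables, signed Eta and Eta^2,
Cohen's d for the band powers -- on the cohort written by
02_simulate_cohort.py, and summarises which contrasts separate the groups.

Expected finding at template n (a single draw, so subject to sampling
noise): the BDI contrast and most delta/theta power contrasts are
significant; CAARS/ASRS/WURS-K and the alpha/beta powers are not.

Output: results/group_stats.csv
"""

from pathlib import Path

from arousalkit.io import read_cohort
from arousalkit.stats import cohort_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    cohort_path = OUT / "cohort.csv"
    if not cohort_path.exists():
        raise SystemExit("run analysis/02_simulate_cohort.py first")
    report = cohort_analysis(read_cohort(cohort_path))
    report.to_csv(OUT / "group_stats.csv", index=False)
    cols = ["variable", "test", "statistic", "df", "p", "eta", "eta2", "cohens_d"]
    print(report[cols].round(3).to_string(index=False))
    sig = report.loc[report.p < 0.05, "variable"].tolist()
    print(f"\nsignificant at p < 0.05: {sig}")


if __name__ == "__main__":
    main()
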