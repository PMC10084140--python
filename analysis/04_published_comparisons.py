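"""Recompute the published worked-example statistics from printed summaries.

The study's raw images were never deposited; its group tables print mean,
SD and n per outcome, which fully determine the pooled-SD Cohen's d, the
Student-t statistic and the 95% CI of the mean difference. This script
recomputes all of them through the summary-statistic path of the stats
module and writes results/published_effect_sizes.csv.

Usage: python analysis/04_published_comparisons.py
"""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from musclemorph.published import MORPHOLOGY_SUMMARIES, SIMILARITY_SUMMARIES
from musclemorph.stats import ttest_independent

ROOT = Path(__file__).resolve().parents[1]


def main():
    rows = []
    for outcome, groups in SIMILARITY_SUMMARIES.items():
        res = ttest_independent(groups["healthy"], groups["aclr"],
                                outcome=outcome, contrast="healthy_vs_aclr")
        rows.append(res.to_row())
    for outcome, groups in MORPHOLOGY_SUMMARIES.items():
        res = ttest_independent(groups["injured_aclr"], groups["healthy"],
                                outcome=outcome,
                                contrast="injured_vs_healthy_average")
        rows.append(res.to_row())
        res = ttest_independent(groups["uninjured_aclr"], groups["healthy"],
                                outcome=outcome,
                                contrast="uninjured_vs_healthy_average")
        rows.append(res.to_row())

    df = pd.DataFrame(rows)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    df.to_csv(out / "published_effect_sizes.csv", index=False)
    cols = ["outcome", "contrast", "mean_difference", "ci95_low", "ci95_high",
            "cohens_d", "effect_label"]
    print(df[cols].round(3).to_string(index=False))
    print(f"\nwritten to {out/'published_effect_sizes.csv'}")


if __name__ == "__main__":
    main()
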