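"""Group statistics on the pipeline outputs.

Consumes the tidy tables written by 02_run_pipeline.py and emits the study
report: group summaries, between-group similarity t-tests, per-outcome
group-by-limb mixed-ANOVA interactions with post-hoc contrasts, and the
tendon-regeneration subgroup comparisons.

Usage: python analysis/03_group_statistics.py
"""

from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from musclemorph.stats import cohort_report

ROOT = Path(__file__).resolve().parents[1]


def main():
    res = ROOT / "results"
    sim = pd.read_csv(res / "similarity.csv")
    morph = pd.read_csv(res / "morphology.csv")
    meta = pd.read_csv(res / "meta.csv")

    report = cohort_report(sim, morph, meta)
    for name in ("demographics", "similarity_groups", "morphology_groups",
                 "anova", "comparisons", "regeneration"):
        report[name].to_csv(res / f"{name}.csv", index=False)

    print("== similarity (healthy vs reconstructed) ==")
    print(report["similarity_groups"].to_string(index=False))
    print("\n== group-by-limb interactions ==")
    print(report["anova"].to_string(index=False))
    sig = report["comparisons"].query("p_value < 0.05")
    print(f"\n{len(sig)} significant contrasts at p < 0.05; "
          f"full table in {res/'comparisons.csv'}")


if __name__ == "__main__":
    main()
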