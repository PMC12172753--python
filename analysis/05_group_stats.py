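"""Group-level inference: repeated-measures ANOVAs and post-hoc tests.

Muscle x Intensity ANOVAs on the centroid components and area size,
Muscle-Group x Intensity on the pair overlaps, with Mauchly sphericity
checks, Greenhouse-Geisser correction where indicated, and
Bonferroni-corrected pairwise post-hocs.
"""

import pandas as pd

from common import results_dir
from tmsmap.pipeline import group_statistics


def main() -> None:
    out = results_dir()
    metrics = pd.read_csv(out / "metrics.csv")
    overlaps = pd.read_csv(out / "overlaps.csv")
    anova_tables, posthoc_tables = group_statistics(metrics, overlaps)

    for name, tab in anova_tables.items():
        tab.to_csv(out / f"anova_{name}.csv")
    for name, tab in posthoc_tables.items():
        tab.to_csv(out / f"posthoc_{name}.csv", index=False)

    cols = ["F", "df1", "df2", "gg_epsilon", "gg_applied", "p"]
    for name in ["Cy", "W_size", "overlap"]:
        print(f"\nANOVA — {name}:")
        print(anova_tables[name][cols].round(4).to_string())
    ph = posthoc_tables["overlap_pair_group"]
    print("\nBonferroni post-hoc, overlap by pair group:")
    print(ph[["level_a", "level_b", "mean_diff", "t", "p_adj"]].round(4).to_string(index=False))
    print(f"\nwrote ANOVA and post-hoc tables -> {out}")


if __name__ == "__main__":
    main()
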