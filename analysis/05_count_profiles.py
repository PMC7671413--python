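#!/usr/bin/env python
"""The two regimes of sequencing count data, profiled and categorized.

Generates an RNA-seq-like matrix (log-normal profile, few zeros) and a
metagenome-like matrix (Zipf tail + turnover, zero-dominated), profiles
both with log-like count bins, classifies features into the six
abundance/rarity categories (AAT/CAT/ART/CRT/MT/CRAT at 0.01% and 1%
relative abundance), and compares low-abundance filters.

Writes results/profile_{rnaseq,metagenome}_{bins,categories,filters}.csv.
"""

from pathlib import Path

import pandas as pd

import latticecoda as lc

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 2026


def profile_one(name: str, counts) -> None:
    zero_frac = (counts == 0).mean()
    print(f"\n== {name}: {counts.shape[0]} samples x {counts.shape[1]} features, "
          f"{zero_frac:.1%} zeros ==")

    _, bin_summary = lc.bin_profile(counts)
    bin_summary.to_csv(OUT / f"profile_{name}_bins.csv")

    cats = lc.classify_taxa(counts)
    cat_summary = lc.category_summary(counts, cats)
    cat_summary.to_csv(OUT / f"profile_{name}_categories.csv", index=False)
    print(cat_summary[["category", "n_features", "pct_features",
                       "pct_sequences"]].to_string(index=False))

    filt_rows = []
    for label, rule, t in [
        ("rel_abundance>=1e-4", "rel_abundance", 1e-4),
        ("rel_abundance>=1e-3", "rel_abundance", 1e-3),
        ("max_count>=2", "max_count", 2),
        ("max_count>=10", "max_count", 10),
    ]:
        _, summ = lc.filter_features(counts, rule=rule, threshold=t)
        filt_rows.append({"filter": label, **summ.as_dict()})
    pd.DataFrame(filt_rows).to_csv(OUT / f"profile_{name}_filters.csv", index=False)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    profile_one("rnaseq", lc.rnaseq_like(seed=SEED))
    profile_one("metagenome", lc.metagenome_like(seed=SEED))
    print("\nrare categories dominate the survey regime; the transcriptome "
          "regime keeps moderate/abundant features")


if __name__ == "__main__":
    main()
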