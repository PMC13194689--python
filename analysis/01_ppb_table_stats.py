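#!/usr/bin/env python
"""PPB-category contingency statistics.

Runs the two-sided Fisher's exact test on each row of the published
wild-type vs katanin-mutant PPB tally (161 vs 182 symmetrically dividing
cells) against the rest of the table, applies the Bonferroni threshold
0.05/7, and writes the per-category table with p-values and calls.

Finding: normal, uneven, one-sided and misoriented PPBs differ between
genotypes at the 0.007 threshold; four-sided, three-sided and split do not.
"""

from pathlib import Path

import pandas as pd

from katquant.division import (
    BONFERRONI_ALPHA,
    PPB_CATEGORIES,
    category_fisher_tests,
    reference_count_table,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = reference_count_table()
    results = category_fisher_tests(table)
    rows = []
    for cat in PPB_CATEGORIES:
        r = results[cat]
        wt, mut = table.counts[cat]
        rows.append({
            "category": cat,
            "wild_type": wt,
            "mutant": mut,
            "wt_percent": round(100 * wt / table.totals[0], 1),
            "mut_percent": round(100 * mut / table.totals[1], 1),
            "p_value": r.p_value,
            "significant": r.extra["significant"],
        })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "ppb_table_tests.csv", index=False)
    threshold = BONFERRONI_ALPHA / len(PPB_CATEGORIES)
    print(f"n = {table.totals} cells; Bonferroni threshold {threshold:.4g}")
    print(df.to_string(index=False))
    sig = df.loc[df.significant, "category"].tolist()
    print(f"\ncategories differing between genotypes: {', '.join(sig)}")


if __name__ == "__main__":
    main()
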