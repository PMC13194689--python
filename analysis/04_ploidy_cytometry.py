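#!/usr/bin/env python
"""DNA-content cytometry on synthetic nuclear populations.

Generates per-image gain-shifted 2N/S/4N integrated-density mixtures at the
study's sample sizes (~3076 wild-type-like and ~4124 mutant-like nuclei over
3 images each), normalizes each image by its modal 2N peak, bins phases, and
tests the G1 (2N) shift with a 2x2 chi-square.

Finding: normalization removes the 0.8-1.5x per-image gains; the recovered
2N percentages preserve the generated wild-type/mutant difference and the 2N
shift is highly significant at these sample sizes. The bracket estimator
systematically undercounts S (most S-phase densities fall inside the 2N/4N
brackets) — an inherent property of bracket binning, quantified here.
"""

from pathlib import Path

import pandas as pd

from katquant.ploidy import classify_phases, normalize_by_modal_peak
from katquant.stats import chi_square_independence
from katquant.synth import gen_nuclei_population

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1

SCENARIOS = {
    "wild_type": {"fractions": (0.69, 0.05, 0.18), "n_per_image": 1026},
    "mutant": {"fractions": (0.73, 0.08, 0.12), "n_per_image": 1375},
}


def main() -> None:
    rows = []
    phases = {}
    for i, (name, sc) in enumerate(SCENARIOS.items()):
        measures, truth = gen_nuclei_population(
            fractions=sc["fractions"], n_per_image=sc["n_per_image"],
            per_image_gains=(0.8, 1.0, 1.5), seed=SEED + i)
        ph = classify_phases(normalize_by_modal_peak(measures))
        phases[name] = ph
        for key, true_f in zip(("2N", "S", "4N"), sc["fractions"]):
            rows.append({
                "genotype": name, "phase": key,
                "true_fraction": true_f,
                "recovered_fraction": round(ph.fractions[key], 4),
                "recovered_count": {"2N": ph.n_2N, "S": ph.n_S, "4N": ph.n_4N}[key],
                "n_total": ph.total,
            })
    df = pd.DataFrame(rows)
    table = [[phases["wild_type"].n_2N,
              phases["wild_type"].total - phases["wild_type"].n_2N],
             [phases["mutant"].n_2N, phases["mutant"].total - phases["mutant"].n_2N]]
    res = chi_square_independence(table)

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "ploidy_fractions.csv", index=False)
    print(df.to_string(index=False))
    print(f"\n2N-vs-rest chi-square: statistic {res.statistic:.1f}, "
          f"p = {res.p_value:.2g} "
          f"(n = {phases['wild_type'].total} + {phases['mutant'].total} nuclei)")


if __name__ == "__main__":
    main()
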