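#!/usr/bin/env python
"""Division geometry: nuclear positioning by PPB category, mitotic
proportions, and division timing.

Generates division records at the published category frequencies with
category-dependent nuclear offsets (centered for normal PPBs, shifted toward
the dominant microtubule accumulation for uneven/one-sided/misoriented),
then summarizes nuclear offset and axis position per category, recovers a
mitotic proportion, and fits phragmoplast expansion on synthetic tracks.

Finding: offset-category cells show nuclei displaced toward the accumulation
side (axis position > 50%), normal-PPB cells center near 50%; the mitotic
proportion and expansion-rate estimators recover their ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from katquant.division import (
    REFERENCE_PPB_COUNTS,
    DivisionTimelapse,
    mitotic_proportion,
    nuclear_offset_percent,
    nuclear_position_along_axis,
    phragmoplast_expansion_rate,
)
from katquant.synth import gen_division_records, gen_stage_records

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    mut_total = sum(v[1] for v in REFERENCE_PPB_COUNTS.values())
    probs = {"mutant": {c: v[1] / mut_total for c, v in REFERENCE_PPB_COUNTS.items()}}
    records = gen_division_records(probs, {"mutant": 4 * mut_total}, seed=SEED)

    rows = []
    for cat in sorted({r.ppb_category for r in records}):
        group = [r for r in records if r.ppb_category == cat]
        offsets = [nuclear_offset_percent(r) for r in group]
        positions = [nuclear_position_along_axis(r) for r in group]
        rows.append({
            "category": cat,
            "n_cells": len(group),
            "mean_offset_pct": round(float(np.mean(offsets)), 2),
            "mean_axis_position_pct": round(float(np.mean(positions)), 2),
        })
    df = pd.DataFrame(rows)

    stage_records = gen_stage_records(2000, p_division=0.15, seed=SEED)
    prop = mitotic_proportion(stage_records)

    rng = np.random.default_rng(SEED)
    rates = []
    for _ in range(69):
        n_frames = int(rng.integers(5, 9))
        t = np.arange(n_frames) * 10.0
        tl = DivisionTimelapse(
            cell_id="sim", frame_interval=10.0, stages=("telophase",) * n_frames,
            phragmoplast_length=tuple(0.31 * t + rng.normal(0, 0.3, n_frames)))
        rates.append(phragmoplast_expansion_rate(tl))

    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "division_geometry.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nmitotic proportion: true 0.15, recovered {prop:.3f} (n = 2000 cells)")
    print(f"phragmoplast expansion: true 0.31, recovered "
          f"{np.mean(rates):.3f} +- {np.std(rates) / np.sqrt(len(rates)):.3f} SE um/min "
          f"(n = {len(rates)} tracks)")


if __name__ == "__main__":
    main()
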