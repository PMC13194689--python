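"""Preprophase-band (PPB) bookkeeping, nuclear-positioning geometry, and
division timing.

The PPB is a cortical microtubule ring that forms before mitosis and marks
the future division plane. Each dividing cell is annotated (by eye, not from
pixels) with a PPB category; categories are tallied per genotype and each
category is tested 2x2 (category vs rest, by genotype) with a two-sided
Fisher's exact test under a Bonferroni threshold of 0.05/7.

Nuclear-positioning metrics use the cell's long axis:

* offset percent — distance between nucleus centroid and cell centroid,
  normalized by the full long-axis length, x100;
* position along axis — projection of the nucleus onto the long axis as a
  percentage of its length, with 0% at the end opposite the dominant
  microtubule accumulation and 100% at the accumulation itself (50 = mid-cell).

Division timing comes from 10-minute-interval time-lapses: stage durations
use inclusive frame counting (frames-in-stage x interval), and the
phragmoplast expansion rate is the least-squares slope of phragmoplast
length on time over the telophase window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress
from shapely.geometry import Polygon

from .stats import TestResult, bonferroni, fisher_exact_two_sided

__all__ = [
    "DivisionCellRecord",
    "PPBCountTable",
    "DivisionTimelapse",
    "PPB_CATEGORIES",
    "REFERENCE_PPB_COUNTS",
    "BONFERRONI_ALPHA",
    "nuclear_offset_percent",
    "nuclear_position_along_axis",
    "tally_and_test",
    "mitotic_proportion",
    "stage_durations",
    "phragmoplast_expansion_rate",
]

STAGES = ("interphase", "ppb", "metaphase", "telophase")
MITOTIC_STAGES = ("ppb", "metaphase", "telophase")
PPB_CATEGORIES = (
    "normal",
    "four_sided",
    "three_sided",
    "split",
    "uneven",
    "one_sided",
    "misoriented",
)

#: family-wise alpha for the per-category Fisher tests (7 categories)
BONFERRONI_ALPHA = 0.05

#: Published PPB-category tallies for symmetric divisions in the maize
#: katanin study this pipeline models: wild-type siblings (n = 161 cells)
#: vs double-mutant (n = 182 cells), three plants per genotype.
REFERENCE_PPB_COUNTS = {
    "normal": (147, 84),
    "four_sided": (1, 1),
    "three_sided": (2, 9),
    "split": (3, 5),
    "uneven": (8, 58),
    "one_sided": (0, 16),
    "misoriented": (0, 9),
}


@dataclass(frozen=True)
class DivisionCellRecord:
    """One annotated dividing (or interphase) cell."""

    cell_id: str
    plant_id: str
    genotype: str
    stage: str
    ppb_category: str = "none"
    cell_polygon: tuple = ()  # (x_um, y_um) vertices
    long_axis_direction: tuple = (1.0, 0.0)  # unit vector
    long_axis_length: float = 0.0  # um
    nucleus_centroid: tuple = (0.0, 0.0)  # (x_um, y_um)
    ppb_axis_position: float | None = None  # fraction of long axis in [0, 1]
    dominant_accumulation_side: str = "none"  # {left, right, none}

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if (self.ppb_category != "none") != (self.stage == "ppb"):
            raise ValueError("ppb_category must be set exactly when stage == 'ppb'")
        if self.ppb_category != "none" and self.ppb_category not in PPB_CATEGORIES:
            raise ValueError(f"unknown ppb_category {self.ppb_category!r}")
        if self.ppb_axis_position is not None and not (0.0 <= self.ppb_axis_position <= 1.0):
            raise ValueError("ppb_axis_position must lie in [0, 1]")
        if self.dominant_accumulation_side not in ("left", "right", "none"):
            raise ValueError("dominant_accumulation_side must be left, right, or none")


@dataclass(frozen=True)
class PPBCountTable:
    """Category x genotype counts with per-genotype totals."""

    counts: dict  # category -> (count per genotype, ordered as `genotypes`)
    genotypes: tuple
    totals: tuple

    def __post_init__(self) -> None:
        sums = [0] * len(self.genotypes)
        for row in self.counts.values():
            for i, v in enumerate(row):
                sums[i] += v
        if tuple(sums) != tuple(self.totals):
            raise ValueError("category counts do not sum to genotype totals")


@dataclass(frozen=True)
class DivisionTimelapse:
    """Stage labels (and telophase phragmoplast lengths) per frame."""

    cell_id: str
    frame_interval: float  # min
    stages: tuple  # per-frame stage labels
    phragmoplast_length: tuple = ()  # um, NaN outside telophase

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        order = {s: i for i, s in enumerate(STAGES)}
        idx = [order[s] for s in self.stages]
        if any(b < a for a, b in zip(idx, idx[1:])):
            raise ValueError("stages must be in temporal order (ppb -> metaphase -> telophase)")
        if self.phragmoplast_length and len(self.phragmoplast_length) != len(self.stages):
            raise ValueError("phragmoplast_length must align with stages")


def _cell_centroid(record: DivisionCellRecord) -> np.ndarray:
    poly = Polygon(record.cell_polygon)
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate cell polygon")
    return np.array([poly.centroid.x, poly.centroid.y])


def nuclear_offset_percent(record: DivisionCellRecord) -> float:
    """Distance from nucleus centroid to cell centroid, % of long-axis length.

    Normalization uses the full long-axis length (not the half-length).
    """
    if record.long_axis_length <= 0:
        raise ValueError("long_axis_length must be positive")
    c = _cell_centroid(record)
    d = float(np.hypot(*(np.asarray(record.nucleus_centroid) - c)))
    return 100.0 * d / record.long_axis_length


def nuclear_position_along_axis(record: DivisionCellRecord) -> float:
    """Nucleus position projected on the long axis, % in [0, 100].

    0% is the cell end opposite the dominant microtubule accumulation, 100%
    the accumulation end, 50% mid-cell. With no dominant side recorded, the
    axis direction as given defines the 100% end.
    """
    if record.long_axis_length <= 0:
        raise ValueError("long_axis_length must be positive")
    c = _cell_centroid(record)
    d = np.asarray(record.long_axis_direction, dtype=float)
    norm = np.hypot(*d)
    if norm == 0:
        raise ValueError("long_axis_direction must be nonzero")
    d = d / norm
    if record.dominant_accumulation_side == "left":
        d = -d
    proj = float(np.dot(np.asarray(record.nucleus_centroid) - c, d))
    pos = 50.0 + 100.0 * proj / record.long_axis_length
    return float(np.clip(pos, 0.0, 100.0))


def tally_and_test(records, alpha: float = BONFERRONI_ALPHA):
    """Tally PPB categories per genotype and Fisher-test each category vs rest.

    Only stage == 'ppb' records enter the tally. Returns the count table and
    a dict category -> TestResult carrying the Bonferroni per-test threshold
    alpha / 7.
    """
    ppb_records = [r for r in records if r.stage == "ppb"]
    genotypes = tuple(sorted({r.genotype for r in ppb_records}))
    if len(genotypes) < 2:
        raise ValueError("need at least two genotypes")
    counts = {
        cat: tuple(
            sum(1 for r in ppb_records if r.genotype == g and r.ppb_category == cat)
            for g in genotypes
        )
        for cat in PPB_CATEGORIES
    }
    totals = tuple(sum(1 for r in ppb_records if r.genotype == g) for g in genotypes)
    table = PPBCountTable(counts=counts, genotypes=genotypes, totals=totals)
    return table, category_fisher_tests(table, alpha=alpha)


def category_fisher_tests(table: PPBCountTable, alpha: float = BONFERRONI_ALPHA) -> dict:
    """Per-category 2x2 Fisher tests (category vs rest, by genotype) on a tally."""
    if len(table.genotypes) != 2:
        raise ValueError("per-category 2x2 tests require exactly two genotypes")
    threshold = alpha / len(PPB_CATEGORIES)
    results = {}
    raw = []
    for cat in PPB_CATEGORIES:
        a, b = table.counts.get(cat, (0, 0))
        t = np.array([[a, table.totals[0] - a], [b, table.totals[1] - b]])
        res = fisher_exact_two_sided(t)
        res.threshold = threshold
        results[cat] = res
        raw.append(res.p_value)
    for cat, (adj, sig) in zip(PPB_CATEGORIES, bonferroni(raw, alpha=alpha)):
        results[cat].extra["adjusted_p"] = adj
        results[cat].extra["significant"] = sig
    return results


def reference_count_table() -> PPBCountTable:
    """The published wild-type vs mutant PPB tally as a PPBCountTable."""
    wt = sum(v[0] for v in REFERENCE_PPB_COUNTS.values())
    mut = sum(v[1] for v in REFERENCE_PPB_COUNTS.values())
    return PPBCountTable(
        counts=dict(REFERENCE_PPB_COUNTS),
        genotypes=("wild_type", "mutant"),
        totals=(wt, mut),
    )


def mitotic_proportion(records) -> float:
    """Fraction of cells in a division stage (PPB/late G2 through telophase)."""
    records = list(records)
    if not records:
        raise ValueError("no records")
    return sum(1 for r in records if r.stage in MITOTIC_STAGES) / len(records)


def stage_durations(tl: DivisionTimelapse) -> dict:
    """Metaphase / telophase / total durations in minutes.

    Inclusive frame counting: a stage spanning k frames lasts k x interval.
    Metaphase runs from the first PPB-free frame to the last pre-telophase
    frame; telophase from the first phragmoplast frame to disassembly.
    Stages absent from the record yield None.
    """
    stages = list(tl.stages)
    meta = stages.count("metaphase")
    telo = stages.count("telophase")
    meta_min = meta * tl.frame_interval if meta else None
    telo_min = telo * tl.frame_interval if telo else None
    total = (meta_min or 0.0) + (telo_min or 0.0)
    return {
        "metaphase_min": meta_min,
        "telophase_min": telo_min,
        "total_min": total if (meta or telo) else None,
    }


def phragmoplast_expansion_rate(tl: DivisionTimelapse) -> float:
    """Least-squares slope (um/min) of phragmoplast length over telophase frames."""
    if not tl.phragmoplast_length:
        raise ValueError("no phragmoplast lengths recorded")
    lengths = np.asarray(tl.phragmoplast_length, dtype=float)
    frames = np.arange(len(lengths))
    sel = np.array([s == "telophase" for s in tl.stages]) & np.isfinite(lengths)
    if sel.sum() < 2:
        raise ValueError("need at least 2 telophase frames with lengths")
    t = frames[sel] * tl.frame_interval
    y = lengths[sel]
    if np.all(y == y[0]):
        return 0.0
    return float(linregress(t, y).slope)
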