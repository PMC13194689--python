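"""Leaf epidermis morphometry, cell-count extrapolation, and leaf projections.

Cell outlines (pavement cells and stomatal complexes, traced from glue
impressions of the leaf base, middle and tip) drive three analyses:

* per-cell shape metrics — area, length/width from the minimum-area bounding
  rectangle, and the elongation ratio length/width;
* whole-leaf cell-count extrapolation — each third of the leaf contributes
  (leaf area / 3) x (cells per sampled area), where a stomatal complex counts
  as 4 cells (2 guard + 2 subsidiary):

      Total ~= sum_r (A/3) * [PC_r + 4*SC_r] / [sum PCA_r + sum SCA_r]

* four leaf projections that ask what a wild-type leaf would look like with
  mutant cell dimensions (1), mutant cell areas (2), mutant cell numbers (3),
  or both mutant cell number and area (4).

Outline coordinates are um; leaf dimensions are mm (converted internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress
from shapely.geometry import Polygon

__all__ = [
    "CellOutline",
    "RegionSample",
    "LeafRecord",
    "CellStats",
    "ProjectionResult",
    "REGIONS",
    "cell_shape_metrics",
    "estimate_total_cells",
    "summarize_cells",
    "project_leaf",
    "elongation_rate",
]

REGIONS = ("base", "middle", "tip")
CELL_CLASSES = ("pavement", "stomatal_complex")

#: cells per stomatal complex in the count extrapolation (2 guard + 2 subsidiary)
STOMATAL_COMPLEX_CELLS = 4


def _shoelace_area(vertices) -> float:
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        area += x0 * y1 - x1 * y0
    return abs(area) / 2.0


@dataclass(frozen=True)
class CellOutline:
    """A traced cell boundary polygon (um) with class and leaf-region labels.

    Construction checks labels and positive shoelace area (cheap, since
    mosaics hold hundreds of thousands of outlines); ``validate()`` runs the
    full simple-polygon check via shapely.
    """

    vertices: tuple  # of (x_um, y_um)
    cell_class: str
    region: str

    def __post_init__(self) -> None:
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"unknown cell_class {self.cell_class!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if len(self.vertices) < 3 or _shoelace_area(self.vertices) <= 0:
            raise ValueError("outline must have >= 3 vertices and positive area")

    def validate(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError("outline must be a simple (non-self-intersecting) polygon")

    @property
    def area(self) -> float:
        """Shoelace area in um^2."""
        return _shoelace_area(self.vertices)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class RegionSample:
    """All outlines sampled from one leaf region (>= 1 micrograph)."""

    region: str
    outlines: tuple  # of CellOutline
    micrograph_count: int = 1

    def __post_init__(self) -> None:
        if not self.outlines:
            raise ValueError("a region sample needs at least one outline")
        for o in self.outlines:
            if o.region != self.region:
                raise ValueError("all outlines must share the sample's region label")


@dataclass(frozen=True)
class LeafRecord:
    """One leaf: gross dimensions plus base/middle/tip region samples."""

    leaf_id: str
    genotype: str
    total_leaf_area: float  # mm^2
    leaf_length: float  # mm
    leaf_width: float  # mm
    samples: dict  # region -> RegionSample

    def __post_init__(self) -> None:
        if self.total_leaf_area <= 0:
            raise ValueError("total_leaf_area must be positive")
        if set(self.samples) != set(REGIONS):
            raise ValueError("need exactly one sample per region (base, middle, tip)")


@dataclass(frozen=True)
class CellStats:
    mean_length: float  # um
    mean_width: float  # um
    mean_area: float  # um^2
    mean_lw_ratio: float
    n_cells: int


@dataclass(frozen=True)
class ProjectionResult:
    mode: int
    projected_area: float  # mm^2
    projected_length: float | None  # mm; None for area-only modes 2 and 4
    projected_width: float | None  # mm
    pct_of_wildtype: float
    pct_of_mutant: float | None = None


def cell_shape_metrics(outline) -> tuple[float, float, float, float]:
    """(area um^2, length um, width um, length/width) for one outline.

    Length and width are the long and short sides of the minimum-area
    bounding rectangle, making the metrics rotation-invariant.
    """
    poly = outline.polygon if isinstance(outline, CellOutline) else Polygon(outline)
    area = poly.area
    if area <= 0:
        raise ValueError("degenerate polygon")
    mrr = poly.minimum_rotated_rectangle
    coords = np.asarray(mrr.exterior.coords)[:4]
    e1 = float(np.hypot(*(coords[1] - coords[0])))
    e2 = float(np.hypot(*(coords[2] - coords[1])))
    length, width = max(e1, e2), min(e1, e2)
    if width <= 0:
        raise ValueError("degenerate polygon")
    return float(area), length, width, length / width


def summarize_cells(outlines, cell_class: str | None = None) -> CellStats:
    """Arithmetic-mean shape statistics over outlines, optionally filtered by class."""
    if cell_class is not None:
        outlines = [o for o in outlines if o.cell_class == cell_class]
    else:
        outlines = list(outlines)
    if not outlines:
        raise ValueError("no outlines after filtering")
    metrics = np.array([cell_shape_metrics(o) for o in outlines])
    return CellStats(
        mean_area=float(metrics[:, 0].mean()),
        mean_length=float(metrics[:, 1].mean()),
        mean_width=float(metrics[:, 2].mean()),
        mean_lw_ratio=float(metrics[:, 3].mean()),
        n_cells=len(outlines),
    )


def estimate_total_cells(leaf: LeafRecord) -> float:
    """Extrapolate the whole-leaf epidermal cell count from region samples.

    Each region contributes one third of the leaf area times its sampled
    cells-per-area, with stomatal complexes weighted as 4 cells.
    """
    leaf_area_um2 = leaf.total_leaf_area * 1e6  # mm^2 -> um^2
    total = 0.0
    for region in REGIONS:
        sample = leaf.samples[region]
        pc = sum(1 for o in sample.outlines if o.cell_class == "pavement")
        sc = sum(1 for o in sample.outlines if o.cell_class == "stomatal_complex")
        summed_area = sum(o.area for o in sample.outlines)
        if summed_area <= 0:
            raise ValueError(f"zero summed outline area in region {region!r}")
        total += (leaf_area_um2 / 3.0) * (pc + STOMATAL_COMPLEX_CELLS * sc) / summed_area
    return total


def project_leaf(
    wt_leaf: LeafRecord,
    wt_stats: CellStats,
    wt_count: float,
    mut_stats: CellStats,
    mut_count: float,
    mode: int,
    mut_leaf_area: float | None = None,
) -> ProjectionResult:
    """Project a hypothetical wild-type leaf under mutant cell properties.

    mode 1: mutant cell length/width x wild-type cells along each axis
            (leaf_length / mean cell length, leaf_width / mean cell width;
            real-valued, not rounded);
    mode 2: wild-type cell number x mutant mean cell area (area only);
    mode 3: mutant cell number x wild-type mean cell area, length/width laid
            out in the wild-type leaf aspect ratio;
    mode 4: mutant cell number x mutant mean cell area (area only).
    """
    if mode not in (1, 2, 3, 4):
        raise ValueError("mode must be 1, 2, 3, or 4")
    if min(wt_count, mut_count, wt_stats.mean_area, mut_stats.mean_area) <= 0:
        raise ValueError("counts and means must be positive")
    length = width = None
    if mode == 1:
        n_long = wt_leaf.leaf_length * 1000.0 / wt_stats.mean_length
        n_short = wt_leaf.leaf_width * 1000.0 / wt_stats.mean_width
        length = n_long * mut_stats.mean_length / 1000.0
        width = n_short * mut_stats.mean_width / 1000.0
        area = length * width
    elif mode == 2:
        area = wt_count * mut_stats.mean_area / 1e6
    elif mode == 3:
        area = mut_count * wt_stats.mean_area / 1e6
        aspect = wt_leaf.leaf_length / wt_leaf.leaf_width
        length = float(np.sqrt(area * aspect))
        width = float(np.sqrt(area / aspect))
    else:  # mode 4
        area = mut_count * mut_stats.mean_area / 1e6
    return ProjectionResult(
        mode=mode,
        projected_area=float(area),
        projected_length=length,
        projected_width=width,
        pct_of_wildtype=100.0 * area / wt_leaf.total_leaf_area,
        pct_of_mutant=(100.0 * area / mut_leaf_area) if mut_leaf_area else None,
    )


def elongation_rate(times_hr, lengths_mm) -> float:
    """Ordinary least-squares slope of organ length on time, mm/hr."""
    times_hr = np.asarray(times_hr, dtype=float)
    lengths_mm = np.asarray(lengths_mm, dtype=float)
    if times_hr.size != lengths_mm.size or times_hr.size < 3:
        raise ValueError("need at least 3 matched (time, length) points")
    return float(linregress(times_hr, lengths_mm).slope)
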