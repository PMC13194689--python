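"""Seeded synthetic-data generators with known ground truth.

Every pipeline input can be generated here, so each stage is testable
against exact ground truth without any imaging data:

* epidermis mosaics — a leaf rectangle tiled by jittered-grid cells in three
  regions (base, middle, tip) with region-dependent cell dimensions and a
  configurable stomatal-complex fraction; the exact generated cell count is
  returned alongside the sampled outlines;
* filament images — anti-aliased line segments whose orientations follow an
  axial von Mises distribution (concentration kappa, folded to [0, 180)),
  plus Gaussian noise, emulating cortical microtubule arrays;
* severing-event streams — homogeneous Poisson events in area x time;
* nuclear populations — per-image gain-shifted 2N/S/4N integrated-density
  mixtures with multiplicative noise and disk-consistent geometry;
* division records — multinomial (or exact-quota) PPB-category draws with
  category-dependent nuclear offsets toward the dominant accumulation side.

All generators are pure functions of (parameters, seed): identical calls
give identical outputs. Quota mode turns categorical sampling into exact
counts so printed tallies can be reproduced verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .division import PPB_CATEGORIES, DivisionCellRecord
from .leaf import CellOutline, LeafRecord, RegionSample, REGIONS
from .microtubules import IntensityImage, SeveringRecord
from .ploidy import NucleusMeasure

__all__ = [
    "GeneratorConfig",
    "OffsetModel",
    "gen_epidermis_mosaic",
    "gen_filament_image",
    "gen_severing_series",
    "gen_nuclei_population",
    "gen_division_records",
    "gen_stage_records",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Seed plus free-form scenario parameters for one generator call."""

    seed: int
    params: dict = field(default_factory=dict)


# Default cell dimensions (length, width in um) per leaf region for the
# mosaic generator. Basal cells are youngest and shortest; cells lengthen
# toward the tip of an expanded maize leaf blade.
DEFAULT_REGION_CELL_SIZE = {
    "base": (60.0, 18.0),
    "middle": (100.0, 20.0),
    "tip": (80.0, 20.0),
}


def _jittered_partition(rng, total: float, n: int, cv: float) -> np.ndarray:
    """n positive segment lengths with relative spread cv, summing exactly to total."""
    raw = np.maximum(rng.normal(1.0, cv, size=n), 0.1)
    return raw * (total / raw.sum())


def gen_epidermis_mosaic(
    leaf_length_mm: float = 50.0,
    leaf_width_mm: float = 10.0,
    region_cell_size: dict | None = None,
    size_cv: float = 0.15,
    stomatal_fraction: float = 0.25,
    sample_fraction: float = 1.0,
    seed: int = 0,
    leaf_id: str = "synthetic",
    genotype: str = "synthetic",
) -> tuple[LeafRecord, int]:
    """Tile a rectangular leaf with epidermal cells and sample its regions.

    The leaf is split lengthwise into three equal-area regions tiled by a
    jittered rectangular grid (grid lines perturbed, then rescaled so each
    region tiles exactly). Each cell is a stomatal complex with probability
    ``stomatal_fraction`` (counting as 4 cells), else a pavement cell.
    Returns the LeafRecord (with ``sample_fraction`` of each region's cells
    in its RegionSample) and the exact generated cell count.
    """
    if leaf_length_mm <= 0 or leaf_width_mm <= 0:
        raise ValueError("leaf dimensions must be positive")
    if not (0.0 <= stomatal_fraction < 0.5):
        raise ValueError("stomatal_fraction must be in [0, 0.5)")
    if not (0.0 < sample_fraction <= 1.0):
        raise ValueError("sample_fraction must be in (0, 1]")
    region_cell_size = region_cell_size or DEFAULT_REGION_CELL_SIZE
    rng = np.random.default_rng(seed)
    L_um, W_um = leaf_length_mm * 1000.0, leaf_width_mm * 1000.0
    region_len = L_um / 3.0
    samples = {}
    true_total = 0
    for ridx, region in enumerate(REGIONS):
        mean_len, mean_wid = region_cell_size[region]
        n_cols = max(1, round(region_len / mean_len))
        n_rows = max(1, round(W_um / mean_wid))
        col_w = _jittered_partition(rng, region_len, n_cols, size_cv)
        row_h = _jittered_partition(rng, W_um, n_rows, size_cv)
        x_edges = ridx * region_len + np.concatenate([[0.0], np.cumsum(col_w)])
        y_edges = np.concatenate([[0.0], np.cumsum(row_h)])
        is_sc = rng.random(n_cols * n_rows) < stomatal_fraction
        true_total += int(np.count_nonzero(is_sc)) * 4
        true_total += int(n_cols * n_rows - np.count_nonzero(is_sc))
        outlines = [
            CellOutline(
                vertices=(
                    (x_edges[i], y_edges[j]),
                    (x_edges[i + 1], y_edges[j]),
                    (x_edges[i + 1], y_edges[j + 1]),
                    (x_edges[i], y_edges[j + 1]),
                ),
                cell_class="stomatal_complex" if is_sc[i * n_rows + j] else "pavement",
                region=region,
            )
            for i in range(n_cols)
            for j in range(n_rows)
        ]
        if sample_fraction < 1.0:
            k = max(1, round(sample_fraction * len(outlines)))
            idx = rng.choice(len(outlines), size=k, replace=False)
            outlines = [outlines[i] for i in sorted(idx)]
        samples[region] = RegionSample(region=region, outlines=tuple(outlines),
                                       micrograph_count=3)
    leaf = LeafRecord(
        leaf_id=leaf_id,
        genotype=genotype,
        total_leaf_area=leaf_length_mm * leaf_width_mm,
        leaf_length=leaf_length_mm,
        leaf_width=leaf_width_mm,
        samples=samples,
    )
    return leaf, true_total


def _sample_axial_angles(rng, n: int, mean_deg: float, kappa: float) -> np.ndarray:
    """Axial von Mises angles in degrees, folded to [0, 180)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    # sample on the doubled circle, then halve: the standard axial construction
    phi = rng.vonmises(np.radians(2.0 * mean_deg), kappa, size=n)
    return (np.degrees(phi) / 2.0) % 180.0


def _render_segment(img: np.ndarray, p0, p1, sigma: float, amp: float = 1.0) -> None:
    """Add a filament with a Gaussian cross-section profile to ``img`` in place.

    Intensity at each pixel is amp * exp(-d^2 / (2 sigma^2)) with d the
    distance to the segment; evaluated analytically, so the rendered line is
    smooth (no rasterization staircase that would bias orientation metrics).
    """
    h, w = img.shape
    reach = 4.0 * sigma
    r_lo = max(0, int(math.floor(min(p0[1], p1[1]) - reach)))
    r_hi = min(h, int(math.ceil(max(p0[1], p1[1]) + reach)) + 1)
    c_lo = max(0, int(math.floor(min(p0[0], p1[0]) - reach)))
    c_hi = min(w, int(math.ceil(max(p0[0], p1[0]) + reach)) + 1)
    if r_lo >= r_hi or c_lo >= c_hi:
        return
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    px, py = cc - p0[0], rr - p0[1]
    vx, vy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = vx * vx + vy * vy
    t = np.clip((px * vx + py * vy) / seg2, 0.0, 1.0) if seg2 > 0 else 0.0
    d2 = (px - t * vx) ** 2 + (py - t * vy) ** 2
    img[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-d2 / (2.0 * sigma**2))


def gen_filament_image(
    size: int = 256,
    n_filaments: int = 150,
    mean_angle: float = 30.0,
    kappa: float = 8.0,
    line_width: float = 2.0,
    noise_sd: float = 0.02,
    seed: int = 0,
    pixel_size: float = 0.1,
    growth_axis_angle: float = 0.0,
) -> tuple[IntensityImage, float]:
    """Render filaments with axial von Mises orientations; returns (image, mean angle).

    Angles follow the package-wide convention (degrees CCW from +x, image y
    down, axial modulo 180). kappa = 0 gives an isotropic array; large kappa
    gives near-parallel filaments at ``mean_angle``. Filaments have a smooth
    Gaussian cross-section of full width ``line_width`` pixels.
    """
    if size < 64:
        raise ValueError("size must be at least 64")
    rng = np.random.default_rng(seed)
    img = np.zeros((size, size), dtype=float)
    angles = _sample_axial_angles(rng, n_filaments, mean_angle, kappa)
    sigma = max(0.5, line_width / 2.0)
    for theta in angles:
        cx = rng.uniform(0, size)
        cy = rng.uniform(0, size)
        half = 0.5 * rng.uniform(0.4, 0.9) * size
        t = np.radians(theta)
        dx, dy = math.cos(t) * half, math.sin(t) * half
        _render_segment(img, (cx - dx, cy - dy), (cx + dx, cy + dy), sigma)
    img += rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return (
        IntensityImage(img, pixel_size=pixel_size, growth_axis_angle=growth_axis_angle),
        float(mean_angle % 180.0),
    )


def gen_severing_series(
    rate: float,
    area: float = 100.0,
    duration: float = 5.0,
    seed: int = 0,
    cell_id: str = "synthetic",
) -> SeveringRecord:
    """Homogeneous Poisson severing events at ``rate`` events um^-2 min^-1.

    Event count ~ Poisson(rate x area x duration); times uniform over the
    observation window, positions uniform in a square of the given area.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * area * duration)
    side = math.sqrt(area)
    times = np.sort(rng.uniform(0.0, duration * 60.0, size=n))
    xs = rng.uniform(0.0, side, size=n)
    ys = rng.uniform(0.0, side, size=n)
    events = tuple((float(t), (float(x), float(y))) for t, x, y in zip(times, xs, ys))
    return SeveringRecord(cell_id=cell_id, events=events, cell_area=area, duration=duration)


#: density multiplier ranges: 2N = 1, 4N = 2, S uniform between, debris/clumps above
_TAIL_MULTIPLIER = (2.2, 4.0)


def gen_nuclei_population(
    fractions: tuple[float, float, float] = (0.65, 0.10, 0.25),
    mean_2n_density: float = 1000.0,
    cv: float = 0.08,
    per_image_gains=(1.0, 1.0, 1.0),
    n_per_image: int = 1000,
    seed: int = 0,
    mean_radius_um: float = 4.0,
) -> tuple[list[NucleusMeasure], dict]:
    """Per-image gain-shifted 2N/S/4N nuclear-density mixtures.

    Each nucleus draws a phase from ``fractions`` (f_2N, f_S, f_4N; the
    remainder is an out-of-range tail emulating debris/aggregates), then
    density = gain_i x mu x m x (1 + eps) with m = 1 (2N), 2 (4N),
    uniform(1, 2) (S), and eps ~ Normal(0, CV) truncated at -0.9. Geometry is
    disk-consistent. Returns the measures and a ground-truth dict with true
    per-phase counts and per-image gains.
    """
    f2, fs, f4 = fractions
    if min(f2, fs, f4) < 0 or f2 + fs + f4 > 1.0 + 1e-12:
        raise ValueError("fractions must be non-negative and sum to at most 1")
    if not (0.0 < cv < 0.3):
        raise ValueError("CV must be in (0, 0.3)")
    rng = np.random.default_rng(seed)
    phases = ("2N", "S", "4N", "tail")
    probs = np.array([f2, fs, f4, max(0.0, 1.0 - f2 - fs - f4)])
    probs = probs / probs.sum()
    measures = []
    truth_counts = {p: 0 for p in phases}
    for i, gain in enumerate(per_image_gains):
        if gain <= 0:
            raise ValueError("per-image gains must be positive")
        image_id = f"img{i:02d}"
        for j in range(n_per_image):
            phase = phases[rng.choice(4, p=probs)]
            truth_counts[phase] += 1
            if phase == "2N":
                m = 1.0
            elif phase == "4N":
                m = 2.0
            elif phase == "S":
                m = rng.uniform(1.0, 2.0)
            else:
                m = rng.uniform(*_TAIL_MULTIPLIER)
            eps = max(-0.9, rng.normal(0.0, cv))
            density = gain * mean_2n_density * m * (1.0 + eps)
            radius = mean_radius_um * m**0.5 * (1.0 + 0.1 * rng.normal())
            radius = max(0.5, radius)
            measures.append(
                NucleusMeasure(
                    image_id=image_id,
                    nucleus_id=f"{image_id}_n{j:04d}",
                    integrated_density=density,
                    area=math.pi * radius**2,
                    perimeter=2.0 * math.pi * radius,
                    centroid=(float(rng.uniform(0, 200)), float(rng.uniform(0, 200))),
                )
            )
    truth = {
        "counts": truth_counts,
        "fractions": {p: truth_counts[p] / len(measures) for p in phases},
        "per_image_gain": {f"img{i:02d}": float(g) for i, g in enumerate(per_image_gains)},
        "mean_2n_density": mean_2n_density,
    }
    return measures, truth


@dataclass(frozen=True)
class OffsetModel:
    """Category-conditional nuclear offset along the long axis.

    ``shift`` is the mean displacement toward the dominant accumulation side
    as a fraction of the long-axis length; ``sd`` the per-cell spread.
    """

    shift: dict = field(
        default_factory=lambda: {
            "normal": 0.0,
            "four_sided": 0.0,
            "three_sided": 0.05,
            "split": 0.0,
            "uneven": 0.10,
            "one_sided": 0.15,
            "misoriented": 0.10,
        }
    )
    sd: float = 0.03


def _quota_counts(probs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder rounding of probs*n into integer counts summing to n."""
    raw = probs * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1
    return counts


def gen_division_records(
    category_probs: dict,
    n: dict,
    offset_model: OffsetModel | None = None,
    seed: int = 0,
    quota: bool = False,
    cell_length_um: float = 30.0,
    cell_width_um: float = 12.0,
) -> list[DivisionCellRecord]:
    """PPB-stage division records per genotype with category-dependent offsets.

    ``category_probs`` maps genotype -> {category: probability}; ``n`` maps
    genotype -> cell count. With ``quota=True`` category counts are exact
    largest-remainder quotas of probs x n (no sampling noise), so printed
    tallies reproduce verbatim. Cells are rectangles with the long axis along
    +x; offset categories displace the nucleus toward the dominant
    accumulation side (the +x end).
    """
    offset_model = offset_model or OffsetModel()
    rng = np.random.default_rng(seed)
    half = (cell_length_um / 2.0, cell_width_um / 2.0)
    poly = (
        (-half[0], -half[1]),
        (half[0], -half[1]),
        (half[0], half[1]),
        (-half[0], half[1]),
    )
    records = []
    for genotype, probs in category_probs.items():
        cats = list(probs)
        p = np.array([probs[c] for c in cats], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or np.any(p < 0):
            raise ValueError(f"category probabilities for {genotype!r} must sum to 1")
        unknown = set(cats) - set(PPB_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {unknown}")
        n_g = int(n[genotype])
        if quota:
            counts = _quota_counts(p, n_g)
            drawn = np.repeat(np.arange(len(cats)), counts)
        else:
            drawn = rng.choice(len(cats), size=n_g, p=p)
        for j, ci in enumerate(drawn):
            cat = cats[ci]
            shift = offset_model.shift.get(cat, 0.0)
            dx = rng.normal(shift, offset_model.sd) * cell_length_um
            dy = rng.normal(0.0, offset_model.sd) * cell_width_um
            side = "right" if shift > 0 else "none"
            records.append(
                DivisionCellRecord(
                    cell_id=f"{genotype}_c{j:04d}",
                    plant_id=f"{genotype}_p{j % 3}",
                    genotype=genotype,
                    stage="ppb",
                    ppb_category=cat,
                    cell_polygon=poly,
                    long_axis_direction=(1.0, 0.0),
                    long_axis_length=cell_length_um,
                    nucleus_centroid=(dx, dy),
                    dominant_accumulation_side=side,
                )
            )
    return records


def gen_stage_records(
    n: int,
    p_division: float,
    genotype: str = "synthetic",
    seed: int = 0,
) -> list[DivisionCellRecord]:
    """Interphase/division-stage mixtures for mitotic-proportion estimation.

    Each cell is in a division stage with probability ``p_division``
    (split evenly among PPB, metaphase and telophase), else interphase.
    """
    if not (0.0 <= p_division <= 1.0):
        raise ValueError("p_division must be in [0, 1]")
    rng = np.random.default_rng(seed)
    records = []
    division_stages = ("ppb", "metaphase", "telophase")
    for j in range(n):
        if rng.random() < p_division:
            stage = division_stages[rng.integers(3)]
        else:
            stage = "interphase"
        records.append(
            DivisionCellRecord(
                cell_id=f"{genotype}_s{j:05d}",
                plant_id=f"{genotype}_p{j % 3}",
                genotype=genotype,
                stage=stage,
                ppb_category="normal" if stage == "ppb" else "none",
            )
        )
    return records
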