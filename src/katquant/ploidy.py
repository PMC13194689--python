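"""Nuclear DNA-content image cytometry.

Integrated fluorescence density of a stained nucleus is proportional to its
DNA content, so the density histogram of a dividing tissue shows a 2N peak
(G1, anaphase, telophase), a 4N peak (G2, prophase, metaphase) and an S-phase
valley between them. Because staining and acquisition gain vary from image to
image, densities are normalized per image: each measurement is divided by the
image's modal (2N) peak density and scaled so the mode sits at 100. The modal
peak is located as the maximum of a Gaussian kernel density estimate
(Silverman bandwidth), which is reproducible where a raw histogram argmax
would depend on bin width.

Phase bins on the normalized scale: 2N = [60, 140], 4N = [160, 210],
S = the open interval between them, everything else unclassified. The outer
bins are closed so boundary values are assigned deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

__all__ = [
    "NucleusMeasure",
    "NormalizedPopulation",
    "PhaseFractions",
    "PHASE_BINS",
    "measure_from_labels",
    "normalize_by_modal_peak",
    "classify_phases",
    "circularity",
]

#: normalized-density bin edges: 2N closed [60, 140]; 4N closed [160, 210]
PHASE_BINS = {"2N": (60.0, 140.0), "4N": (160.0, 210.0)}

#: below this many nuclei per image, KDE mode estimation is flagged unreliable
MIN_NUCLEI_PER_IMAGE = 20


@dataclass(frozen=True)
class NucleusMeasure:
    """One segmented nucleus: integrated density plus shape descriptors."""

    image_id: str
    integrated_density: float  # a.u.
    area: float = 0.0  # um^2
    perimeter: float = 0.0  # um
    centroid: tuple = (0.0, 0.0)  # (x_um, y_um)
    nucleus_id: str = ""

    def __post_init__(self) -> None:
        if self.integrated_density < 0:
            raise ValueError("integrated_density must be non-negative")
        if self.area > 0 and self.perimeter <= 0:
            raise ValueError("positive area requires positive perimeter")


@dataclass
class NormalizedPopulation:
    """Per-image mode-normalized densities (mode scaled to 100)."""

    records: list  # of (NucleusMeasure, normalized_density)
    per_image_mode: dict  # image_id -> modal density (a.u.)
    unreliable_images: set = field(default_factory=set)

    @property
    def normalized(self) -> np.ndarray:
        return np.array([v for _, v in self.records], dtype=float)


@dataclass(frozen=True)
class PhaseFractions:
    n_2N: int
    n_S: int
    n_4N: int
    n_unclassified: int

    @property
    def total(self) -> int:
        return self.n_2N + self.n_S + self.n_4N + self.n_unclassified

    @property
    def fractions(self) -> dict:
        """Fractions of the full population (unclassified nuclei included in n)."""
        n = self.total
        if n == 0:
            return {"2N": 0.0, "S": 0.0, "4N": 0.0, "unclassified": 0.0}
        return {
            "2N": self.n_2N / n,
            "S": self.n_S / n,
            "4N": self.n_4N / n,
            "unclassified": self.n_unclassified / n,
        }

    @property
    def fractions_of_classified(self) -> dict:
        """Fractions with only in-range ([60, 210]) nuclei in the denominator."""
        n = self.n_2N + self.n_S + self.n_4N
        if n == 0:
            return {"2N": 0.0, "S": 0.0, "4N": 0.0}
        return {"2N": self.n_2N / n, "S": self.n_S / n, "4N": self.n_4N / n}


def _boundary_chain_length(mask: np.ndarray) -> float:
    """Perimeter of a connected binary region as its 8-connected boundary chain.

    Moore-neighbour tracing over boundary pixel centers; axial steps count 1,
    diagonal steps sqrt(2). Lone pixels fall back to a unit-square boundary.
    """
    pts = np.argwhere(mask)
    if len(pts) == 1:
        return 4.0
    mask = np.pad(mask, 1)
    start = tuple(np.argwhere(mask)[0])  # first foreground pixel in raster order
    # clockwise Moore neighbourhood starting from west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    chain = 0.0
    cur = start
    backtrack = 0  # index into nbrs of the pixel we came from (west of start)
    first_step = None
    while True:
        found = False
        for k in range(8):
            idx = (backtrack + 1 + k) % 8
            dr, dc = nbrs[idx]
            nxt = (cur[0] + dr, cur[1] + dc)
            if mask[nxt]:
                step = np.sqrt(2.0) if dr and dc else 1.0
                if first_step is None:
                    first_step = (cur, nxt)
                elif (cur, nxt) == first_step:
                    return chain
                chain += step
                # new backtrack: direction pointing from nxt to cur
                backtrack = nbrs.index((cur[0] - nxt[0], cur[1] - nxt[1]))
                cur = nxt
                found = True
                break
        if not found:  # isolated pixel surrounded by background
            return 4.0


def measure_from_labels(intensity: np.ndarray, labels: np.ndarray, pixel_size: float = 1.0,
                        image_id: str = "") -> list[NucleusMeasure]:
    """Per-label integrated density, area, chain perimeter and weighted centroid.

    ``labels`` is a non-negative integer mask (0 = background) of the same
    shape as ``intensity``.
    """
    intensity = np.asarray(intensity, dtype=float)
    labels = np.asarray(labels)
    if intensity.shape != labels.shape:
        raise ValueError("intensity and label images must share shape")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError("labels must be integers")
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = []
    for lab in ids:
        m = labels == lab
        dens = float(intensity[m].sum())
        area = float(m.sum()) * pixel_size**2
        # crop to the bounding box before tracing the boundary
        sl = ndimage.find_objects(m.astype(np.int8))[0]
        perim = _boundary_chain_length(m[sl]) * pixel_size
        w = intensity[m]
        rows, cols = np.nonzero(m)
        if w.sum() > 0:
            cy = float((rows * w).sum() / w.sum()) * pixel_size
            cx = float((cols * w).sum() / w.sum()) * pixel_size
        else:
            cy = float(rows.mean()) * pixel_size
            cx = float(cols.mean()) * pixel_size
        out.append(
            NucleusMeasure(
                image_id=image_id,
                nucleus_id=str(int(lab)),
                integrated_density=dens,
                area=area,
                perimeter=perim,
                centroid=(cx, cy),
            )
        )
    return out


def _kde_mode(values: np.ndarray) -> float:
    """Location of the KDE peak (Silverman bandwidth) over a 512-point grid."""
    if np.all(values == values[0]):
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    lo, hi = values.min(), values.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    return float(grid[np.argmax(kde(grid))])


def normalize_by_modal_peak(measures) -> NormalizedPopulation:
    """Normalize integrated densities per image by the modal (2N) peak, x100.

    Images with fewer than 20 nuclei are still normalized but flagged
    unreliable, since the KDE mode is poorly determined at small n.
    """
    by_image: dict[str, list[NucleusMeasure]] = {}
    for m in measures:
        by_image.setdefault(m.image_id, []).append(m)
    if not by_image:
        raise ValueError("no measurements supplied")
    records = []
    modes = {}
    unreliable = set()
    for image_id, group in by_image.items():
        dens = np.array([m.integrated_density for m in group], dtype=float)
        if dens.size < MIN_NUCLEI_PER_IMAGE:
            unreliable.add(image_id)
            warnings.warn(
                f"image {image_id!r} has {dens.size} nuclei; modal peak unreliable",
                stacklevel=2,
            )
        mode = _kde_mode(dens)
        if mode <= 0:
            raise ValueError(f"non-positive modal density in image {image_id!r}")
        modes[image_id] = mode
        records.extend((m, 100.0 * m.integrated_density / mode) for m in group)
    return NormalizedPopulation(records=records, per_image_mode=modes,
                                unreliable_images=unreliable)


def classify_phases(pop) -> PhaseFractions:
    """Bin normalized densities into 2N / S / 4N / unclassified.

    Accepts a NormalizedPopulation or a bare sequence of normalized values.
    """
    values = pop.normalized if isinstance(pop, NormalizedPopulation) else np.asarray(pop, dtype=float)
    lo2, hi2 = PHASE_BINS["2N"]
    lo4, hi4 = PHASE_BINS["4N"]
    n2 = int(np.sum((values >= lo2) & (values <= hi2)))
    n4 = int(np.sum((values >= lo4) & (values <= hi4)))
    ns = int(np.sum((values > hi2) & (values < lo4)))
    return PhaseFractions(n_2N=n2, n_S=ns, n_4N=n4,
                          n_unclassified=int(values.size) - n2 - ns - n4)


def circularity(measure) -> float:
    """Shape circularity 4*pi*area / perimeter^2, capped at 1 (1 = circle)."""
    if isinstance(measure, NucleusMeasure):
        area, perim = measure.area, measure.perimeter
    else:
        area, perim = measure
    if perim <= 0 or area <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * np.pi * area / perim**2)
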