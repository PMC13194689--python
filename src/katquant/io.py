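"""Plain-text tabular and TIFF input/output.

All tables are comma-separated with a header row. Layouts:

* cell outlines — one vertex per row:
  leaf_id, cell_id, cell_class, region, x_um, y_um, vertex_order
* leaf metadata — one leaf per row:
  leaf_id, genotype, leaf_area_mm2, leaf_length_mm, leaf_width_mm
* severing events — one event per row, with per-cell geometry repeated:
  cell_id, cell_area_um2, duration_min, time_s, x_um, y_um
* nucleus measurements — one nucleus per row:
  image_id, nucleus_id, integrated_density, area_um2, perimeter_um, x, y
* division records — one cell per row (polygon in the outline sidecar)
* division time-lapses — one frame per row:
  cell_id, frame, stage, phragmoplast_length_um

Images and stacks are single- or multi-page TIFF via tifffile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import tifffile

from .division import DivisionCellRecord, DivisionTimelapse
from .leaf import CellOutline, LeafRecord, RegionSample, REGIONS
from .microtubules import IntensityImage, SeveringRecord, TimelapseStack
from .ploidy import NucleusMeasure

__all__ = [
    "read_image",
    "write_image",
    "read_stack",
    "write_stack",
    "read_outlines",
    "write_outlines",
    "read_leaf_records",
    "read_severing_records",
    "write_severing_records",
    "read_nucleus_table",
    "write_nucleus_table",
    "read_division_records",
    "write_division_records",
    "read_timelapses",
    "write_timelapses",
]


def read_image(path, pixel_size: float = 1.0, growth_axis_angle: float = 0.0) -> IntensityImage:
    return IntensityImage(tifffile.imread(path).astype(float), pixel_size=pixel_size,
                          growth_axis_angle=growth_axis_angle)


def write_image(path, image: IntensityImage) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def read_stack(path, frame_interval: float, pixel_size: float = 1.0,
               growth_axis_angle: float = 0.0) -> TimelapseStack:
    arr = tifffile.imread(path).astype(float)
    if arr.ndim != 3:
        raise ValueError("expected a multi-page TIFF stack")
    frames = tuple(
        IntensityImage(f, pixel_size=pixel_size, growth_axis_angle=growth_axis_angle)
        for f in arr
    )
    return TimelapseStack(frames=frames, frame_interval=frame_interval)


def write_stack(path, stack: TimelapseStack) -> None:
    tifffile.imwrite(path, np.stack([f.pixels for f in stack.frames]).astype(np.float32),
                     photometric="minisblack")


def write_outlines(path, leaves: dict) -> None:
    """Write {leaf_id: list of (cell_id, CellOutline)} as a vertex table."""
    rows = []
    for leaf_id, cells in leaves.items():
        for cell_id, outline in cells:
            for k, (x, y) in enumerate(outline.vertices):
                rows.append((leaf_id, cell_id, outline.cell_class, outline.region, x, y, k))
    pd.DataFrame(
        rows,
        columns=["leaf_id", "cell_id", "cell_class", "region", "x_um", "y_um", "vertex_order"],
    ).to_csv(path, index=False)


def read_outlines(path) -> dict:
    """Read a vertex table into {leaf_id: list of (cell_id, CellOutline)}."""
    df = pd.read_csv(path)
    out: dict = {}
    for (leaf_id, cell_id), grp in df.groupby(["leaf_id", "cell_id"], sort=False):
        grp = grp.sort_values("vertex_order")
        outline = CellOutline(
            vertices=tuple(zip(grp["x_um"], grp["y_um"])),
            cell_class=grp["cell_class"].iloc[0],
            region=grp["region"].iloc[0],
        )
        out.setdefault(leaf_id, []).append((cell_id, outline))
    return out


def read_leaf_records(meta_path, outlines_path) -> list[LeafRecord]:
    """Assemble LeafRecords from a metadata table and an outline vertex table."""
    meta = pd.read_csv(meta_path)
    outlines = read_outlines(outlines_path)
    records = []
    for _, row in meta.iterrows():
        cells = outlines.get(row["leaf_id"], [])
        samples = {}
        for region in REGIONS:
            region_outlines = tuple(o for _, o in cells if o.region == region)
            if not region_outlines:
                raise ValueError(f"leaf {row['leaf_id']!r} has no outlines in region {region!r}")
            samples[region] = RegionSample(region=region, outlines=region_outlines)
        records.append(
            LeafRecord(
                leaf_id=str(row["leaf_id"]),
                genotype=str(row["genotype"]),
                total_leaf_area=float(row["leaf_area_mm2"]),
                leaf_length=float(row["leaf_length_mm"]),
                leaf_width=float(row["leaf_width_mm"]),
                samples=samples,
            )
        )
    return records


def write_severing_records(path, records) -> None:
    rows = []
    for r in records:
        if not r.events:
            rows.append((r.cell_id, r.cell_area, r.duration, np.nan, np.nan, np.nan))
        for t, (x, y) in r.events:
            rows.append((r.cell_id, r.cell_area, r.duration, t, x, y))
    pd.DataFrame(
        rows, columns=["cell_id", "cell_area_um2", "duration_min", "time_s", "x_um", "y_um"]
    ).to_csv(path, index=False)


def read_severing_records(path) -> list[SeveringRecord]:
    df = pd.read_csv(path)
    records = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        events = tuple(
            (float(t), (float(x), float(y)))
            for t, x, y in zip(grp["time_s"], grp["x_um"], grp["y_um"])
            if np.isfinite(t)
        )
        records.append(
            SeveringRecord(
                cell_id=str(cell_id),
                events=events,
                cell_area=float(grp["cell_area_um2"].iloc[0]),
                duration=float(grp["duration_min"].iloc[0]),
            )
        )
    return records


def write_nucleus_table(path, measures) -> None:
    pd.DataFrame(
        [
            (m.image_id, m.nucleus_id, m.integrated_density, m.area, m.perimeter,
             m.centroid[0], m.centroid[1])
            for m in measures
        ],
        columns=["image_id", "nucleus_id", "integrated_density", "area_um2",
                 "perimeter_um", "x", "y"],
    ).to_csv(path, index=False)


def read_nucleus_table(path) -> list[NucleusMeasure]:
    df = pd.read_csv(path)
    return [
        NucleusMeasure(
            image_id=str(r["image_id"]),
            nucleus_id=str(r["nucleus_id"]),
            integrated_density=float(r["integrated_density"]),
            area=float(r["area_um2"]),
            perimeter=float(r["perimeter_um"]),
            centroid=(float(r["x"]), float(r["y"])),
        )
        for _, r in df.iterrows()
    ]


_DIVISION_COLS = [
    "cell_id", "plant_id", "genotype", "stage", "ppb_category",
    "long_axis_dx", "long_axis_dy", "long_axis_length_um",
    "nucleus_x_um", "nucleus_y_um", "ppb_axis_position",
    "dominant_accumulation_side", "polygon",
]


def write_division_records(path, records) -> None:
    rows = []
    for r in records:
        poly = ";".join(f"{x}:{y}" for x, y in r.cell_polygon)
        rows.append(
            (r.cell_id, r.plant_id, r.genotype, r.stage, r.ppb_category,
             r.long_axis_direction[0], r.long_axis_direction[1], r.long_axis_length,
             r.nucleus_centroid[0], r.nucleus_centroid[1],
             np.nan if r.ppb_axis_position is None else r.ppb_axis_position,
             r.dominant_accumulation_side, poly)
        )
    pd.DataFrame(rows, columns=_DIVISION_COLS).to_csv(path, index=False)


def read_division_records(path) -> list[DivisionCellRecord]:
    df = pd.read_csv(path)
    records = []
    for _, r in df.iterrows():
        poly = ()
        if isinstance(r["polygon"], str) and r["polygon"]:
            poly = tuple(
                tuple(float(v) for v in pair.split(":")) for pair in r["polygon"].split(";")
            )
        pos = r["ppb_axis_position"]
        records.append(
            DivisionCellRecord(
                cell_id=str(r["cell_id"]),
                plant_id=str(r["plant_id"]),
                genotype=str(r["genotype"]),
                stage=str(r["stage"]),
                ppb_category=str(r["ppb_category"]),
                cell_polygon=poly,
                long_axis_direction=(float(r["long_axis_dx"]), float(r["long_axis_dy"])),
                long_axis_length=float(r["long_axis_length_um"]),
                nucleus_centroid=(float(r["nucleus_x_um"]), float(r["nucleus_y_um"])),
                ppb_axis_position=None if pd.isna(pos) else float(pos),
                dominant_accumulation_side=str(r["dominant_accumulation_side"]),
            )
        )
    return records


def write_timelapses(path, timelapses) -> None:
    rows = []
    for tl in timelapses:
        lengths = tl.phragmoplast_length or (np.nan,) * len(tl.stages)
        for k, (stage, plen) in enumerate(zip(tl.stages, lengths)):
            rows.append((tl.cell_id, k, tl.frame_interval, stage, plen))
    pd.DataFrame(
        rows, columns=["cell_id", "frame", "frame_interval_min", "stage",
                       "phragmoplast_length_um"]
    ).to_csv(path, index=False)


def read_timelapses(path) -> list[DivisionTimelapse]:
    df = pd.read_csv(path)
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            DivisionTimelapse(
                cell_id=str(cell_id),
                frame_interval=float(grp["frame_interval_min"].iloc[0]),
                stages=tuple(grp["stage"]),
                phragmoplast_length=tuple(float(v) for v in grp["phragmoplast_length_um"]),
            )
        )
    return out
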