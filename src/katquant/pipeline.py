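"""Pipeline orchestration: configuration, stage execution, reporting.

A PipelineConfig selects stages and carries their parameters plus one seed.
``run_pipeline`` executes the enabled stages in dependency order, writes
per-stage tables and a JSON summary under the output directory, and records
a run manifest (package version, seed, full config and its hash) from which
the identical run can be reproduced: deterministic stages yield byte-identical
summary JSON on re-run.

Default stage parameters are the study conditions of the maize katanin
analysis this pipeline models: the published PPB tally (161 wild-type vs 182
mutant cells, Bonferroni 0.05/7), nuclear populations of 3 images per
genotype at the published phase mixtures, and filament/severing scenarios at
realistic cortical-array settings.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .division import (
    BONFERRONI_ALPHA,
    PPB_CATEGORIES,
    REFERENCE_PPB_COUNTS,
    reference_count_table,
    tally_and_test,
    category_fisher_tests,
)
from .leaf import estimate_total_cells, project_leaf, summarize_cells
from .microtubules import nematic_anisotropy, severing_frequency
from .ploidy import classify_phases, normalize_by_modal_peak
from .stats import chi_square_independence
from . import synth

__all__ = ["PipelineConfig", "run_pipeline", "run_from_manifest", "validate_inputs"]

ALL_STAGES = ("table1", "divisions", "leaf", "ploidy", "microtubules")


@dataclass
class PipelineConfig:
    """Stage selection, per-stage parameters, seed and output directory."""

    out_dir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            out_dir=raw.get("out_dir", "results"),
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", ALL_STAGES)),
            params=raw.get("params", {}),
        )

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "stages": list(self.stages),
            "params": self.params,
        }


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def _round_floats(obj, ndigits: int = 10):
    """Round floats recursively so summaries serialize reproducibly."""
    if isinstance(obj, float):
        return round(obj, ndigits) if np.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _stage_table1(cfg: PipelineConfig) -> dict:
    """Fisher tests on the published PPB-category tally."""
    table = reference_count_table()
    results = category_fisher_tests(table, alpha=BONFERRONI_ALPHA)
    return {
        "counts": {c: list(v) for c, v in table.counts.items()},
        "totals": list(table.totals),
        "threshold": BONFERRONI_ALPHA / len(PPB_CATEGORIES),
        "tests": {
            c: {"p_value": r.p_value, "significant": r.extra["significant"], "n": sum(table.totals)}
            for c, r in results.items()
        },
    }


def _stage_divisions(cfg: PipelineConfig) -> dict:
    """Quota-generated division records reproducing the published tally."""
    p = cfg.params.get("divisions", {})
    wt_total = sum(v[0] for v in REFERENCE_PPB_COUNTS.values())
    mut_total = sum(v[1] for v in REFERENCE_PPB_COUNTS.values())
    probs = {
        "wild_type": {c: v[0] / wt_total for c, v in REFERENCE_PPB_COUNTS.items()},
        "mutant": {c: v[1] / mut_total for c, v in REFERENCE_PPB_COUNTS.items()},
    }
    records = synth.gen_division_records(
        probs, {"wild_type": wt_total, "mutant": mut_total},
        seed=cfg.seed, quota=p.get("quota", True),
    )
    table, results = tally_and_test(records)
    return {
        "n": {g: t for g, t in zip(table.genotypes, table.totals)},
        "counts": {c: list(v) for c, v in table.counts.items()},
        "tests": {
            c: {"p_value": r.p_value, "significant": r.extra["significant"]}
            for c, r in results.items()
        },
    }


def _stage_leaf(cfg: PipelineConfig) -> dict:
    """Synthetic wild-type/mutant leaf pair: counts, stats and projections."""
    p = cfg.params.get("leaf", {})
    wt_leaf, wt_true = synth.gen_epidermis_mosaic(
        leaf_length_mm=p.get("wt_length_mm", 50.0),
        leaf_width_mm=p.get("wt_width_mm", 10.0),
        seed=cfg.seed, sample_fraction=p.get("sample_fraction", 0.05),
        leaf_id="wt", genotype="wild_type",
    )
    mut_leaf, mut_true = synth.gen_epidermis_mosaic(
        leaf_length_mm=p.get("mut_length_mm", 25.0),
        leaf_width_mm=p.get("mut_width_mm", 8.0),
        region_cell_size={k: (l * 0.6, w * 0.9) for k, (l, w)
                          in synth.DEFAULT_REGION_CELL_SIZE.items()},
        seed=cfg.seed + 1, sample_fraction=p.get("sample_fraction", 0.05),
        leaf_id="mut", genotype="mutant",
    )
    out = {}
    for name, leaf, true_n in (("wild_type", wt_leaf, wt_true), ("mutant", mut_leaf, mut_true)):
        est = estimate_total_cells(leaf)
        pooled = [o for s in leaf.samples.values() for o in s.outlines]
        stats = summarize_cells(pooled, cell_class="pavement")
        out[name] = {
            "true_total_cells": true_n,
            "estimated_total_cells": est,
            "relative_error": est / true_n - 1.0,
            "mean_cell_area_um2": stats.mean_area,
            "mean_lw_ratio": stats.mean_lw_ratio,
            "n_cells_sampled": stats.n_cells,
        }
    wt_stats = summarize_cells([o for s in wt_leaf.samples.values() for o in s.outlines],
                               cell_class="pavement")
    mut_stats = summarize_cells([o for s in mut_leaf.samples.values() for o in s.outlines],
                                cell_class="pavement")
    projections = {}
    for mode in (1, 2, 3, 4):
        res = project_leaf(
            wt_leaf, wt_stats, out["wild_type"]["estimated_total_cells"],
            mut_stats, out["mutant"]["estimated_total_cells"], mode,
            mut_leaf_area=mut_leaf.total_leaf_area,
        )
        projections[f"mode{mode}"] = {
            "projected_area_mm2": res.projected_area,
            "pct_of_wildtype": res.pct_of_wildtype,
            "pct_of_mutant": res.pct_of_mutant,
        }
    out["projections"] = projections
    return out


def _stage_ploidy(cfg: PipelineConfig) -> dict:
    """Gain-shifted nuclear mixtures per genotype, normalized and binned."""
    p = cfg.params.get("ploidy", {})
    scenarios = p.get("scenarios", {
        "wild_type": {"fractions": (0.69, 0.05, 0.18), "n_per_image": 1026},
        "mutant": {"fractions": (0.73, 0.08, 0.12), "n_per_image": 1375},
    })
    out = {}
    n2_rest = []
    for i, (name, sc) in enumerate(sorted(scenarios.items())):
        measures, truth = synth.gen_nuclei_population(
            fractions=tuple(sc["fractions"]),
            per_image_gains=sc.get("gains", (0.8, 1.0, 1.5)),
            n_per_image=sc["n_per_image"],
            seed=cfg.seed + i,
        )
        pop = normalize_by_modal_peak(measures)
        phases = classify_phases(pop)
        out[name] = {
            "n": phases.total,
            "counts": {"2N": phases.n_2N, "S": phases.n_S, "4N": phases.n_4N,
                       "unclassified": phases.n_unclassified},
            "fractions": phases.fractions,
            "true_fractions": truth["fractions"],
        }
        n2_rest.append([phases.n_2N, phases.total - phases.n_2N])
    if len(n2_rest) == 2:
        res = chi_square_independence(np.array(n2_rest))
        out["chi_square_2n_vs_rest"] = {"statistic": res.statistic, "p_value": res.p_value,
                                        "df": res.df}
    return out


def _stage_microtubules(cfg: PipelineConfig) -> dict:
    """Anisotropy/orientation on synthetic arrays plus severing-rate recovery."""
    p = cfg.params.get("microtubules", {})
    mean_angle = p.get("mean_angle", 30.0)
    # noise-free kappa -> infinity limit: the ideal "parallel stripes" scenario
    parallel, true_angle = synth.gen_filament_image(
        mean_angle=mean_angle, kappa=1e6, noise_sd=0.0, seed=cfg.seed)
    isotropic, _ = synth.gen_filament_image(
        n_filaments=200, kappa=0.0, seed=cfg.seed + 1)
    mp = nematic_anisotropy(parallel)
    mi = nematic_anisotropy(isotropic)
    rate = p.get("severing_rate", 0.02)
    rec = synth.gen_severing_series(rate=rate, area=200.0, duration=10.0, seed=cfg.seed + 2)
    return {
        "parallel": {"anisotropy": mp.anisotropy, "principal_angle": mp.principal_angle,
                     "true_angle": true_angle,
                     "angle_to_growth_axis": mp.angle_to_growth_axis},
        "isotropic": {"anisotropy": mi.anisotropy},
        "severing": {"true_rate": rate, "estimated_rate": severing_frequency(rec),
                     "n_events": len(rec.events)},
    }


_STAGE_FUNCS = {
    "table1": _stage_table1,
    "divisions": _stage_divisions,
    "leaf": _stage_leaf,
    "ploidy": _stage_ploidy,
    "microtubules": _stage_microtubules,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run enabled stages, write summary.json and manifest.json, return the summary."""
    unknown = set(cfg.stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": {}}
    status = {}
    for stage in cfg.stages:
        try:
            summary["stages"][stage] = _round_floats(_STAGE_FUNCS[stage](cfg))
            status[stage] = "ok"
        except Exception as exc:  # record partial status, keep going
            status[stage] = f"failed: {exc}"
            summary["stages"][stage] = None
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "stage_status": status,
        "outputs": ["summary.json"],
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return summary


def run_from_manifest(manifest_path, out_dir=None) -> dict:
    """Re-run a pipeline exactly as recorded in a manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    raw = manifest["config"]
    cfg = PipelineConfig(
        out_dir=out_dir or raw["out_dir"],
        seed=raw["seed"],
        stages=tuple(raw["stages"]),
        params=raw["params"],
    )
    return run_pipeline(cfg)


def validate_inputs(paths: dict) -> list[dict]:
    """Schema/invariant diagnostics for input tables.

    ``paths`` maps kind -> path, kinds: outlines, nuclei, divisions.
    Returns a list of {file, row, field, message}; empty iff all inputs valid.
    """
    import pandas as pd

    required = {
        "outlines": ["leaf_id", "cell_id", "cell_class", "region", "x_um", "y_um",
                     "vertex_order"],
        "nuclei": ["image_id", "nucleus_id", "integrated_density", "area_um2",
                   "perimeter_um", "x", "y"],
        "divisions": ["cell_id", "plant_id", "genotype", "stage", "ppb_category"],
    }
    diags: list[dict] = []
    for kind, path in paths.items():
        if kind not in required:
            diags.append({"file": str(path), "row": None, "field": None,
                          "message": f"unknown input kind {kind!r}"})
            continue
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            diags.append({"file": str(path), "row": None, "field": None,
                          "message": f"unreadable: {exc}"})
            continue
        missing = [c for c in required[kind] if c not in df.columns]
        if missing:
            diags.append({"file": str(path), "row": None, "field": ",".join(missing),
                          "message": "missing required columns"})
            continue
        if kind == "outlines":
            for (leaf_id, cell_id), grp in df.groupby(["leaf_id", "cell_id"]):
                if len(grp) < 3:
                    diags.append({"file": str(path), "row": int(grp.index[0]),
                                  "field": "cell_id",
                                  "message": f"cell {cell_id!r} has fewer than 3 vertices"})
        elif kind == "nuclei":
            bad = df.index[df["integrated_density"] < 0]
            for i in bad:
                diags.append({"file": str(path), "row": int(i),
                              "field": "integrated_density",
                              "message": "negative integrated density"})
        elif kind == "divisions":
            bad = df.index[~df["stage"].isin(["interphase", "ppb", "metaphase", "telophase"])]
            for i in bad:
                diags.append({"file": str(path), "row": int(i), "field": "stage",
                              "message": f"unknown stage {df.loc[i, 'stage']!r}"})
    return diags
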