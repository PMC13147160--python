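"""End-to-end orchestration: simulate -> segment/track -> metrics -> stats.

A run is driven by a single YAML/dict config and produces per-cell CSVs,
cohort comparison tables, an inclusion report and a JSON manifest recording
every configurable decision (seed, units, perimeter estimator, phase-level
rule, thresholds) plus any warnings raised along the way.  No timestamps are
written, so identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import ConditionGroup, summarize_conditions
from .de import classify_genes, summarize_de, volcano_coordinates, zscore_rows
from .flux import group_flux
from .masks_io import build_tracks, filter_tracks, inclusion_report, read_mask_stack, write_mask_stack
from .motility import DEFAULT_PERIMETER_METHOD, compute_motility
from .synthetic import MotilitySimConfig, rasterize_movie, simulate_de_table, simulate_flux_trace

__all__ = [
    "AcquisitionSummary",
    "validate_acquisition",
    "run_motility_pipeline",
    "run_flux_pipeline",
    "run_de_pipeline",
    "demo_config",
]


@dataclass
class AcquisitionSummary:
    """Schedule arithmetic for one recording.

    ``total_time_min`` counts n_frames x interval (the acquisition-protocol
    convention: 60 frames at 20 s = 20 min); ``span_min`` is the first-to-
    last-frame span (n_frames - 1) x interval.  Both are reported to avoid
    ambiguity.
    """

    n_frames: int
    interval_s: float
    total_time_min: float
    span_min: float
    metric_interval_s: float
    frames_per_interval: int
    n_pairs: int
    trailing_frames: int


def validate_acquisition(
    n_frames: int, interval_s: float, metric_interval_s: float = 180.0
) -> AcquisitionSummary:
    """Total imaging time and the number of complete metric intervals.

    Non-overlapping 3-min pairs: with 60 frames at 20 s there are 6 complete
    pairs (frames 0-54) and 5 unused trailing frames.  An interval not
    commensurate with ``metric_interval_s`` triggers a warning and the pair
    stride is floored.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if interval_s <= 0:
        raise ValueError("interval_s must be > 0")
    stride_f = metric_interval_s / interval_s
    stride = int(stride_f)
    if abs(stride_f - round(stride_f)) > 1e-9:
        warnings.warn(
            f"frame interval {interval_s} s does not divide {metric_interval_s} s; "
            f"pair stride floored to {stride} frames",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        stride = int(round(stride_f))
    stride = max(stride, 1)
    n_pairs = (n_frames - 1) // stride
    if n_pairs == 0:
        warnings.warn(
            f"recording of {n_frames} frames holds no complete "
            f"{metric_interval_s}-s interval",
            RuntimeWarning,
            stacklevel=2,
        )
    return AcquisitionSummary(
        n_frames=n_frames,
        interval_s=interval_s,
        total_time_min=n_frames * interval_s / 60.0,
        span_min=(n_frames - 1) * interval_s / 60.0,
        metric_interval_s=metric_interval_s,
        frames_per_interval=stride,
        n_pairs=n_pairs,
        trailing_frames=(n_frames - 1) - n_pairs * stride,
    )


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def _derived_seed(root: int, *key: int) -> int:
    return int(np.random.SeedSequence((root, *key)).generate_state(1)[0] & 0x7FFFFFFF)


def run_motility_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Simulate (or load), track, measure and compare motility cohorts.

    Config keys: ``seed``, ``output_dir``, ``metric_interval_s``,
    ``simulation`` (shared generator settings incl. ``cells_per_field``) and
    ``conditions`` (list with ``name``, ``label``, ``arm``, ``n_cells`` and
    per-condition speed/protrusion overrides).  Returns a bundle with the
    per-cell table, comparison tables and the manifest.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("output_dir", "coldmotility_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    metric_interval_s = float(cfg.get("metric_interval_s", 180.0))
    sim = dict(cfg.get("simulation", {}))
    cells_per_field = int(sim.pop("cells_per_field", 5))
    pixel_size_um = sim.get("pixel_size_um", 0.25)
    px_units = pixel_size_um is None
    if px_units:
        warnings.warn(
            "config gives no pixel size; all outputs are in pixel units",
            RuntimeWarning,
            stacklevel=2,
        )
        sim["pixel_size_um"] = 1.0

    collected_warnings: list[str] = []
    cell_rows, pair_rows, incl_frames = [], [], []
    groups: list[ConditionGroup] = []
    frame_interval_s = float(sim.get("frame_interval_s", 20.0))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        for ci, cond in enumerate(cfg["conditions"]):
            name = cond["name"]
            n_cells = int(cond.get("n_cells", 10))
            overrides = {
                k: cond[k]
                for k in (
                    "mean_speed_um_per_min",
                    "protrusion_amplitude",
                    "persistence",
                    "base_radius_um",
                )
                if k in cond
            }
            summaries = {"mean_acd_um2": [], "mean_displacement_um": [], "mean_circularity": []}
            n_fields = int(np.ceil(n_cells / cells_per_field))
            for fi in range(n_fields):
                n_here = min(cells_per_field, n_cells - fi * cells_per_field)
                mcfg = MotilitySimConfig(
                    n_cells=n_here,
                    seed=_derived_seed(seed, ci, fi),
                    **{**sim, **overrides},
                )
                stack, truth = rasterize_movie(mcfg)
                tif = out / f"{name}_field{fi}.tif"
                sidecar = write_mask_stack(
                    tif, stack, mcfg.frame_interval_s, mcfg.pixel_size_um
                )
                frames = read_mask_stack(tif, sidecar)
                truth.to_frame().to_csv(out / f"{name}_field{fi}_truth.csv", index=False)
                tracks = filter_tracks(build_tracks(frames), frames)
                rep = inclusion_report(tracks)
                rep.insert(0, "condition", name)
                rep.insert(1, "field", fi)
                incl_frames.append(rep)
                for tr in tracks:
                    if not tr.included:
                        continue
                    rec = compute_motility(
                        tr,
                        frame_interval_s=mcfg.frame_interval_s,
                        pixel_size_um=None if px_units else mcfg.pixel_size_um,
                        interval_s=metric_interval_s,
                    )
                    cell_rows.append(
                        {
                            "condition": name,
                            "label": str(cond.get("label", name)),
                            "arm": cond.get("arm", ""),
                            "field": fi,
                            "cell_id": tr.cell_id,
                            "units": rec.units,
                            **rec.summaries,
                        }
                    )
                    for (t0, t1), acd, disp in zip(
                        rec.interval_pairs, rec.acd_um2, rec.displacement_um
                    ):
                        pair_rows.append(
                            {
                                "condition": name,
                                "field": fi,
                                "cell_id": tr.cell_id,
                                "frame_start": t0,
                                "frame_end": t1,
                                "acd": acd,
                                "displacement": disp,
                                "units": rec.units,
                            }
                        )
                    for k in summaries:
                        summaries[k].append(rec.summaries[k])
            if not summaries["mean_acd_um2"]:
                breakdown = pd.concat(incl_frames).groupby("criterion")["passed"].mean()
                raise RuntimeError(
                    f"condition {name!r}: zero included cells; inclusion pass rates:\n"
                    f"{breakdown.to_string()}"
                )
            for metric, vals in summaries.items():
                groups.append(
                    ConditionGroup(
                        label=f"{cond.get('label', name)}:{metric}",
                        values=vals,
                        arm=cond.get("arm", ""),
                    )
                )
        collected_warnings = sorted({str(w.message) for w in caught})

    cells = pd.DataFrame(cell_rows)
    pairs = pd.DataFrame(pair_rows)
    inclusion = pd.concat(incl_frames, ignore_index=True)
    comparisons = summarize_conditions(groups)

    cells.to_csv(out / "per_cell.csv", index=False)
    pairs.to_csv(out / "per_pair.csv", index=False)
    inclusion.to_csv(out / "inclusion_report.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "units": "px" if px_units else "um",
        "perimeter_method": DEFAULT_PERIMETER_METHOD,
        "metric_interval_s": metric_interval_s,
        "acquisition": asdict(
            validate_acquisition(int(sim.get("n_frames", 60)), frame_interval_s, metric_interval_s)
        ),
        "simulation": {**sim, "cells_per_field": cells_per_field},
        "conditions": cfg["conditions"],
        "warnings": collected_warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "cells": cells,
        "pairs": pairs,
        "inclusion": inclusion,
        "comparisons": comparisons,
        "manifest": manifest,
        "output_dir": out,
    }


def run_flux_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Simulate (or load) per-well flux traces and derive cohort parameters.

    Config: ``seed``, ``n_wells``, ``n_cycles_per_phase``, ``noise_sd``,
    ``normalize`` and ``conditions`` (name -> phase_levels, protein_ug).
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("output_dir", "coldmotility_flux"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_wells = int(cfg.get("n_wells", 5))
    traces = {}
    for ci, cond in enumerate(cfg["conditions"]):
        wells = [
            simulate_flux_trace(
                cond["phase_levels"],
                n_cycles_per_phase=int(cfg.get("n_cycles_per_phase", 3)),
                noise_sd=float(cfg.get("noise_sd", 0.0)),
                protein_ug=float(cond.get("protein_ug", 10.0)),
                seed=_derived_seed(seed, ci, wi),
                well=f"{cond['name']}_w{wi}",
            )
            for wi in range(n_wells)
        ]
        traces[cond["name"]] = wells
        pd.concat(wells, ignore_index=True).to_csv(out / f"{cond['name']}_traces.csv", index=False)
    timecourse, parameters, comparisons = group_flux(
        traces,
        rule=cfg.get("level_rule", "report"),
        normalize=bool(cfg.get("normalize", False)),
    )
    timecourse.to_csv(out / "timecourse.csv", index=False)
    parameters.to_csv(out / "parameters.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    return {
        "timecourse": timecourse,
        "parameters": parameters,
        "comparisons": comparisons,
        "output_dir": out,
    }


def run_de_pipeline(config, out_dir: str | Path | None = None) -> dict:
    """Classify a DE table (loaded or simulated) and write the summaries.

    Config: either ``table`` (path to a TSV with gene_id, log2fc, pvalue) or
    ``simulate`` (n_genes, n_up, n_down, lfc_effect) plus ``seed``; threshold
    overrides ``lfc_min`` / ``fdr_max``.  Writes the classified TSV, summary
    JSON, volcano CSV, and a row-Z-scored demo expression matrix for the
    significant genes.
    """
    cfg = _load_config(config)
    out = Path(out_dir or cfg.get("output_dir", "coldmotility_de"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    if "table" in cfg:
        table = pd.read_csv(cfg["table"], sep="\t")
    else:
        simcfg = cfg.get("simulate", {})
        table = simulate_de_table(
            n_genes=int(simcfg.get("n_genes", 15234)),
            n_up=int(simcfg.get("n_up", 1243)),
            n_down=int(simcfg.get("n_down", 1008)),
            lfc_effect=float(simcfg.get("lfc_effect", 3.0)),
            seed=seed,
        )
    classified = classify_genes(
        table,
        lfc_min=float(cfg.get("lfc_min", 1.0)),
        fdr_max=float(cfg.get("fdr_max", 0.05)),
    )
    summary = summarize_de(classified)
    volcano = volcano_coordinates(classified)
    classified.to_csv(out / "classified.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(asdict(summary), indent=1))
    volcano.to_csv(out / "volcano.csv", index=False)

    # synthetic 3+3-replicate expression matrix for the significant genes,
    # row-Z-scored with the +/-2 clamp used for heatmap display
    sig = classified[classified["label"] != "ns"]
    if len(sig):
        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((seed, 0x2EA7))))
        lfc = sig["log2fc"].to_numpy()[:, None]
        expr = np.hstack(
            [
                0.3 * rng.standard_normal((len(sig), 3)),
                lfc + 0.3 * rng.standard_normal((len(sig), 3)),
            ]
        )
        mat = pd.DataFrame(
            expr,
            index=sig["gene_id"],
            columns=["nonAC_R1", "nonAC_R2", "nonAC_R3", "AC_R1", "AC_R2", "AC_R3"],
        )
        zscore_rows(mat).to_csv(out / "heatmap_matrix.tsv", sep="\t")
    return {"classified": classified, "summary": summary, "volcano": volcano, "output_dir": out}


def demo_config(seed: int = 1) -> dict:
    """Bundled demo: non-AC vs AC cohorts imaged at 37 C and 26 C.

    Speeds and protrusion amplitudes encode the study conditions: warm or
    acclimated cells crawl fast with strong membrane remodeling; acutely
    cooled non-acclimated cells are nearly immobile and round.  Acclimated
    cells at 37 C are programmed slightly below warm non-acclimated ones.
    """
    return {
        "seed": seed,
        "metric_interval_s": 180,
        "simulation": {
            "n_frames": 60,
            "frame_interval_s": 20,
            "pixel_size_um": 0.25,
            "field_size_px": [512, 512],
            "cells_per_field": 5,
            "base_radius_um": 5.0,
        },
        "conditions": [
            {"name": "37C_nonAC", "label": "37", "arm": "non-AC", "n_cells": 10,
             "mean_speed_um_per_min": 3.0, "protrusion_amplitude": 0.35},
            {"name": "37C_AC", "label": "37", "arm": "AC", "n_cells": 10,
             "mean_speed_um_per_min": 2.0, "protrusion_amplitude": 0.25},
            {"name": "26C_nonAC", "label": "26", "arm": "non-AC", "n_cells": 10,
             "mean_speed_um_per_min": 0.3, "protrusion_amplitude": 0.06},
            {"name": "26C_AC", "label": "26", "arm": "AC", "n_cells": 10,
             "mean_speed_um_per_min": 2.4, "protrusion_amplitude": 0.3},
        ],
    }
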