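"""End-to-end orchestration: generate → QC → fit λ → nulls → cable → motifs.

A run is configured by a single YAML file with per-stage blocks and a
global seed; every run writes a manifest (config hash, seed, package
version, per-stage record counts) and a JSON report into the output
directory.  Stages execute in dependency order and abort with
stage-named errors.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .arbor import write_swc, write_synapse_csv
from .cable import CableParams, SweepGrid, sweep
from .influence import InfluenceParams
from .length_constant import (FitConfig, RoiSet, consensus_lambda,
                              fit_correlation, fit_depth_polarity,
                              fit_roi_polarity, neighbor_consistency, qc_filter)
from .motifs import ei_balance, find_triads, type_adjacency
from .null_models import (arbor_depth_histogram, overlap_weights,
                          relocation_null, type_assignment_null)
from .synthetic import (GeneratorConfig, default_bc_profiles,
                        default_rgc_profiles, generate_plexus,
                        place_bc_rgc_synapses)

logger = logging.getLogger(__name__)

ALL_STAGES = ("generate", "qc", "fit-lambda", "nulls", "cable", "motifs",
              "report")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def default_config() -> dict:
    """A small, fast end-to-end configuration."""
    return {
        "seed": 0,
        "generator": {"n_cells": 3, "target_cable_length_um": 400.0,
                      "resample_spacing_um": 0.5, "rois_per_cell": 30},
        "fit": {"lambda_max": 60},
        "nulls": {"n_reps": 2000},
        "cable": {"enabled": True, "gm_grid": [1e-4], "Ge_grid": [1e-3],
                  "Gi_grid": [0.0, 1e-3], "on_scale_grid": [0.5],
                  "duration_ms": 25.0, "dt_ms": 0.05},
    }


def run_pipeline(config: dict, outdir, seed: int | None = None,
                 stages=ALL_STAGES) -> dict:
    """Execute the pipeline; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stages": {},
    }
    report: dict = {"seed": seed}
    state: dict = {}

    for stage in stages:
        if stage not in ALL_STAGES:
            raise PipelineError(stage, "unknown stage")
        try:
            counts = _STAGE_FUNCS[stage](config, state, report, outdir, seed)
        except PipelineError:
            raise
        except Exception as exc:  # surface stage-named failures
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = counts
        logger.info("stage %s done: %s", stage, counts)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=_jsonable))
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_generate(config, state, report, outdir, seed):
    gen_kwargs = dict(config.get("generator", {}))
    gen_kwargs["rng_seed"] = seed
    gcfg = GeneratorConfig(**gen_kwargs)
    cells = generate_plexus(gcfg)
    state["cells"] = cells
    state["gcfg"] = gcfg
    state["skels"] = {c["skeleton"].cell_id: c["skeleton"] for c in cells}
    state["synapses"] = {c["skeleton"].cell_id: c["synapses"] for c in cells}
    state["rois"] = RoiSet.concat([c["rois"] for c in cells])
    data_dir = outdir / "data"
    data_dir.mkdir(exist_ok=True)
    for c in cells:
        skel = c["skeleton"]
        write_swc(skel, data_dir / f"{skel.cell_id}.swc")
        write_synapse_csv(c["synapses"], data_dir / f"{skel.cell_id}_synapses.csv")
    return {"n_cells": len(cells),
            "n_synapses": int(sum(len(c["synapses"]) for c in cells)),
            "n_rois": len(state["rois"])}


def _stage_qc(config, state, report, outdir, seed):
    _require(state, "cells", "qc")
    fitcfg = state.setdefault("fitcfg", _make_fitcfg(config))
    before = len(state["rois"])
    nc = neighbor_consistency(state["rois"], state["skels"], fitcfg.neighbor_um)
    state["rois_qc"] = qc_filter(state["rois"], state["skels"], fitcfg)
    report["qc"] = {
        "median_neighbor_dpolarity": nc["median_abs_dpolarity"],
        "n_rois_before": before, "n_rois_after": len(state["rois_qc"]),
    }
    return {"n_rois_in": before, "n_rois_out": len(state["rois_qc"])}


def _make_fitcfg(config):
    fit = config.get("fit", {})
    kwargs = {}
    if "lambda_max" in fit:
        kwargs["lambda_grid"] = np.arange(1.0, float(fit["lambda_max"]) + 1)
    return FitConfig(**kwargs)


def _stage_fit_lambda(config, state, report, outdir, seed):
    _require(state, "rois_qc", "fit-lambda")
    fitcfg = state.setdefault("fitcfg", _make_fitcfg(config))
    skels = state["skels"]
    bc = _all_bc(state)
    rois = state["rois_qc"]

    depth_targets = _depth_targets_from_rois(rois, skels)
    fit_depth = fit_depth_polarity(skels, bc, depth_targets[0], depth_targets[1],
                                   fitcfg)
    fit_roi = fit_roi_polarity(skels, bc, rois, fitcfg)
    estimates = [fit_depth.best_lambda, fit_roi.best_lambda]
    try:
        fit_corr = fit_correlation(skels, bc, rois, fitcfg)
        estimates.append(fit_corr.best_lambda)
        corr_dict = fit_corr.to_dict()
    except ValueError as exc:
        corr_dict = {"error": str(exc)}
    consensus = consensus_lambda(estimates)
    report["lambda"] = {
        "depth_fit": fit_depth.to_dict(),
        "roi_fit": fit_roi.to_dict(),
        "correlation_fit": corr_dict,
        "consensus": consensus,
    }
    state["lambda_um"] = consensus["consensus_um"]
    return {"consensus_um": consensus["consensus_um"],
            "estimates": [float(e) for e in estimates]}


def _depth_targets_from_rois(rois, skels):
    """Mean measured ROI polarity in coarse depth bins, as fit targets."""
    depths = []
    for _, row in rois.frame.iterrows():
        skel = skels[row["cell_id"]]
        d = skel.nodes.set_index("node_id").loc[row["node_id"], "ipl_depth"]
        depths.append(float(d))
    depths = np.asarray(depths)
    pol = rois.frame["polarity_measured"].to_numpy()
    edges = np.linspace(depths.min(), depths.max() + 1e-9, 8)
    centers, targets = [], []
    for k in range(len(edges) - 1):
        sel = (depths >= edges[k]) & (depths < edges[k + 1])
        if sel.sum() >= 2:
            centers.append((edges[k] + edges[k + 1]) / 2)
            targets.append(pol[sel].mean())
    return np.asarray(centers), np.asarray(targets)


def _all_bc(state):
    import pandas as pd
    return pd.concat([syn[syn["ribbon"]] for syn in state["synapses"].values()],
                     ignore_index=True)


def _stage_nulls(config, state, report, outdir, seed):
    _require(state, "cells", "nulls")
    ncfg = config.get("nulls", {})
    n_reps = int(ncfg.get("n_reps", 10000))
    rng = np.random.default_rng(seed + 1)
    cell0 = state["cells"][0]
    skel = cell0["skeleton"]
    syn = cell0["synapses"]
    bc = syn[syn["ribbon"]]

    hist = arbor_depth_histogram(skel)
    weights = overlap_weights(hist, default_bc_profiles())
    obs = bc["partner_type_label"].value_counts(normalize=True)
    null = type_assignment_null(len(bc), weights, n_reps, rng)
    report["nulls"] = {
        "bc_type_weights": weights.to_dict(),
        "bc_type_observed": obs.to_dict(),
        "bc_type_ci": {k: list(v) for k, v in null.ci.items()},
    }
    rgc_out = syn[(syn["direction"] == "output") & (syn["partner_class"] == "RGC")]
    if len(rgc_out):
        params = InfluenceParams(float(state.get("lambda_um", 16.0)))
        reloc = relocation_null(skel, rgc_out, default_rgc_profiles(), bc,
                                params, n_reps, rng)
        report["nulls"]["relocation_ci"] = {k: list(v) for k, v in reloc.ci.items()}
        report["nulls"]["relocation_observed"] = reloc.observed
    return {"n_reps": n_reps}


def _stage_cable(config, state, report, outdir, seed):
    _require(state, "cells", "cable")
    ccfg = config.get("cable", {})
    if not ccfg.get("enabled", True):
        report["cable"] = {"enabled": False}
        return {"enabled": False}
    cell0 = state["cells"][0]
    skel, syn, rois = cell0["skeleton"], cell0["synapses"], cell0["rois"]
    bc = syn[syn["ribbon"]]
    inh = syn[(syn["direction"] == "input") & (syn["partner_class"] == "AMC")]
    grids = SweepGrid(
        gm_grid=np.asarray(ccfg.get("gm_grid", [1e-4]), dtype=float),
        Ge_grid=np.asarray(ccfg.get("Ge_grid", [1e-3]), dtype=float),
        Gi_grid=np.asarray(ccfg.get("Gi_grid", [0.0, 1e-3]), dtype=float),
        on_scale_grid=np.asarray(ccfg.get("on_scale_grid", [0.5]), dtype=float),
    )
    table = sweep(
        skel, bc, inh, rois.frame["node_id"].to_numpy(),
        rois.frame["polarity_measured"].to_numpy(), grids,
        CableParams(), duration_ms=float(ccfg.get("duration_ms", 25.0)),
        dt_ms=float(ccfg.get("dt_ms", 0.05)),
    )
    table.to_csv(outdir / "cable_sweep.csv", index=False)
    report["cable"] = {"best": table.iloc[0].to_dict(),
                       "n_combinations": len(table)}
    return {"n_combinations": len(table)}


def _stage_motifs(config, state, report, outdir, seed):
    _require(state, "cells", "motifs")
    import pandas as pd
    all_syn = pd.concat(state["synapses"].values(), ignore_index=True)
    ei = ei_balance(all_syn)
    adj = type_adjacency(all_syn[all_syn["ribbon"]])
    rng = np.random.default_rng(seed + 2)
    cell0 = state["cells"][0]
    skel, syn = cell0["skeleton"], cell0["synapses"]
    bc_rgc = place_bc_rgc_synapses(skel, syn, rng)
    triads = find_triads(
        syn[syn["ribbon"]],
        syn[(syn["direction"] == "output") & (syn["partner_class"] == "RGC")],
        bc_rgc, skel)
    report["motifs"] = {
        "ei_ratio_mean": ei["ei_ratio_mean"], "ei_ratio_se": ei["ei_ratio_se"],
        "bc_fraction_mean": ei["bc_fraction_mean"],
        "n_triads": int(len(triads["motifs"])),
        "triad_median_um": triads["median_um"],
        "triad_fraction_under_1um": triads["fraction_under_1um"],
    }
    adj["matrix"].to_csv(outdir / "bc_type_adjacency.csv")
    if len(triads["motifs"]):
        triads["motifs"].to_csv(outdir / "triads.csv", index=False)
    return {"n_triads": int(len(triads["motifs"]))}


def _stage_report(config, state, report, outdir, seed):
    return {"keys": sorted(report)}


def _require(state, key, stage):
    if key not in state:
        raise PipelineError(stage, f"missing upstream result {key!r}; "
                            "run earlier stages first")


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "qc": _stage_qc,
    "fit-lambda": _stage_fit_lambda,
    "nulls": _stage_nulls,
    "cable": _stage_cable,
    "motifs": _stage_motifs,
    "report": _stage_report,
}
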