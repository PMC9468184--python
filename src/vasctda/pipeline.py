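"""End-to-end orchestration: extract → PH → SW/MDS and extract → NHPP → Fisher.

Pipelines take a nested config (dict, typically loaded from YAML), write tidy
CSV/JSON outputs plus a run manifest into an output directory, and are
deterministic for fixed seeds: re-running with an identical manifest
reproduces identical outputs.  The TDA pipeline caches per-sample persistence
diagrams keyed by a hash of the input and the PH settings, so removing or
changing one input only recomputes downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .diagram_metrics import DistanceMatrix, SWConfig, mds_embed, pairwise_distance_matrix
from .nhpp import DomainBox, fit_blocks, region_fisher_table
from .phantoms import PhantomSpec, make_phantom
from .rips import read_diagram, rips_persistence, write_diagram
from .volume_io import (
    LabelVolume,
    PointCloud3D,
    attach_region_labels,
    read_point_cloud,
    read_volume,
    subsample,
    threshold_to_points,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineError", "validate_config", "run_tda_pipeline", "run_nhpp_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


_TDA_KEYS = {
    "inputs", "subsample", "seed", "max_dim", "max_radius",
    "min_persistence", "sw", "cache",
}
_TDA_INPUT_KEYS = {"label", "points", "phantom", "threshold", "volume", "spacing", "channel"}
_SW_KEYS = {"n_slices", "sigma", "dims"}
_NHPP_KEYS = {
    "channel_a", "channel_b", "labels", "block_edge", "min_points",
    "fold", "params", "regions", "two_sided", "bh_correction", "seed", "box",
}


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")


def validate_config(config: dict) -> None:
    """Schema check: unknown keys anywhere are rejected (typo safety)."""
    _check_keys(config, {"tda", "nhpp"}, "top level")
    if "tda" in config:
        tda = config["tda"]
        _check_keys(tda, _TDA_KEYS, "tda")
        for i, inp in enumerate(tda.get("inputs", [])):
            _check_keys(inp, _TDA_INPUT_KEYS, f"tda.inputs[{i}]")
            if ("points" in inp) + ("phantom" in inp) + ("volume" in inp) != 1:
                raise ValueError(
                    f"tda.inputs[{i}]: give exactly one of points/phantom/volume"
                )
        if "sw" in tda:
            _check_keys(tda["sw"], _SW_KEYS, "tda.sw")
    if "nhpp" in config:
        nh = config["nhpp"]
        _check_keys(nh, _NHPP_KEYS, "nhpp")
        for side in ("channel_a", "channel_b"):
            if side not in nh:
                raise ValueError(f"nhpp config requires {side}")
            _check_keys(nh[side], _TDA_INPUT_KEYS, f"nhpp.{side}")


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_input(inp: dict, stage: str) -> tuple[PointCloud3D, str]:
    """Resolve one input spec to a (cloud, content-hash) pair."""
    try:
        if "phantom" in inp:
            spec = PhantomSpec(**inp["phantom"])
            cloud = make_phantom(spec)
            key = hashlib.sha256(json.dumps(inp["phantom"], sort_keys=True).encode()).hexdigest()
        elif "points" in inp:
            cloud = read_point_cloud(inp["points"])
            key = _file_sha256(Path(inp["points"]))
        else:
            vol = read_volume(inp["volume"], spacing=inp.get("spacing"))
            thr = float(inp.get("threshold", 0.5))
            logger.info("thresholding %s at %.3f", inp["volume"], thr)
            cloud = threshold_to_points(vol, thr, channel=inp.get("channel", ""))
            key = _file_sha256(Path(inp["volume"])) + f":thr={thr}"
        return cloud, key
    except (OSError, ValueError, KeyError, TypeError) as exc:
        raise PipelineError(stage, f"input {inp!r}: {exc}") from exc


@dataclass
class TDAResult:
    diagram_paths: dict
    distance_matrix: DistanceMatrix
    mds_coords: pd.DataFrame
    eigenvalues: np.ndarray
    manifest_path: Path


def _write_manifest(path: Path, manifest: dict) -> None:
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def run_tda_pipeline(config: dict, out_dir) -> TDAResult:
    """Per-sample Rips diagrams → pairwise SW matrix → 2D MDS coordinates."""
    validate_config(config)
    tda = config.get("tda")
    if not tda or not tda.get("inputs"):
        raise PipelineError("config", "tda.inputs is empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(tda.get("seed", 0))
    n_sub = int(tda.get("subsample", 120))
    max_dim = int(tda.get("max_dim", 2))
    max_radius = tda.get("max_radius")
    use_cache = bool(tda.get("cache", True))
    sw_cfg = SWConfig(
        n_slices=int(tda.get("sw", {}).get("n_slices", 50)),
        sigma=float(tda.get("sw", {}).get("sigma", 1.0)),
        dims=tuple(tda.get("sw", {}).get("dims", (1, 2))),
    )

    manifest: dict = {
        "version": __version__,
        "config": config,
        "seeds": {"subsample": seed},
        "stages": {},
        "status": "running",
        "started": time.time(),
    }
    manifest_path = out_dir / "manifest.json"
    _write_manifest(manifest_path, manifest)

    diagrams, labels, paths = [], [], {}
    for inp in tda["inputs"]:
        label = str(inp.get("label") or inp.get("points") or "sample")
        t0 = time.time()
        cloud, key = _load_input(inp, f"load[{label}]")
        ph_key = hashlib.sha256(
            f"{key}|{n_sub}|{seed}|{max_dim}|{max_radius}".encode()
        ).hexdigest()[:16]
        pd_path = out_dir / f"diagram_{label}_{ph_key}.csv"
        cached = use_cache and pd_path.exists()
        if cached:
            dg = read_diagram(pd_path)
        else:
            try:
                sub = subsample(cloud, n_sub, seed=seed)
                dg = rips_persistence(sub, max_dim=max_dim, max_radius=max_radius)
            except ValueError as exc:
                raise PipelineError(f"ph[{label}]", str(exc)) from exc
            write_diagram(dg, pd_path)
        dg.meta["label"] = label
        diagrams.append(dg)
        labels.append(label)
        paths[label] = pd_path
        manifest["stages"][f"ph[{label}]"] = {
            "cached": cached, "seconds": time.time() - t0, "input_hash": key,
        }

    t0 = time.time()
    try:
        dm = pairwise_distance_matrix(diagrams, sw_cfg, labels=labels)
    except ValueError as exc:
        raise PipelineError("sw", str(exc)) from exc
    dm.to_csv(out_dir / "sw_distances.csv")
    manifest["stages"]["sw"] = {"seconds": time.time() - t0}

    t0 = time.time()
    coords, eigval = mds_embed(dm, out_dim=2)
    coords_df = pd.DataFrame(coords, index=labels, columns=["mds1", "mds2"])
    coords_df.to_csv(out_dir / "mds_coords.csv")
    manifest["stages"]["mds"] = {
        "seconds": time.time() - t0,
        "eigenvalues": [float(v) for v in eigval],
    }

    manifest["status"] = "finished"
    manifest["finished"] = time.time()
    _write_manifest(manifest_path, manifest)
    return TDAResult(paths, dm, coords_df, eigval, manifest_path)


@dataclass
class NHPPResult:
    fisher_table: pd.DataFrame
    grid: object
    manifest_path: Path


def _load_labels(spec: dict) -> tuple[LabelVolume, tuple]:
    vol = read_volume(spec["volume"], spacing=spec.get("spacing"))
    names = {}
    return LabelVolume(vol.values.astype(int), names), vol.spacing


def run_nhpp_pipeline(config: dict, out_dir) -> NHPPResult:
    """Block-wise two-channel NHPP fits → per-region Fisher's exact tests.

    Output table has one row per (region, parameter).  No multiple-testing
    correction is applied by default (per-area raw p-values are reported);
    ``bh_correction: true`` adds a Benjamini–Hochberg adjusted column.
    """
    validate_config(config)
    nh = config.get("nhpp")
    if not nh:
        raise PipelineError("config", "nhpp section missing")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(nh.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "config": config,
        "seeds": {"fit": seed},
        "stages": {},
        "status": "running",
        "started": time.time(),
    }
    manifest_path = out_dir / "manifest.json"
    _write_manifest(manifest_path, manifest)

    cloud_a, key_a = _load_input(nh["channel_a"], "load[channel_a]")
    cloud_b, key_b = _load_input(nh["channel_b"], "load[channel_b]")
    if "labels" in nh:
        labels, spacing = _load_labels(nh["labels"])
        cloud_a = attach_region_labels(cloud_a, labels, spacing)
        cloud_b = attach_region_labels(cloud_b, labels, spacing)

    if "box" in nh:
        box = DomainBox(tuple(nh["box"]["lo"]), tuple(nh["box"]["hi"]))
    else:
        both = np.vstack([cloud_a.coords, cloud_b.coords])
        box = DomainBox.from_points(both)

    t0 = time.time()
    try:
        grid = fit_blocks(
            cloud_a, cloud_b, box,
            block_edge=float(nh.get("block_edge", 500.0)),
            min_points=int(nh.get("min_points", 50)),
            seed=seed,
        )
    except ValueError as exc:
        raise PipelineError("fit_blocks", str(exc)) from exc
    manifest["stages"]["fit_blocks"] = {
        "seconds": time.time() - t0,
        "input_hashes": [key_a, key_b],
        "n_blocks": len(grid.blocks),
        "n_evaluable": len(grid.evaluable_blocks),
    }

    t0 = time.time()
    table = region_fisher_table(
        grid,
        params=tuple(nh.get("params", ("a", "inv_b_x", "inv_b_y", "inv_b_z"))),
        fold=float(nh.get("fold", 2.0)),
        regions=nh.get("regions"),
        two_sided=bool(nh.get("two_sided", False)),
    )
    if nh.get("bh_correction", False):
        from scipy.stats import false_discovery_control

        table["p_bh"] = np.nan
        for param, idx in table.groupby("param").groups.items():
            table.loc[idx, "p_bh"] = false_discovery_control(table.loc[idx, "p"])
    table.to_csv(out_dir / "fisher_results.csv", index=False)
    manifest["stages"]["fisher"] = {"seconds": time.time() - t0, "n_rows": len(table)}

    manifest["status"] = "finished"
    manifest["finished"] = time.time()
    _write_manifest(manifest_path, manifest)
    return NHPPResult(table, grid, manifest_path)
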