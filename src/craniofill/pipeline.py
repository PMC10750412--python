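"""End-to-end orchestration: defective volume in, implant model out.

Stages: normalise (HU window + Frankfort crop) → downsample ×4 →
stage-1 completion → threshold → stage-2 resolution enhancement →
threshold → Boolean implant extraction (with tolerance scaling) →
morphological clean-up → STL export. Every run writes a machine-
readable manifest (inputs, seeds, parameters, per-stage results) so a
re-run with the same config and seeds reproduces all binary outputs
exactly.

Also hosts the phantom-based training entry points used by the CLI:
they generate paired synthetic datasets, train a network with the
standard recipe, and save a checkpoint.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .defects import make_defect_pairs
from .implant import export_mesh, extract_implant, postprocess_implant
from .metrics import score_reconstruction
from .nn.networks import (
    ModelState,
    binarize_prediction,
    build_completion_network,
    build_enhancement_network,
    forward_completion,
    forward_enhancement,
)
from .phantom import generate_dataset
from .training import TrainingConfig, train_model
from .volume import BinaryVolume, ScalarVolume
from .voxel_io import (
    binarize_hounsfield,
    crop_below_plane,
    downsample_binary,
    read_volume,
    write_volume,
)

__all__ = ["run_pipeline", "train_completion_from_config", "train_enhancement_from_config"]

# constants of the reference protocol, surfaced as named defaults
DEFAULTS = {
    "hounsfield_window": [1200.0, 1817.0],
    "frankfort_plane_index": 0,
    "downsample_factor": 4,
    "threshold": 0.45,
    "tolerance_scale": 1.02,
    "opening_radius": 1,
    "keep_components": 1,
    "rotation_interval_deg": 2.0,
    "defect_diameter_range_mm": [60.0, 120.0],
    "defects_per_skull": 25,
    "seed": 0,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _load_config(config_path) -> dict:
    cfg = dict(DEFAULTS)
    with open(config_path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg.update(user)
    return cfg


def _require(cfg: dict, key: str) -> object:
    if key not in cfg or cfg[key] is None:
        raise PipelineError("config", f"missing required config key {key!r}")
    return cfg[key]


def run_pipeline(config_path: str | Path) -> dict:
    """Execute the full reconstruction flow described by a YAML config.

    Required keys: ``input`` (defective volume), ``completion_checkpoint``,
    ``enhancement_checkpoint``, ``output_dir``. Optional keys override
    the protocol defaults above; ``ground_truth_implant`` adds overlap
    metrics to the manifest. Returns the manifest dict (also written to
    ``output_dir/manifest.json``).
    """
    cfg = _load_config(config_path)
    input_path = _require(cfg, "input")
    out_dir = Path(_require(cfg, "output_dir"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "craniofill",
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "stages": [],
        "artifacts": {},
    }

    def stage(name: str):
        manifest["stages"].append(name)
        return time.time()

    try:
        stage("read")
        vol = read_volume(input_path)

        stage("normalize")
        if isinstance(vol, ScalarVolume):
            lo, hi = cfg["hounsfield_window"]
            vol = binarize_hounsfield(vol, lo, hi)
        plane = int(cfg["frankfort_plane_index"])
        if plane > 0:
            vol = crop_below_plane(vol, plane)
        defective_high: BinaryVolume = vol

        stage("downsample")
        factor = int(cfg["downsample_factor"])
        defective_low = downsample_binary(defective_high, factor)

        stage("completion")
        completion = build_completion_network(defective_low.shape, seed=int(cfg["seed"]))
        completion.net.load(_require(cfg, "completion_checkpoint"))
        completed_low_p = forward_completion(completion, defective_low)
        completed_low = binarize_prediction(completed_low_p, float(cfg["threshold"]))

        stage("enhancement")
        enhancement = build_enhancement_network(
            defective_low.shape, defective_high.shape, seed=int(cfg["seed"])
        )
        enhancement.net.load(_require(cfg, "enhancement_checkpoint"))
        completed_high_p = forward_enhancement(enhancement, completed_low, defective_high)
        completed_high = binarize_prediction(completed_high_p, float(cfg["threshold"]))

        stage("extract_implant")
        implant = extract_implant(
            completed_high, defective_high, float(cfg["tolerance_scale"])
        )

        stage("postprocess")
        implant = postprocess_implant(
            implant, int(cfg["opening_radius"]), int(cfg["keep_components"])
        )

        stage("export")
        for name, v in (
            ("completed_low", completed_low),
            ("completed_high", completed_high),
            ("implant", implant),
        ):
            path = out_dir / f"{name}.nrrd"
            write_volume(v, path)
            manifest["artifacts"][name] = str(path)
        if implant.values.any():
            stl = out_dir / "implant.stl"
            export_mesh(implant, stl)
            manifest["artifacts"]["implant_stl"] = str(stl)

        stage("metrics")
        metrics: dict = {"implant_voxels": implant.ones_count()}
        if cfg.get("ground_truth_implant"):
            truth = read_volume(cfg["ground_truth_implant"])
            if implant.values.any() and truth.values.any():
                metrics.update(score_reconstruction(implant, truth).as_dict())
        manifest["metrics"] = metrics
        metrics_path = out_dir / "metrics.json"
        metrics_path.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        manifest["artifacts"]["metrics"] = str(metrics_path)
    except PipelineError:
        raise
    except Exception as exc:  # attribute failure to the running stage
        raise PipelineError(manifest["stages"][-1] if manifest["stages"] else "setup",
                            str(exc)) from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def phantom_training_samples(
    n_skulls: int = 8,
    defects_per_skull: int = 6,
    dims: tuple[int, int, int] = (32, 32, 24),
    spacing: tuple[float, float, float] = (6.0, 6.0, 6.4),
    seed: int = 0,
    diameter_range_mm: tuple[float, float] = (60.0, 120.0),
    spec_ranges: dict | None = None,
    paired_resolutions: bool = False,
    downsample_factor: int = 4,
) -> list:
    """Phantom-defect samples for supervised training.

    Default (``paired_resolutions=False``): ``(defective, intact)``
    pairs at the working grid ``dims`` — the stage-1 task. With
    ``paired_resolutions=True``: ``(intact_low, defective_high,
    intact_high)`` triples for stage 2, with the low member the
    block-majority downsampling of the intact model (teacher forcing:
    during training the true intact low-res model stands in for the
    stage-1 output).

    Unless ``spec_ranges`` overrides it, the phantom wall thickness is
    set to 2.3-3.0 voxel pitches (never below the anatomical 4.5-8 mm
    range): the completion task's difficulty is governed by the
    discrete shell width, and the reference low-resolution task has
    walls of roughly two to four voxels. Keeping that regime — rather
    than absolute millimetres, which coarse grids cannot resolve
    anyway — is what makes a coarse-grid experiment a faithful
    miniature of it.
    """
    ranges = dict(spec_ranges) if spec_ranges else {}
    if "thickness" not in ranges:
        pitch = max(spacing)
        ranges["thickness"] = (max(2.3 * pitch, 4.5), max(3.0 * pitch, 8.0))
    phantoms = generate_dataset(
        n_skulls, ranges, seed=seed, dims=dims, spacing=spacing,
        low_res_factor=downsample_factor,
    )
    samples = []
    for i, (high, low) in enumerate(phantoms):
        pairs = make_defect_pairs(
            high,
            n_variants=defects_per_skull,
            rng=seed * 10_000 + i,
            diameter_range_mm=diameter_range_mm,
        )
        for pair in pairs:
            if paired_resolutions:
                samples.append((low, pair.defective, high))
            else:
                samples.append((pair.defective, high))
    return samples


def _phantom_training_pairs(cfg: dict, need_high: bool):
    dims = tuple(cfg.get("dims", (32, 32, 32) if need_high else (32, 32, 24)))
    factor = int(cfg.get("downsample_factor", DEFAULTS["downsample_factor"]))
    samples = phantom_training_samples(
        n_skulls=int(cfg.get("n_skulls", 8)),
        defects_per_skull=int(cfg.get("defects_per_skull", 6)),
        dims=dims,
        spacing=tuple(cfg.get("spacing", (6.0, 6.0, 6.4))),
        seed=int(cfg.get("seed", 0)),
        diameter_range_mm=tuple(
            cfg.get("defect_diameter_range_mm", DEFAULTS["defect_diameter_range_mm"])
        ),
        spec_ranges=cfg.get("spec_ranges"),
        paired_resolutions=need_high,
        downsample_factor=factor,
    )
    return samples, dims, factor


def train_completion_from_config(config_path: str | Path) -> dict:
    """Train the stage-1 network on synthetic phantom defects.

    Config keys (all optional): dims, spacing, n_skulls,
    defects_per_skull, epochs, batch_size, seed, checkpoint_out.
    At desk scale (32x32x24 grids) this runs in CPU minutes.
    """
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    samples, dims, _ = _phantom_training_pairs(cfg, need_high=False)
    model = build_completion_network(dims, seed=int(cfg.get("seed", 0)))
    tc = TrainingConfig(
        batch_size=int(cfg.get("batch_size", 10)),
        epochs=int(cfg.get("epochs", 50)),
        seed=int(cfg.get("seed", 0)),
    )
    model, history = train_model(model, samples, tc)
    out = Path(cfg.get("checkpoint_out", "completion.npz"))
    model.net.save(out)
    return {
        "checkpoint": str(out),
        "n_samples": len(samples),
        "best_epoch": history.best_epoch,
        "best_val_loss": min(history.val_loss),
        "history": {"train": history.train_loss, "val": history.val_loss},
    }


def train_enhancement_from_config(config_path: str | Path) -> dict:
    """Train the stage-2 network; the low-resolution input during
    training is the true intact low-res model (teacher forcing)."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    samples, dims, factor = _phantom_training_pairs(cfg, need_high=True)
    low_dims = tuple(d // factor for d in dims)
    model = build_enhancement_network(low_dims, dims, seed=int(cfg.get("seed", 0)))
    tc = TrainingConfig(
        batch_size=int(cfg.get("batch_size", 4)),
        epochs=int(cfg.get("epochs", 20)),
        seed=int(cfg.get("seed", 0)),
    )
    model, history = train_model(model, samples, tc)
    out = Path(cfg.get("checkpoint_out", "enhancement.npz"))
    model.net.save(out)
    return {
        "checkpoint": str(out),
        "n_samples": len(samples),
        "best_epoch": history.best_epoch,
        "best_val_loss": min(history.val_loss),
        "history": {"train": history.train_loss, "val": history.val_loss},
    }
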