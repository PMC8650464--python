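"""End-to-end orchestration: phantom -> relaxometry -> segmentation ->
mesh -> fit -> metrics, driven by a single validated configuration.

Every stage writes its artifacts into the run directory together with a
provenance record (config hash, seed, package version), and each stage's
outputs are plain files a later stage (or a rerun) can pick up.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .discretization import build_mesh, interpolate_idw, tag_subdomains
from .discretization import NodalField
from .fitting import ErrorMaskSpec, grid_search
from .io import save_concentration, save_json, save_signal, save_volume
from .metrics import TransportConstants, build_report
from .phantom import (
    ArtifactSpec,
    build_phantom,
    default_spec,
    injection_location_mm,
    simulate_truth,
    synthesize_signal,
)
from .relaxometry import AcquisitionParams, fit_t1_vfa, signal_to_concentration, total_amount
from .segmentation import SegmentationThresholds, run_segmentation
from .solver import FunctionSpace, SolverConfig, SourceSpec, TransportParams
from .subdomains import Subdomain

__all__ = ["RunConfig", "run_pipeline"]

_STAGES = ("phantom", "relaxometry", "segmentation", "mesh", "fit", "metrics")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "run",
    "stages": list(_STAGES),
    "phantom": {
        "grid_shape": [32, 32, 24],
        "voxel_size": 0.2,
        "true_deff": {"BT": 0.10, "PAS_SURF": 95.0, "PAS_BRANCH": 60.0},
    },
    "acquisition": {
        "tr": 16.0,
        "flip_angles": [3.0, 15.0],
        "r1": 3.2e-3,
        "frame_times": [0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0],
    },
    "artifacts": {
        "noise_model": "gaussian",
        "noise_sigma": 0.02,
        "surface_dropout_voxels": 1,
        "injection_dropout": 30.0,
        "dropout_factor": 0.1,
    },
    "source": {"rate": 0.034, "start": 0.0, "stop": 20.0},
    "segmentation": {},
    "mesh": {"target_cells": None},
    "solver": {"dt": 0.5, "element_order": 1},
    "fit": {
        "grid_bt": [0.03, 0.1, 0.3],
        "grid_surf": [30.0, 95.0, 300.0],
        "grid_branch": [20.0, 60.0, 180.0],
        "max_fit_time": 52.0,
        "injection_radius": 0.5,
    },
    "metrics": {},
}


def _merge_validate(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user and isinstance(dval, dict) and isinstance(user[key], dict):
            out[key] = _merge_validate(dval, user[key], f"{path}{key}.")
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.resolved = _merge_validate(DEFAULT_CONFIG, self.raw)
        bad = [s for s in self.resolved["stages"] if s not in _STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        canon = json.dumps(self.resolved, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns in-memory artifacts.

    All intermediates are persisted under ``output_dir``; a failure in a
    stage leaves earlier outputs on disk.
    """
    cfg = config.resolved
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    artifacts: dict = {}

    save_json(
        out_dir / "provenance.json",
        {"config_hash": config.hash(), "seed": seed, "version": __version__,
         "config": cfg},
    )

    acq = AcquisitionParams(
        tr=cfg["acquisition"]["tr"],
        flip_angles=tuple(cfg["acquisition"]["flip_angles"]),
        r1=cfg["acquisition"]["r1"],
        frame_times=np.asarray(cfg["acquisition"]["frame_times"], dtype=float),
    )
    source_cfg = cfg["source"]
    solver_cfg = SolverConfig(
        dt=cfg["solver"]["dt"], element_order=cfg["solver"]["element_order"]
    )

    stage = "phantom"
    try:
        spec = default_spec(
            grid_shape=tuple(cfg["phantom"]["grid_shape"]),
            voxel_size=cfg["phantom"]["voxel_size"],
            seed=seed,
        )
        gt = build_phantom(spec)
        true_params = TransportParams(
            deff={int(Subdomain[k]): v for k, v in cfg["phantom"]["true_deff"].items()}
        )
        source = SourceSpec(
            location=tuple(injection_location_mm(spec)),
            rate=source_cfg["rate"],
            start=source_cfg["start"],
            stop=source_cfg["stop"],
        )
        conc_true = simulate_truth(gt, true_params, source, acq.frame_times, solver_cfg)
        art = ArtifactSpec(seed=seed, **cfg["artifacts"])
        signal = synthesize_signal(conc_true, gt.t1_map, acq, art, gt.brain_mask)
        save_volume(out_dir / "labels_truth.nii", gt.labels, spec.voxel_size)
        save_volume(out_dir / "t1_truth.nii", np.nan_to_num(gt.t1_map), spec.voxel_size)
        save_concentration(out_dir / "concentration_truth.nii", conc_true)
        save_signal(out_dir / "signal", signal)
        save_json(out_dir / "true_params.json",
                  {"deff": true_params.deff, "source": source_cfg})
        artifacts.update(gt=gt, signal=signal, conc_true=conc_true, source=source)

        stage = "relaxometry"
        if "relaxometry" in cfg["stages"]:
            a_lo, a_hi = acq.flip_angles
            t1 = fit_t1_vfa(signal.baseline(a_lo), signal.baseline(a_hi), acq)
            conc = signal_to_concentration(signal, signal.baseline(a_hi), t1, acq)
            amounts = total_amount(conc, gt.brain_mask)
            save_volume(out_dir / "t1_fit.nii", np.nan_to_num(t1.values), spec.voxel_size)
            save_concentration(out_dir / "concentration.nii", conc)
            np.savetxt(
                out_dir / "amount_vs_time.csv",
                np.column_stack([acq.frame_times, amounts]),
                delimiter=",",
                header="time_min,amount_umol",
                comments="",
            )
            artifacts.update(t1=t1, conc=conc, amounts=amounts)

        stage = "segmentation"
        if "segmentation" in cfg["stages"]:
            thr = SegmentationThresholds(**cfg["segmentation"])
            labels = run_segmentation(
                artifacts["t1"], artifacts["conc"], gt.brain_mask,
                gt.artery_class_map(), thr,
            )
            save_volume(out_dir / "labels.nii", labels.values, spec.voxel_size)
            save_json(out_dir / "labels.json", labels.provenance)
            artifacts["labels"] = labels

        stage = "mesh"
        if "mesh" in cfg["stages"]:
            mesh = build_mesh(
                gt.brain_mask, cfg["mesh"]["target_cells"], spec.voxel_size
            )
            tag_subdomains(mesh, artifacts["labels"].values, spec.voxel_size)
            mesh.write_vtu(out_dir / "mesh.vtu")
            save_json(out_dir / "mesh_quality.json", mesh.quality)
            artifacts["mesh"] = mesh

        stage = "fit"
        if "fit" in cfg["stages"]:
            mesh = artifacts["mesh"]
            space = FunctionSpace(mesh, solver_cfg.element_order)
            node_vals = interpolate_idw(
                artifacts["conc"].frames, voxel_size=spec.voxel_size,
                coords=space.coords,
            )
            data = NodalField(
                values=node_vals, coords=space.coords, times=acq.frame_times,
                tagbits=space.tagbits,
            )
            mask = ErrorMaskSpec(
                injection_radius=cfg["fit"]["injection_radius"],
                injection_site=tuple(injection_location_mm(spec)),
                max_fit_time=cfg["fit"]["max_fit_time"],
            )
            fit = grid_search(
                data, mesh,
                cfg["fit"]["grid_bt"], cfg["fit"]["grid_surf"], cfg["fit"]["grid_branch"],
                source, solver_cfg, mask,
            )
            fit.to_dataframe().to_csv(out_dir / "error_surface.csv", index=False)
            save_json(out_dir / "fit.json", fit.to_dict())
            artifacts["fit"] = fit

        stage = "metrics"
        if "metrics" in cfg["stages"]:
            fit = artifacts["fit"]
            constants = TransportConstants(**cfg["metrics"])
            report = build_report(
                {
                    int(Subdomain.BT): fit.optimum[0],
                    int(Subdomain.PAS_SURF): fit.optimum[1],
                    int(Subdomain.PAS_BRANCH): fit.optimum[2],
                },
                constants,
            )
            report.to_json(out_dir / "metrics.json")
            (out_dir / "metrics.txt").write_text(report.to_table() + "\n")
            artifacts["report"] = report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return artifacts
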