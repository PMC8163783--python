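"""Experiment orchestration: YAML config schema, run manifests, metrics.

A run directory contains ``config.yaml`` (snapshot), ``manifest.json``
(written before any compute), ``metrics.csv`` and ``checkpoints/``.  Every
number in a metrics file is traceable to the manifest's config hash and
root seed.
"""

from __future__ import annotations

import hashlib
import json
import shutil
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .solver import SimulationParams

__all__ = ["ConfigError", "load_config", "validate_config", "run_experiment",
           "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Invalid experiment configuration; message names the offending keys."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "runs/exp",
    "units": {
        "kinds": ["pipe", "bifurcation"],
        "n_geometries": 8,
        "n_boundary_values": 4,
        "n_steps": 20,
    },
    "training": {
        "epochs": 20,
        "batch_size": 16,
        "split": 0.75,
        "loss_mode": "mse+pde",
        "n_gn_steps": 3,
    },
    "networks": {
        "enabled": False,
        "n_train": 3,
        "n_test": 2,
        "n_steps": 20,
        "assembly_epochs": 10,
        "alpha": 10.0,
    },
    "physics": {
        "D": 1.0, "k_plus": 1.0, "kp_plus": 0.5, "u_i": 0.1,
        "dt": 0.1, "lambda_in": 2.0,
    },
}


def _check_keys(cfg: dict, ref: dict, path: str = "") -> list[str]:
    bad = []
    for k, v in cfg.items():
        if k not in ref:
            bad.append(f"{path}{k}")
        elif isinstance(v, dict) and isinstance(ref[k], dict):
            bad += _check_keys(v, ref[k], f"{path}{k}.")
    return bad


def validate_config(cfg: dict) -> dict:
    """Merge onto defaults; unknown keys raise :class:`ConfigError`."""
    bad = _check_keys(cfg, DEFAULT_CONFIG)
    if bad:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(bad))}")

    def merge(base, over):
        out = dict(base)
        for k, v in over.items():
            out[k] = merge(base[k], v) if isinstance(v, dict) else v
        return out

    return merge(DEFAULT_CONFIG, cfg)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return validate_config(raw)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_experiment(config_path: str | Path) -> dict:
    """Execute generate → train → evaluate per the config; returns the
    manifest.  All artifacts live under the configured run directory."""
    from .train import (TrainingConfig, cross_validate, evaluate_mre,
                        make_network_cases, make_unit_dataset,
                        network_rollout_mre, train_assembly, train_simulator,
                        _split_indices)

    cfg = load_config(config_path)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "checkpoints").mkdir(exist_ok=True)
    shutil.copy(config_path, outdir / "config.yaml")

    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "artifacts": {"metrics": "metrics.csv", "checkpoints": "checkpoints/"},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    phys = cfg["physics"]
    params = SimulationParams(D=phys["D"], k_plus=phys["k_plus"], k_minus=phys["k_plus"],
                              kp_plus=phys["kp_plus"], kp_minus=phys["kp_plus"],
                              u_i=phys["u_i"], dt=phys["dt"],
                              lambda_in=phys["lambda_in"])
    tc = TrainingConfig(epochs=cfg["training"]["epochs"],
                        batch_size=cfg["training"]["batch_size"],
                        split=cfg["training"]["split"],
                        loss_mode=cfg["training"]["loss_mode"],
                        n_gn_steps=cfg["training"]["n_gn_steps"],
                        seed=cfg["seed"])

    rows = []
    simulators = {}
    for kind in cfg["units"]["kinds"]:
        ds = make_unit_dataset(kind, cfg["units"]["n_geometries"],
                               cfg["units"]["n_boundary_values"],
                               cfg["units"]["n_steps"], seed=cfg["seed"],
                               params=params)
        model, log = train_simulator(ds, tc)
        rng = np.random.default_rng(tc.seed)
        _, test_idx = _split_indices(len(ds), tc.split, rng)
        score = evaluate_mre(model, ds, test_idx)
        model.save(outdir / "checkpoints" / f"{kind}.npz")
        simulators[kind] = model
        rows.append({"stage": "simulator", "kind": kind,
                     "metric": "test_mre_percent", "value": score,
                     "n_samples": len(ds), "seed": cfg["seed"]})

    if cfg["networks"]["enabled"]:
        ncfg = cfg["networks"]
        cases = make_network_cases(ncfg["n_train"] + ncfg["n_test"],
                                   ncfg["n_steps"], seed=cfg["seed"] + 7,
                                   params=params)
        train_cases = cases[:ncfg["n_train"]]
        test_cases = cases[ncfg["n_train"]:]
        atc = replace(tc, epochs=ncfg["assembly_epochs"])
        amodel, _ = train_assembly(simulators, train_cases, atc,
                                   alpha=ncfg["alpha"])
        scores = [network_rollout_mre(simulators, amodel, c) for c in test_cases]
        rows.append({"stage": "network", "kind": "assembly",
                     "metric": "rollout_mre_percent",
                     "value": float(np.mean(scores)),
                     "n_samples": len(test_cases), "seed": cfg["seed"]})

    pd.DataFrame(rows).to_csv(outdir / "metrics.csv", index=False)
    return manifest
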