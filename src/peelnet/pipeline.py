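"""End-to-end pipeline driver.

A YAML config describes the stages to run — synthetic data generation,
region localization/refinement, classifier training, cross-device
meta-adaptation, evaluation — and every run writes its seed, a copy of the
config, and JSON reports into a run directory, so a run is reproducible
from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
from dataclasses import replace

import numpy as np
import pandas as pd
import yaml

from .detect import ContrastDetector, localize_and_refine
from .meta import DomainDataset, MetaConfig, adapt_and_evaluate, direct_transfer_evaluate, meta_train
from .metrics import compute_metrics, relative_improvement
from .model import (
    InteractionConfig,
    MultiStreamClassifier,
    TrainConfig,
    train_classifier,
)
from .nn.layers import BackboneConfig
from .refine import RefinementParams, as_gray_image, refine_box
from .synth import generate_dataset, load_crops
from PIL import Image

log = logging.getLogger("peelnet")

__all__ = ["load_config", "run_pipeline", "localize_manifest"]

DEFAULT_CONFIG = {
    "seed": 0,
    "generate": {"enabled": True, "n_per_class": 24, "size": 160},
    "localize": {"enabled": True, "step": 1, "tau": 20.0},
    "train": {
        "enabled": True,
        "device": "cam0",
        "crop_size": 64,
        "epochs": 20,
        "lr": 1e-3,
        "batch_size": 8,
        "interaction": {"active": True, "forward_ratio": 0.10, "reverse_ratio": 0.05, "stage": 2},
    },
    "meta": {"enabled": False, "targets": ["cam1", "cam2"], "iterations": 10, "k_shot": 5, "runs": 10},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | None) -> dict:
    """Read a YAML pipeline config, filling defaults for missing keys."""
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def localize_manifest(manifest: pd.DataFrame, root: str, params: RefinementParams) -> pd.DataFrame:
    """Run detection + refinement over every manifest image; returns a table
    of refined boxes (one row per image and region kind)."""
    det = ContrastDetector()
    rows = []
    for _, row in manifest.iterrows():
        img = np.asarray(Image.open(os.path.join(root, row["path"])).convert("RGB"))
        try:
            loc = localize_and_refine(img, det, params)
        except Exception as exc:  # noqa: BLE001 - keep going, record the miss
            log.warning("localization failed for %s: %s", row["path"], exc)
            continue
        for d, r in zip(loc.detections, loc.refined):
            rows.append(
                {
                    "image_id": row["path"],
                    "kind": d.kind,
                    "x1": r.box.x1,
                    "y1": r.box.y1,
                    "x2": r.box.x2,
                    "y2": r.box.y2,
                    "converged": r.converged,
                    "iterations": r.iterations,
                }
            )
    return pd.DataFrame(rows)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: dict, run_dir: str, dry_run: bool = False) -> dict:
    """Execute the configured stages, logging artifacts under ``run_dir``.

    Returns a summary dict (also written to ``run_dir/metrics.json``).
    With ``dry_run`` the config is validated and echoed but nothing runs.
    """
    seed = int(config.get("seed", 0))
    summary: dict = {"seed": seed, "config_hash": _config_hash(config)}
    if dry_run:
        summary["dry_run"] = True
        return summary
    os.makedirs(run_dir, exist_ok=True)
    with open(os.path.join(run_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config, fh)

    data_dir = config.get("data_dir") or os.path.join(run_dir, "data")
    gen = config["generate"]
    if gen["enabled"]:
        n = int(gen["n_per_class"])
        manifest = generate_dataset(
            data_dir,
            class_counts={190: n, 560: n, 2800: n, 3300: n},
            seed=seed,
            size=int(gen["size"]),
        )
        log.info("generated %d manifest rows under %s", len(manifest), data_dir)
    else:
        manifest = pd.read_csv(os.path.join(data_dir, "manifest.csv"))
    summary["n_images"] = int(len(manifest))

    loc = config["localize"]
    if loc["enabled"]:
        params = RefinementParams(step=int(loc["step"]), tau=float(loc["tau"]))
        boxes = localize_manifest(manifest, data_dir, params)
        boxes.to_csv(os.path.join(run_dir, "boxes.csv"), index=False)
        summary["localization"] = {
            "n_boxes": int(len(boxes)),
            "convergence_rate": float(boxes["converged"].mean()) if len(boxes) else 0.0,
        }

    tr = config["train"]
    model = None
    params_best = None
    if tr["enabled"]:
        crop = int(tr["crop_size"])
        data_train = load_crops(manifest, data_dir, crop, device=tr["device"], split="train")
        data_val = load_crops(manifest, data_dir, crop, device=tr["device"], split="val")
        data_test = load_crops(manifest, data_dir, crop, device=tr["device"], split="test")
        icfg = tr["interaction"]
        model = MultiStreamClassifier(
            backbone=BackboneConfig.reduced(),
            interaction=InteractionConfig(
                active=bool(icfg["active"]),
                forward_ratio=float(icfg["forward_ratio"]),
                reverse_ratio=float(icfg["reverse_ratio"]),
                stage=int(icfg["stage"]),
                seed=seed,
            ),
        )
        p0 = model.init_params(seed)
        tcfg = TrainConfig(lr=float(tr["lr"]), epochs=int(tr["epochs"]), batch_size=int(tr["batch_size"]))
        x_tr = (data_train["whole"], data_train["exocarp"], data_train["albedo"])
        x_va = (data_val["whole"], data_val["exocarp"], data_val["albedo"])
        params_best, history = train_classifier(model, p0, (x_tr, data_train["y"]), (x_va, data_val["y"]), tcfg, seed=seed)
        x_te = (data_test["whole"], data_test["exocarp"], data_test["albedo"])
        report = compute_metrics(model.predict(params_best, x_te), data_test["y"])
        summary["test_metrics"] = report.as_dict()
        np.savetxt(os.path.join(run_dir, "confusion.csv"), report.confusion, fmt="%d", delimiter=",")
        log.info("test accuracy %.3f", report.accuracy)

    meta_cfg = config["meta"]
    if meta_cfg["enabled"]:
        if model is None or params_best is None:
            raise RuntimeError("meta stage requires the train stage")
        crop = int(tr["crop_size"])
        rng = np.random.default_rng(seed + 1)
        src = load_crops(manifest, data_dir, crop, device=tr["device"], split="train")
        source = DomainDataset(tr["device"], (src["whole"], src["exocarp"], src["albedo"]), src["y"], role="source")
        mcfg = MetaConfig(
            meta_iterations=int(meta_cfg["iterations"]),
            k_shot=int(meta_cfg["k_shot"]),
            tasks_per_batch=2,
            query_per_class=8,
        )
        theta, _ = meta_train(source, model, mcfg, rng, init_params=params_best)
        summary["meta"] = {}
        for tid in meta_cfg["targets"]:
            tgt_data = load_crops(manifest, data_dir, crop, device=tid)
            tgt = DomainDataset(tid, (tgt_data["whole"], tgt_data["exocarp"], tgt_data["albedo"]), tgt_data["y"], role="target")
            direct = direct_transfer_evaluate(model, theta, tgt)
            adapted = adapt_and_evaluate(model, theta, tgt, mcfg, rng, n_runs=int(meta_cfg["runs"]))
            summary["meta"][tid] = {
                "direct_accuracy": direct["accuracy"],
                "adapted_mean": adapted.mean_accuracy,
                "adapted_std": adapted.std_accuracy,
                "relative_improvement_pct": relative_improvement(
                    direct["accuracy"] * 100, adapted.mean_accuracy * 100
                )
                if direct["accuracy"] > 0
                else None,
            }

    with open(os.path.join(run_dir, "metrics.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
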