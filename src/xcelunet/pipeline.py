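"""End-to-end pipeline: generation, preprocessing, two-stage training,
inference, GradCAM and evaluation, driven by one YAML config.

Each stage writes its artifacts under ``outdir/<stage>/`` together with a
hash of its effective inputs (stage config + upstream stage hashes); a
rerun with unchanged configuration is a cache hit and the stage is skipped.
A run manifest records the config snapshot, seeds, package version, stage
hashes and output paths, which is sufficient to re-execute the run
bit-identically on one device.

Exit codes: 0 ok, 2 config error, 3 data error, 4 numerical failure.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

EXIT_OK = 0
EXIT_CONFIG = 2
EXIT_DATA = 3
EXIT_NUMERIC = 4

_STAGES = ("generate", "train_seg", "train_cls", "evaluate", "gradcam")
_TOP_KEYS = {"seed", "outdir", "stages"} | set(_STAGES)


class ConfigError(ValueError):
    pass


def _load_config(path: str | Path) -> dict:
    import yaml

    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:  # malformed YAML
        raise ConfigError(f"cannot parse config: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    for key in raw:
        if key not in _TOP_KEYS:
            raise ConfigError(f"unknown config field: {key!r}")
    raw.setdefault("seed", 0)
    raw.setdefault("outdir", "runs/run")
    raw.setdefault("stages", [s for s in _STAGES if s in raw] or list(_STAGES))
    for stage in raw["stages"]:
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage: {stage!r}")
        raw.setdefault(stage, {})
    return raw


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_seed(root_seed: int, stage: str) -> int:
    return int(
        np.random.SeedSequence([root_seed, _STAGES.index(stage)]).generate_state(1)[0]
        % (2**31 - 1)
    )


class Pipeline:
    def __init__(self, config: dict):
        self.config = config
        self.outdir = Path(config["outdir"])
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists() else {"stages": {}}
        )
        self.manifest["config"] = config
        from . import __version__

        self.manifest["version"] = __version__
        self.manifest["root_seed"] = config["seed"]

    def _cached(self, stage: str, stage_hash: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        return bool(rec and rec.get("hash") == stage_hash
                    and all(Path(p).exists() for p in rec.get("outputs", [])))

    def _record(self, stage: str, stage_hash: str, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "hash": stage_hash,
            "outputs": outputs,
            "seed": _stage_seed(self.config["seed"], stage),
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    # -- stages ---------------------------------------------------------------

    def run(self) -> int:
        upstream = ""
        for stage in self.config["stages"]:
            cfg = self.config[stage]
            stage_hash = _hash([stage, cfg, upstream, self.config["seed"]])
            if self._cached(stage, stage_hash):
                print(f"[{stage}] cache hit, skipping")
            else:
                getattr(self, f"_run_{stage}")(cfg, stage_hash)
            upstream = stage_hash
        return EXIT_OK

    def _phantoms(self):
        from .synthetic import generate_dataset

        cfg = self.config["generate"]
        edge = int(cfg.get("grid", 48))
        return generate_dataset(
            int(cfg.get("n", 24)),
            seed=_stage_seed(self.config["seed"], "generate"),
            grid_shape=(edge,) * 3,
            spacing_mm=float(cfg.get("spacing", 1.0)),
        )

    def _run_generate(self, cfg: dict, stage_hash: str) -> None:
        from .synthetic import save_phantom

        out = self.outdir / "generate"
        phantoms = self._phantoms()
        outputs = []
        rows = ["id,os,js,hsa"]
        for i, ph in enumerate(phantoms):
            stem = f"phantom_{i:03d}"
            save_phantom(ph, out, stem)
            rows.append(f"{stem},{ph.truth.os_grade},{ph.truth.js_grade},{ph.truth.hsa}")
            outputs.append(str(out / f"{stem}_ct.nii.gz"))
        (out / "truth.csv").write_text("\n".join(rows) + "\n")
        outputs.append(str(out / "truth.csv"))
        self._record("generate", stage_hash, outputs)

    def _run_train_seg(self, cfg: dict, stage_hash: str) -> None:
        from .network import NetworkConfig, build_model, save_weights
        from .preprocessing import build_dseg
        from .training import TrainConfig, train_segmentation

        out = self.outdir / "train_seg"
        out.mkdir(parents=True, exist_ok=True)
        phantoms = self._phantoms()
        dseg = build_dseg(phantoms, patch_edge=cfg.get("patch_edge"))
        seed = _stage_seed(self.config["seed"], "train_seg")
        tc = TrainConfig(
            seed=seed,
            max_epochs=int(cfg.get("max_epochs", 20)),
            batch_size=int(cfg.get("batch_size", 2)),
            early_stop_patience=int(cfg.get("patience", 40)),
            stop_at_val_dice=cfg.get("stop_at_val_dice"),
            network=NetworkConfig(seed=seed),
        )
        weights, record = train_segmentation(dseg, tc)
        model = build_model(tc.network)
        model.load_state_dict(weights)
        save_weights(model, out / "seg_weights.npz")
        (out / "run_record.json").write_text(
            json.dumps(asdict(record), indent=2, default=str)
        )
        self._record("train_seg", stage_hash,
                     [str(out / "seg_weights.npz"),
                      str(out / "run_record.json")])

    def _run_train_cls(self, cfg: dict, stage_hash: str) -> None:
        from .network import NetworkConfig, build_model, save_weights
        from .preprocessing import build_dcls
        from .training import TrainConfig, train_classification

        out = self.outdir / "train_cls"
        out.mkdir(parents=True, exist_ok=True)
        seg_seed = _stage_seed(self.config["seed"], "train_seg")
        with np.load(self.outdir / "train_seg" / "seg_weights.npz") as data:
            weights = {k: data[k] for k in data.files}
        phantoms = self._phantoms()
        crop_edge = int(cfg.get("crop_edge", 32))
        dcls = build_dcls(phantoms, crop_edge=crop_edge)
        seed = _stage_seed(self.config["seed"], "train_cls")
        tc = TrainConfig(
            seed=seed,
            freeze_setup=str(cfg.get("setup", "FT-E")),
            max_epochs=int(cfg.get("max_epochs", 30)),
            batch_size=int(cfg.get("batch_size", 8)),
            early_stop_patience=int(cfg.get("patience", 40)),
            stop_at_val_accuracy=cfg.get("stop_at_val_accuracy"),
            network=NetworkConfig(seed=seg_seed),
        )
        weights2, record = train_classification(weights, dcls, tc)
        model = build_model(tc.network)
        model.load_state_dict(weights2)
        save_weights(model, out / "cls_weights.npz")
        (out / "run_record.json").write_text(
            json.dumps(asdict(record), indent=2, default=str)
        )
        self._record("train_cls", stage_hash,
                     [str(out / "cls_weights.npz"),
                      str(out / "run_record.json")])

    def _run_evaluate(self, cfg: dict, stage_hash: str) -> None:
        from .network import NetworkConfig
        from .surfaces import labels_to_mesh, one_way_distances, overlap_metrics
        from .training import predict

        out = self.outdir / "evaluate"
        out.mkdir(parents=True, exist_ok=True)
        with np.load(self.outdir / "train_cls" / "cls_weights.npz") as data:
            weights = {k: data[k] for k in data.files}
        seg_seed = _stage_seed(self.config["seed"], "train_seg")
        phantoms = self._phantoms()
        n_eval = int(cfg.get("n_eval", min(4, len(phantoms))))
        crop_edge = int(cfg.get("crop_edge", 32))
        rows = ["id,dice_humerus,dice_scapula,rmse_humerus_mm,hausdorff_humerus_mm,"
                "os_true,os_pred,js_true,js_pred,hsa_true,hsa_pred"]
        for i, ph in enumerate(phantoms[:n_eval]):
            res = predict(weights, ph.ct, net_cfg=NetworkConfig(seed=seg_seed),
                          crop_edge=crop_edge)
            ov = overlap_metrics(res.labels, ph.labels)
            if (res.labels.data == 1).any():
                pred_mesh = labels_to_mesh(res.labels, 1)
                rep = one_way_distances(ph.humerus_morph_mesh, pred_mesh)
                rmse, hd = rep.rmse, rep.hausdorff
            else:
                rmse = hd = float("nan")
            c = res.conditions
            rows.append(
                f"{i},{ov.dice[1]},{ov.dice[2]},{rmse},{hd},"
                f"{ph.truth.os_grade},{c.os_grade if c else ''},"
                f"{ph.truth.js_grade},{c.js_grade if c else ''},"
                f"{ph.truth.hsa},{c.hsa if c else ''}"
            )
        (out / "metrics.csv").write_text("\n".join(rows) + "\n")
        self._record("evaluate", stage_hash, [str(out / "metrics.csv")])

    def _run_gradcam(self, cfg: dict, stage_hash: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .gradcam import compute_gradcam, overlay
        from .network import NetworkConfig, build_model
        from .preprocessing import build_dcls

        out = self.outdir / "gradcam"
        out.mkdir(parents=True, exist_ok=True)
        with np.load(self.outdir / "train_cls" / "cls_weights.npz") as data:
            weights = {k: data[k] for k in data.files}
        seg_seed = _stage_seed(self.config["seed"], "train_seg")
        model = build_model(NetworkConfig(seed=seg_seed))
        model.load_state_dict(weights)
        phantoms = self._phantoms()
        crop_edge = int(cfg.get("crop_edge", 32))
        crops = build_dcls(phantoms[:1], crop_edge=crop_edge,
                           augment_flips=False)
        task = str(cfg.get("task", "OS")).upper()
        cls_idx = int(cfg.get("class_index", crops[0].labels.os_grade))
        act = compute_gradcam(model, crops[0], task, cls_idx)
        montage = overlay(act, crops[0])
        png = out / f"gradcam_{task}_{cls_idx}.png"
        plt.imsave(png, montage)
        np.save(out / "heatmap.npy", act.heatmap)
        self._record("gradcam", stage_hash, [str(png), str(out / "heatmap.npy")])


def run_pipeline(config_path: str | Path) -> int:
    """Execute the configured stages in order; returns a process exit code."""
    try:
        config = _load_config(config_path)
    except ConfigError as exc:
        print(f"config error: {exc}")
        return EXIT_CONFIG
    try:
        return Pipeline(config).run()
    except (ValueError, KeyError, FileNotFoundError) as exc:
        print(f"data error: {exc}")
        return EXIT_DATA
    except (RuntimeError, FloatingPointError, np.linalg.LinAlgError) as exc:
        print(f"numerical failure: {exc}")
        return EXIT_NUMERIC
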