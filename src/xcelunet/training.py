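"""Two-stage training protocol and the inference pipeline.

Stage 1 trains the segmentation module (encoder, mask decoder, contour
decoder) by minimizing the region plus contour losses, with the Dice-weight
``alpha`` following its warm-down schedule per epoch and ``beta`` recomputed
per batch as the boundary-voxel fraction.  Stage 2 trains the clinical
staging branch on GH crops under one of the TL / FT-B / FT-E / FT-N freeze
setups with class-balanced cross-entropy.  Optimization uses Adam at
learning rate 1e-4; early stopping aborts after a configured number of
consecutive epochs without validation-loss improvement and the best-epoch
weights are returned.

During stage 2 only the classification path (encoder, bottleneck, heads) is
evaluated: the classification loss carries no gradient into the decoders,
so skipping their forward pass is exact (a joint segmentation-loss switch
exists but defaults off).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .core import ConditionLabels, CTVolume, GHCrop, LabelVolume
from .layers import Adam
from .losses import (
    alpha_schedule,
    beta_fraction,
    class_weights,
    classification_loss_from_logits,
    contour_loss,
    dice_score,
    distance_weight_maps,
    edge_targets,
    one_hot,
    region_loss,
    ClassWeightTable,
)
from .network import (
    FREEZE_SETUPS,
    NetworkConfig,
    XCELUNet,
    apply_freeze,
    build_model,
)
from .preprocessing import extract_gh_crop, extract_patches, hu_normalize, stitch_patches

__all__ = [
    "TrainConfig",
    "RunRecord",
    "EarlyStopping",
    "split_sizes",
    "train_segmentation",
    "train_classification",
    "predict",
    "PredictionResult",
]


def split_sizes(n_cases: int, test_fraction: float = 0.15) -> tuple[int, int]:
    """(train+val, test) case counts for a fractional random split."""
    n_test = int(round(n_cases * test_fraction))
    return n_cases - n_test, n_test


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without val improvement."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.since_best = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record epoch (1-based); returns True if training should stop."""
        if val_loss < self.best:
            self.best, self.best_epoch, self.since_best = val_loss, epoch, 0
        else:
            self.since_best += 1
        return self.since_best >= self.patience


@dataclass
class TrainConfig:
    lr: float = 1e-4                     # Adam learning rate
    batch_size: int = 2
    max_epochs: int = 100
    early_stop_patience: int = 40        # epochs without val improvement
    val_fraction: float = 0.15
    seed: int = 0
    freeze_setup: str = "FT-E"           # stage-2 only
    network: NetworkConfig | None = None
    joint_seg_loss: bool = False         # replay seg losses in stage 2
    stop_at_val_dice: float | None = None        # stage-1 train-until-good
    stop_at_val_accuracy: float | None = None    # stage-2 train-until-good
    stop_metric_task: str = "os"
    split_group_size: int = 1  # e.g. 2 keeps a crop and its mirror together
    # stage-2 optimization schedule: the heads are first fitted on pooled
    # bottleneck features cached from the frozen encoder (cheap full-batch
    # steps), then the requested freeze setup fine-tunes with the
    # segmentation groups at a reduced learning rate
    head_warmup_steps: int = 2000
    head_warmup_lr: float = 3e-3
    finetune_lr_scale: float = 0.1

    def __post_init__(self):
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class RunRecord:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    val_metrics: list[float] = field(default_factory=list)
    stopping_epoch: int = 0
    best_epoch: int = 0
    stop_reason: str = ""
    seed: int = 0
    wall_time_s: float = 0.0
    config: dict = field(default_factory=dict)


def _split(n: int, val_fraction: float, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_val = max(1, int(round(n * val_fraction))) if n > 1 else 0
    return idx[n_val:], idx[:n_val]


def _as_array(vol) -> np.ndarray:
    return vol.data if isinstance(vol, (CTVolume, LabelVolume, GHCrop)) else np.asarray(vol)


def train_segmentation(dseg, cfg: TrainConfig) -> tuple[dict, RunRecord]:
    """Stage 1: fit the segmentation module on (volume, labels) pairs.

    ``dseg`` is a list of (normalized volume, label volume) pairs whose
    edges are divisible by the network's downsampling factor.  Returns the
    best-validation state dict and the run record.
    """
    if not dseg:
        raise ValueError("empty segmentation corpus")
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    net_cfg = cfg.network or NetworkConfig(seed=cfg.seed)
    model = build_model(net_cfg)

    vols = [np.asarray(_as_array(v), dtype=np.float32) for v, _ in dseg]
    labs = [np.asarray(_as_array(l), dtype=np.int16) for _, l in dseg]
    spacing = (dseg[0][1].spacing_mm
               if isinstance(dseg[0][1], LabelVolume) else (1.0,) * 3)
    onehots = [one_hot(l[None], 3)[0] for l in labs]
    edges = [edge_targets(l) for l in labs]
    edge_onehots = [one_hot(e[None], 3)[0] for e in edges]
    wmaps = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for l in labs:
            wmaps.append(distance_weight_maps(l, spacing))

    train_idx, val_idx = _split(len(dseg), cfg.val_fraction, rng)
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, np.array([], dtype=int)

    opt = Adam(model.parameters(), lr=cfg.lr)
    record = RunRecord(seed=cfg.seed, config=asdict(cfg))
    stopper = EarlyStopping(cfg.early_stop_patience)
    best_state = model.state_dict()

    def batch_loss(ids, alpha):
        x = np.stack([vols[i] for i in ids])[:, None]
        t_region = np.stack([onehots[i] for i in ids])
        t_edges = np.stack([edge_onehots[i] for i in ids])
        w_near = np.stack([wmaps[i][0] for i in ids])
        w_far = np.stack([wmaps[i][1] for i in ids])
        beta = beta_fraction(np.stack([edges[i] for i in ids]))
        out = model.forward(x, seg=True, cls=False)
        l_r = region_loss(out["md_probs"], t_region, alpha, w_near)
        l_c = contour_loss(out["cd_probs"], t_edges, beta, w_near, w_far)
        d = dice_score(out["md_probs"], t_region)
        return l_r + l_c, float(d.data)

    for epoch in range(cfg.max_epochs):
        alpha = alpha_schedule(epoch)
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            ids = order[start:start + cfg.batch_size]
            loss, _ = batch_loss(ids, alpha)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch + 1}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        record.train_losses.append(float(np.mean(epoch_losses)))

        eval_idx = val_idx if len(val_idx) else train_idx
        with no_grad():
            v_losses, v_dices = [], []
            for start in range(0, len(eval_idx), cfg.batch_size):
                ids = eval_idx[start:start + cfg.batch_size]
                loss, d = batch_loss(ids, alpha)
                v_losses.append(float(loss.data))
                v_dices.append(d)
        val_loss = float(np.mean(v_losses))
        val_dice = float(np.mean(v_dices))
        record.val_losses.append(val_loss)
        record.val_metrics.append(val_dice)
        record.stopping_epoch = epoch + 1

        should_stop = stopper.update(val_loss, epoch + 1)
        if stopper.since_best == 0:
            best_state = model.state_dict()
        record.best_epoch = stopper.best_epoch
        if cfg.stop_at_val_dice is not None and val_dice >= cfg.stop_at_val_dice:
            best_state, record.best_epoch = model.state_dict(), epoch + 1
            record.stop_reason = "target validation Dice reached"
            break
        if should_stop:
            record.stop_reason = "early stopping (patience exhausted)"
            break
    else:
        record.stop_reason = "max_epochs reached"
    record.wall_time_s = time.time() - t0
    return best_state, record


def _heads_from_pooled(model: XCELUNet, pooled: Tensor) -> dict[str, Tensor]:
    h = model.cls_dense2(model.cls_dense1(pooled).relu()).relu()
    return {"os": model.os_head(h), "js": model.js_head(h),
            "hsa": model.hsa_head(h)}


def _warmup_heads(model: XCELUNet, xs: np.ndarray, train_idx: np.ndarray,
                  truth_all: dict, tables: dict, cfg: TrainConfig) -> None:
    """Fit the classification heads on cached pooled bottleneck features.

    While the heads are still uninformative, fine-tuning gradients into the
    encoder are noise, and the pooled features do not change — so the head
    can be brought to convergence with cheap full-batch steps on features
    computed once from the stage-1 encoder.  Only classification-branch
    parameters move here.
    """
    feats = []
    batch = max(cfg.batch_size, 1)
    with no_grad():
        for start in range(0, len(train_idx), batch):
            out = model.forward(xs[train_idx[start:start + batch]],
                                seg=False, cls=False)
            feats.append(out["bottleneck"].data.mean(axis=(2, 3, 4)))
    f = Tensor(np.concatenate(feats))
    truth = {k: v[train_idx] for k, v in truth_all.items()}
    opt = Adam(model.parameter_groups()["classification"],
               lr=cfg.head_warmup_lr)
    for _ in range(cfg.head_warmup_steps):
        loss = classification_loss_from_logits(
            _heads_from_pooled(model, f), truth, tables
        )
        opt.zero_grad()
        loss.backward()
        opt.step()


def _task_truth(crops: list[GHCrop]) -> dict[str, np.ndarray]:
    return {
        "os": np.array([c.labels.os_grade for c in crops]),
        "js": np.array([c.labels.js_grade for c in crops]),
        "hsa": np.array([c.labels.hsa for c in crops]),
    }


def _task_weights(truth: dict[str, np.ndarray]) -> dict[str, ClassWeightTable]:
    sizes = {"os": 3, "js": 3, "hsa": 2}
    tables = {}
    for task, n in sizes.items():
        counts = np.bincount(truth[task], minlength=n)
        if (counts == 0).any():
            warnings.warn(
                f"{task}: a class is absent from the corpus; class balancing "
                "is undefined, using uniform weights"
            )
            tables[task] = ClassWeightTable(weights=(1.0 / n,) * n,
                                            counts=tuple(counts))
        else:
            tables[task] = class_weights(counts)
    return tables


def _accuracies(out: dict, truth: dict[str, np.ndarray]) -> dict[str, float]:
    acc = {}
    for task in ("os", "js"):
        pred = out[f"{task}_probs"].data.argmax(axis=1)
        acc[task] = float((pred == truth[task]).mean())
    pred = (out["hsa_probs"].data.ravel() >= 0.5).astype(int)
    acc["hsa"] = float((pred == truth["hsa"]).mean())
    return acc


def train_classification(weights: dict, dcls: list[GHCrop],
                         cfg: TrainConfig) -> tuple[dict, RunRecord]:
    """Stage 2: fit the clinical-staging heads under a freeze setup.

    ``weights`` is the stage-1 state dict; under TL all segmentation
    parameters are bit-identical before and after.
    """
    if not dcls:
        raise ValueError("empty classification corpus")
    for crop in dcls:
        if crop.labels is None:
            raise ValueError("every GH crop needs condition labels")
    if cfg.freeze_setup not in FREEZE_SETUPS:
        raise ValueError(f"unknown freeze setup {cfg.freeze_setup!r}")
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    net_cfg = cfg.network or NetworkConfig(seed=cfg.seed)
    model = build_model(net_cfg)
    model.load_state_dict(weights)
    apply_freeze(model, cfg.freeze_setup)

    xs = np.stack([np.asarray(c.data, dtype=np.float32) for c in dcls])[:, None]
    truth_all = _task_truth(dcls)
    tables = _task_weights(truth_all)

    g = cfg.split_group_size
    if g > 1 and len(dcls) % g == 0:
        # split at group granularity (augmented copies stay with their source)
        gtrain, gval = _split(len(dcls) // g, cfg.val_fraction, rng)
        train_idx = np.array([gi * g + j for gi in gtrain for j in range(g)])
        val_idx = np.array([gi * g + j for gi in gval for j in range(g)],
                           dtype=int)
    else:
        train_idx, val_idx = _split(len(dcls), cfg.val_fraction, rng)
    if len(train_idx) == 0:
        train_idx, val_idx = val_idx, np.array([], dtype=int)

    if cfg.max_epochs > 0 and cfg.head_warmup_steps > 0:
        _warmup_heads(model, xs, train_idx, truth_all, tables, cfg)

    # discriminative fine-tuning: segmentation groups (when trainable) step
    # at a reduced rate so early head gradients cannot wreck the features
    groups = model.parameter_groups()
    seg_params = [p for gname in ("encoder", "bottleneck", "decoders")
                  for p in groups[gname] if p.requires_grad]
    optimizers = [Adam(groups["classification"], lr=cfg.lr)]
    if seg_params:
        optimizers.append(Adam(seg_params, lr=cfg.lr * cfg.finetune_lr_scale))
    record = RunRecord(seed=cfg.seed, config=asdict(cfg))
    stopper = EarlyStopping(cfg.early_stop_patience)
    best_state = model.state_dict()

    def eval_ids(ids):
        out = model.forward(xs[ids], seg=cfg.joint_seg_loss, cls=True)
        truth = {k: v[ids] for k, v in truth_all.items()}
        heads = {"os": out["os_logits"], "js": out["js_logits"],
                 "hsa": out["hsa_logits"]}
        return classification_loss_from_logits(heads, truth, tables), out, truth

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            ids = order[start:start + cfg.batch_size]
            loss, _, _ = eval_ids(ids)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite classification loss at epoch {epoch + 1}"
                )
            for opt in optimizers:
                opt.zero_grad()
            loss.backward()
            for opt in optimizers:
                opt.step()
            epoch_losses.append(float(loss.data))
        record.train_losses.append(float(np.mean(epoch_losses)))

        eval_set = val_idx if len(val_idx) else train_idx
        with no_grad():
            loss, out, truth = eval_ids(eval_set)
            accs = _accuracies(out, truth)
        val_loss = float(loss.data)
        record.val_losses.append(val_loss)
        record.val_metrics.append(accs[cfg.stop_metric_task])
        record.stopping_epoch = epoch + 1

        should_stop = stopper.update(val_loss, epoch + 1)
        if stopper.since_best == 0:
            best_state = model.state_dict()
        record.best_epoch = stopper.best_epoch
        if (cfg.stop_at_val_accuracy is not None
                and accs[cfg.stop_metric_task] >= cfg.stop_at_val_accuracy):
            best_state, record.best_epoch = model.state_dict(), epoch + 1
            record.stop_reason = "target validation accuracy reached"
            break
        if should_stop:
            record.stop_reason = "early stopping (patience exhausted)"
            break
    else:
        record.stop_reason = ("max_epochs reached" if cfg.max_epochs
                              else "zero-epoch run")
    record.wall_time_s = time.time() - t0
    return best_state, record


@dataclass
class PredictionResult:
    labels: LabelVolume
    conditions: ConditionLabels | None
    probabilities: dict
    status: str


def predict(weights: dict, ct: CTVolume, net_cfg: NetworkConfig | None = None,
            patch_edge: int | None = None, crop_edge: int = 80
            ) -> PredictionResult:
    """Full inference: normalize, patch, segment, stitch, stage conditions."""
    model = build_model(net_cfg or NetworkConfig())
    model.load_state_dict(weights)
    vol = hu_normalize(ct)
    ds = model.cfg.downsample_factor
    if patch_edge is None:
        longest = max(vol.data.shape)
        patch_edge = min(160, int(np.ceil(longest / ds)) * ds)
    patches = extract_patches(vol, patch_edge=patch_edge)

    with no_grad():
        pred_patches = []
        for sub, off in patches.patches:
            out = model.forward(sub[None], seg=True, cls=False)
            pred_patches.append((out["md_probs"].data[0], off))
    patches.patches = pred_patches
    probs = stitch_patches(patches)
    seg = LabelVolume(probs.argmax(axis=0).astype(np.int16), vol.spacing_mm)

    result_probs = {"segmentation": probs.astype(np.float32)}
    if not ((seg.data == 1).any() and (seg.data == 2).any()):
        return PredictionResult(seg, None, result_probs, "no GH joint found")

    crop = extract_gh_crop(vol, seg, crop_edge=crop_edge)
    with no_grad():
        out = model.forward(crop.data[None], seg=False, cls=True)
    conditions = ConditionLabels(
        os_grade=int(out["os_probs"].data[0].argmax()),
        js_grade=int(out["js_probs"].data[0].argmax()),
        hsa=int(out["hsa_probs"].data[0, 0] >= 0.5),
    )
    result_probs.update(
        os=out["os_probs"].data[0],
        js=out["js_probs"].data[0],
        hsa=float(out["hsa_probs"].data[0, 0]),
    )
    return PredictionResult(seg, conditions, result_probs, "ok")
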