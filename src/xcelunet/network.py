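"""The xCEL-UNet: shared encoder, dual decoders, and clinical-staging heads.

Architecture summary (base 8 filters, three resolution levels):

* encoder: three blocks of two 3x3x3 conv + ReLU followed by 2x2x2 max
  pooling, doubling feature maps (8 -> 16 -> 32); a 64-channel bottleneck;
* two parallel decoders upsampling by 2x2x2 transpose convolutions that
  halve the feature maps per block: the contour decoder (CD) predicts
  3-class edge maps, the mask decoder (MD) predicts 3-class region maps
  (background, proximal humerus, scapula), both ending in a 1x1x1
  convolution with softmax.  Encoder skip connections feed both decoders;
  unidirectional skips concatenate each CD block output into the
  same-resolution MD block input;
* classification branch: global average pooling of the bottleneck maps,
  dense 64 -> dense 16 (ReLU), then three heads — 3-way softmax for
  osteophyte size (OS) and joint space (JS), a single sigmoid for
  humeroscapular alignment (HSA).

Stage-2 freeze setups (TL, FT-B, FT-E, FT-N) toggle the trainability of the
encoder / bottleneck / decoders parameter groups; the classification branch
is always trainable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .layers import (
    Adam,
    Conv3d,
    ConvTranspose3d,
    Dense,
    Module,
    Parameter,
    global_avg_pool,
    max_pool3d,
)

__all__ = [
    "NetworkConfig",
    "FreezeSetup",
    "FREEZE_SETUPS",
    "XCELUNet",
    "build_model",
    "apply_freeze",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    base_filters: int = 8
    n_blocks: int = 3
    seg_out_channels: int = 3
    cls_dense_units: tuple[int, int] = (64, 16)
    os_out: int = 3
    js_out: int = 3
    hsa_out: int = 1
    input_edge: int | None = None  # if set, validated at build time
    seed: int = 0

    @property
    def bottleneck_channels(self) -> int:
        return self.base_filters * 2**self.n_blocks

    @property
    def downsample_factor(self) -> int:
        return 2**self.n_blocks


@dataclass(frozen=True)
class FreezeSetup:
    """Which parameter groups stay trainable during stage-2 training."""

    name: str
    encoder: bool
    bottleneck: bool
    decoders: bool
    classification: bool = True


FREEZE_SETUPS: dict[str, FreezeSetup] = {
    "TL": FreezeSetup("TL", encoder=False, bottleneck=False, decoders=False),
    "FT-B": FreezeSetup("FT-B", encoder=False, bottleneck=True, decoders=False),
    "FT-E": FreezeSetup("FT-E", encoder=True, bottleneck=True, decoders=False),
    "FT-N": FreezeSetup("FT-N", encoder=True, bottleneck=True, decoders=True),
}


class _ConvBlock(Module):
    def __init__(self, cin, cout, rng, name):
        self.conv1 = Conv3d(cin, cout, 3, rng, f"{name}.c1")
        self.conv2 = Conv3d(cout, cout, 3, rng, f"{name}.c2")

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class _UpBlock(Module):
    def __init__(self, cin, cout, skip_channels, rng, name):
        self.up = ConvTranspose3d(cin, cout, rng, f"{name}.up")
        self.block = _ConvBlock(cout + skip_channels, cout, rng, name)

    def __call__(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        return self.block(concat([self.up(x)] + skips, axis=1))


class XCELUNet(Module):
    def __init__(self, cfg: NetworkConfig):
        if cfg.input_edge is not None and cfg.input_edge % cfg.downsample_factor:
            raise ValueError(
                f"input edge {cfg.input_edge} not divisible by "
                f"{cfg.downsample_factor}"
            )
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        chans = [f * 2**i for i in range(cfg.n_blocks)]          # 8, 16, 32
        bneck = cfg.bottleneck_channels                           # 64

        self.enc_blocks = []
        cin = cfg.in_channels
        for i, c in enumerate(chans):
            self.enc_blocks.append(_ConvBlock(cin, c, rng, f"enc{i + 1}"))
            cin = c
        self.bottleneck_block = _ConvBlock(chans[-1], bneck, rng, "bottleneck")

        self.cd_blocks, self.md_blocks = [], []
        cin = bneck
        for i, c in reversed(list(enumerate(chans))):             # deep -> shallow
            self.cd_blocks.append(_UpBlock(cin, c, c, rng, f"cd{i + 1}"))
            self.md_blocks.append(_UpBlock(cin, c, 2 * c, rng, f"md{i + 1}"))
            cin = c
        self.cd_head = Conv3d(chans[0], cfg.seg_out_channels, 1, rng, "cd_head")
        self.md_head = Conv3d(chans[0], cfg.seg_out_channels, 1, rng, "md_head")

        d1, d2 = cfg.cls_dense_units
        self.cls_dense1 = Dense(bneck, d1, rng, "cls.dense1")
        self.cls_dense2 = Dense(d1, d2, rng, "cls.dense2")
        self.os_head = Dense(d2, cfg.os_out, rng, "cls.os")
        self.js_head = Dense(d2, cfg.js_out, rng, "cls.js")
        self.hsa_head = Dense(d2, cfg.hsa_out, rng, "cls.hsa")

    # -- forward --------------------------------------------------------------

    def _encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        skips = []
        for block in self.enc_blocks:
            x = block(x)
            skips.append(x)
            x = max_pool3d(x)
        return self.bottleneck_block(x), skips

    def forward(self, x, seg: bool = True, cls: bool = True) -> dict:
        """Run the network; returns decoder probabilities, head outputs and
        the pre-pooling bottleneck activations (for GradCAM)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim == 3:
            x = Tensor(x.data[None, None])
        elif x.data.ndim == 4:
            x = Tensor(x.data[:, None])
        ds = self.cfg.downsample_factor
        if any(s % ds for s in x.data.shape[2:]):
            raise ValueError(
                f"spatial shape {x.data.shape[2:]} not divisible by {ds}"
            )
        bottleneck, skips = self._encode(x)
        out: dict = {"bottleneck": bottleneck}

        if seg:
            cd = bottleneck
            cd_feats = []
            for block, skip in zip(self.cd_blocks, reversed(skips)):
                cd = block(cd, [skip])
                cd_feats.append(cd)
            md = bottleneck
            for block, skip, cdf in zip(self.md_blocks, reversed(skips),
                                        cd_feats):
                md = block(md, [skip, cdf])
            out["cd_logits"] = self.cd_head(cd)
            out["md_logits"] = self.md_head(md)
            out["cd_probs"] = out["cd_logits"].softmax(axis=1)
            out["md_probs"] = out["md_logits"].softmax(axis=1)

        if cls:
            h = self.cls_dense2(self.cls_dense1(
                global_avg_pool(bottleneck)).relu()).relu()
            out["os_logits"] = self.os_head(h)
            out["js_logits"] = self.js_head(h)
            out["hsa_logits"] = self.hsa_head(h)
            out["os_probs"] = out["os_logits"].softmax(axis=1)
            out["js_probs"] = out["js_logits"].softmax(axis=1)
            out["hsa_probs"] = out["hsa_logits"].sigmoid()
        return out

    __call__ = forward

    # -- parameter bookkeeping -------------------------------------------------

    def parameter_groups(self) -> dict[str, list[Parameter]]:
        groups = {
            "encoder": [p for b in self.enc_blocks for p in b.parameters()],
            "bottleneck": self.bottleneck_block.parameters(),
            "decoders": (
                [p for b in self.cd_blocks for p in b.parameters()]
                + [p for b in self.md_blocks for p in b.parameters()]
                + self.cd_head.parameters() + self.md_head.parameters()
            ),
            "classification": (
                self.cls_dense1.parameters() + self.cls_dense2.parameters()
                + self.os_head.parameters() + self.js_head.parameters()
                + self.hsa_head.parameters()
            ),
        }
        return groups

    def parameters(self) -> list[Parameter]:
        return [p for ps in self.parameter_groups().values() for p in ps]

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name}")
            if state[p.name].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.data = state[p.name].astype(np.float32).copy()

    def group_hashes(self) -> dict[str, str]:
        """SHA-256 per parameter group, for freeze audits."""
        out = {}
        for name, params in self.parameter_groups().items():
            h = hashlib.sha256()
            for p in sorted(params, key=lambda p: p.name):
                h.update(p.name.encode())
                h.update(np.ascontiguousarray(p.data).tobytes())
            out[name] = h.hexdigest()
        return out


def build_model(cfg: NetworkConfig | None = None) -> XCELUNet:
    return XCELUNet(cfg or NetworkConfig())


def apply_freeze(model: XCELUNet, setup: FreezeSetup | str) -> XCELUNet:
    """Set ``requires_grad`` per parameter group to match a freeze setup."""
    if isinstance(setup, str):
        if setup not in FREEZE_SETUPS:
            raise ValueError(
                f"unknown setup {setup!r}; expected one of {list(FREEZE_SETUPS)}"
            )
        setup = FREEZE_SETUPS[setup]
    flags = {
        "encoder": setup.encoder,
        "bottleneck": setup.bottleneck,
        "decoders": setup.decoders,
        "classification": setup.classification,
    }
    for group, params in model.parameter_groups().items():
        for p in params:
            p.requires_grad = flags[group]
    return model


def save_weights(model: XCELUNet, path: str | Path) -> None:
    """Checkpoint as .npz plus a JSON architecture manifest alongside."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg = asdict(model.cfg)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "parameter_groups": {
            g: [p.name for p in ps]
            for g, ps in model.parameter_groups().items()
        },
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_weights(path: str | Path, cfg: NetworkConfig | None = None) -> XCELUNet:
    path = Path(path)
    manifest_path = path.with_suffix(".json")
    if cfg is None and manifest_path.exists():
        raw = json.loads(manifest_path.read_text())["config"]
        raw["cls_dense_units"] = tuple(raw["cls_dense_units"])
        cfg = NetworkConfig(**raw)
    model = XCELUNet(cfg or NetworkConfig())
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
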