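"""Volumetric neural-network layers and the Adam optimizer.

Convolutions are implemented as im2col + GEMM with hand-written backward
passes (input gradients via the flipped-kernel full correlation), which is
the fastest formulation available in pure numpy on a single CPU.  All layers
operate on ``(N, C, D, H, W)`` float32 tensors from :mod:`xcelunet.autodiff`.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "Dense",
    "max_pool3d",
    "global_avg_pool",
    "Adam",
]


class Parameter(Tensor):
    """A trainable tensor with a stable name for freeze audits."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


class Module:
    """Minimal container: owns parameters, knows how to list them."""

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out


def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col(vol: np.ndarray, k: int, pad: int,
            out: np.ndarray | None = None) -> np.ndarray:
    """(N, C, D, H, W) -> (N, C*k^3, D*H*W) via offset slicing.

    Each of the k^3 kernel offsets contributes one contiguous block copy of
    the padded volume, which is far cheaper than gathering strided windows.
    ``out`` allows reusing a previously allocated column buffer.
    """
    n, c, d, h, w_ = vol.shape
    if pad:
        vol = np.pad(vol, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    shape = (n, c, k**3, d * h * w_)
    cols = out if out is not None and out.shape == shape else np.empty(
        shape, dtype=np.float32
    )
    view = cols.reshape(n, c, k**3, d, h, w_)
    i = 0
    for a in range(k):
        for b in range(k):
            for e in range(k):
                view[:, :, i] = vol[:, :, a:a + d, b:b + h, e:e + w_]
                i += 1
    return cols.reshape(n, c * k**3, d * h * w_)


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution, stride 1, 'same' padding."""

    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 name: str = "conv"):
        self.cin, self.cout, self.k = cin, cout, kernel
        self.pad = kernel // 2
        fan_in = cin * kernel**3
        # weight layout (cout, cin*k^3): w[o, (c, dz, dy, dx)]
        self.w = Parameter(_he_init(rng, fan_in, (cout, fan_in)), f"{name}.w")
        self.b = Parameter(np.zeros(cout, dtype=np.float32), f"{name}.b")
        # column buffers reused across calls (same-shape inputs); a second
        # forward pass through this layer invalidates the pending backward
        # of the previous one, which the training loops never rely on
        self._bufs: dict = {}

    def __call__(self, x: Tensor) -> Tensor:
        n, _, d, h, w_ = x.data.shape
        cols = _im2col(x.data, self.k, self.pad,
                       out=self._bufs.get(("f",) + x.data.shape))
        self._bufs[("f",) + x.data.shape] = cols.reshape(
            n, self.cin, self.k**3, -1
        )
        out = np.matmul(self.w.data, cols)              # (N, cout, DHW)
        out += self.b.data[None, :, None]
        out_data = out.reshape(n, self.cout, d, h, w_)
        wp, bp, k, pad, cin, cout = (self.w, self.b, self.k, self.pad,
                                     self.cin, self.cout)

        def backward(g):
            rows = g.reshape(n, cout, -1)
            if bp.requires_grad:
                bp._accum(rows.sum(axis=(0, 2)))
            if wp.requires_grad:
                wp._accum(np.matmul(rows, cols.transpose(0, 2, 1)).sum(axis=0))
            if x.requires_grad:
                # dL/dx = full correlation of g with the flipped kernel
                wr = wp.data.reshape(cout, cin, k, k, k)
                wt = wr[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                wt = np.ascontiguousarray(wt.reshape(cin, cout * k**3))
                gc = np.ascontiguousarray(rows.reshape(g.shape))
                gcols = _im2col(gc, k, k - 1 - pad,
                                out=self._bufs.get(("b",) + gc.shape))
                self._bufs[("b",) + gc.shape] = gcols.reshape(
                    n, cout, k**3, -1
                )
                dx = np.matmul(wt, gcols).reshape(n, cin, d, h, w_)
                x._accum(dx)

        return Tensor._node(out_data, (x, self.w, self.b), backward)


class ConvTranspose3d(Module):
    """2x2x2 transpose convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 name: str = "upconv"):
        self.cin, self.cout = cin, cout
        self.w = Parameter(_he_init(rng, cin, (cin, cout, 2, 2, 2)), f"{name}.w")
        self.b = Parameter(np.zeros(cout, dtype=np.float32), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        n, _, d, h, w_ = x.data.shape
        t = np.tensordot(x.data, self.w.data, axes=([1], [0]))
        # t: (N, D, H, W, cout, 2, 2, 2) -> interleave into (N, cout, 2D, 2H, 2W)
        out_data = t.transpose(0, 4, 1, 5, 2, 6, 3, 7).reshape(
            n, self.cout, 2 * d, 2 * h, 2 * w_
        )
        out_data = out_data + self.b.data[None, :, None, None, None]
        wp, bp, cout = self.w, self.b, self.cout

        def backward(g):
            gt = g.reshape(n, cout, d, 2, h, 2, w_, 2).transpose(
                0, 2, 4, 6, 1, 3, 5, 7
            )
            if bp.requires_grad:
                bp._accum(g.sum(axis=(0, 2, 3, 4)))
            if wp.requires_grad:
                wp._accum(
                    np.tensordot(x.data, gt, axes=([0, 2, 3, 4], [0, 1, 2, 3]))
                )
            if x.requires_grad:
                dx = np.tensordot(gt, wp.data, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
                x._accum(np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3)))

        return Tensor._node(
            np.ascontiguousarray(out_data), (x, self.w, self.b), backward
        )


class Dense(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator,
                 name: str = "dense"):
        self.w = Parameter(_he_init(rng, fin, (fin, fout)), f"{name}.w")
        self.b = Parameter(np.zeros(fout, dtype=np.float32), f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


def max_pool3d(x: Tensor) -> Tensor:
    """2x2x2 max pooling with stride 2; even spatial extents required."""
    n, c, d, h, w_ = x.data.shape
    if d % 2 or h % 2 or w_ % 2:
        raise ValueError(f"max_pool3d needs even spatial extents, got {(d, h, w_)}")
    r = x.data.reshape(n, c, d // 2, 2, h // 2, 2, w_ // 2, 2)
    blocks = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
        n, c, d // 2, h // 2, w_ // 2, 8
    )
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        gx = gb.reshape(n, c, d // 2, h // 2, w_ // 2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7
        )
        x._accum(np.ascontiguousarray(gx.reshape(n, c, d, h, w_)))

    return Tensor._node(np.ascontiguousarray(out_data), (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """Mean over the spatial axes: (N, C, D, H, W) -> (N, C)."""
    return x.mean(axis=(2, 3, 4))


class Adam:
    """Adaptive moment estimation over the trainable parameters it is given."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
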