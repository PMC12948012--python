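"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sized for the operations this package's network
actually needs: convolutions (via gather/matmul with hand-written adjoints),
batch normalization, leaky ReLU, channel concatenation, nearest-neighbour
upsampling, replicate padding, bilinear warping, local correlation (cost
volume) and mean-absolute-error losses.  Tensors are NCHW float32.

The engine is deliberately eager and minimal: each op returns a new
:class:`Tensor` holding a closure that scatters the upstream gradient to
its parents; ``Tensor.backward()`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- basic ops ---------------------------------------------------------

    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor(out_data, parents=(a, b), backward=backward)

    def scale(self, c: float) -> "Tensor":
        a = self

        def backward(g):
            if a.requires_grad:
                a._accumulate(g * c)

        return Tensor(self.data * c, parents=(a,), backward=backward)


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, slope * x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.where(mask, g, slope * g))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]

    def backward(g):
        start = 0
        for t, c in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[:, start : start + c])
            start += c

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def _gather_cols(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """im2col by k^2 strided slices -> [B, Hout, Wout, C*kh*kw] (contiguous)."""
    b, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = np.empty((b, ho, wo, c, kh, kw), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride]
            cols[:, :, :, :, i, j] = patch.transpose(0, 2, 3, 1)
    return cols.reshape(b, ho, wo, c * kh * kw)


def _scatter_cols(
    dcols: np.ndarray, xshape, kh: int, kw: int, stride: int
) -> np.ndarray:
    """Adjoint of :func:`_gather_cols`."""
    b, c, hp, wp = xshape
    ho, wo = dcols.shape[1], dcols.shape[2]
    d = dcols.reshape(b, ho, wo, c, kh, kw)
    dx = np.zeros(xshape, dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                d[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            )
    return dx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2D convolution (cross-correlation), zero padding, NCHW.

    ``weight`` has shape [Cout, Cin, kh, kw], ``bias`` [Cout].
    """
    kh, kw = weight.data.shape[2:]
    if pad > 0:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    cols = _gather_cols(xp, kh, kw, stride)  # [B,Ho,Wo,Cin*k*k]
    w2 = weight.data.reshape(weight.data.shape[0], -1)  # [Cout, Cin*k*k]
    out = cols @ w2.T + bias.data  # [B,Ho,Wo,Cout]
    out_data = out.transpose(0, 3, 1, 2)

    def backward(g):
        gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # [B,Ho,Wo,Cout]
        if weight.requires_grad:
            co = gt.shape[-1]
            dw = gt.reshape(-1, co).T @ cols.reshape(-1, cols.shape[-1])
            weight._accumulate(dw.reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accumulate(gt.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            dcols = gt @ w2  # [B,Ho,Wo,Cin*k*k]
            dxp = _scatter_cols(dcols, xp.shape, kh, kw, stride)
            if pad > 0:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            x._accumulate(dxp)

    return Tensor(out_data, parents=(x, weight, bias), backward=backward)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * invstd[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
            if training:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = gi * (g - sum_g / n - xhat * sum_gx / n)
            else:
                dx = gi * g
            x._accumulate(dx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=backward)


def nearest_upsample2(x: Tensor) -> Tensor:
    out_data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        if x.requires_grad:
            b, c, h2, w2 = g.shape
            x._accumulate(g.reshape(b, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor(out_data, parents=(x,), backward=backward)


def pad_replicate(x: Tensor, p: int = 1) -> Tensor:
    out_data = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), mode="edge")

    def backward(g):
        if x.requires_grad:
            gi = g.copy()
            # fold the replicated borders back onto the edge rows/cols
            gi[:, :, p, :] += gi[:, :, :p, :].sum(axis=2)
            gi[:, :, -p - 1, :] += gi[:, :, -p:, :].sum(axis=2)
            gi = gi[:, :, p:-p, :]
            gi[:, :, :, p] += gi[:, :, :, :p].sum(axis=3)
            gi[:, :, :, -p - 1] += gi[:, :, :, -p:].sum(axis=3)
            x._accumulate(gi[:, :, :, p:-p])

    return Tensor(out_data, parents=(x,), backward=backward)


def warp_bilinear(feat: Tensor, flow: np.ndarray) -> Tensor:
    """Sample ``feat`` at (x + dx, y + dy); out-of-frame samples are zero.

    ``flow`` is a plain [B, 2, H, W] array (channel 0 = dx, 1 = dy) and is
    treated as constant: gradients propagate to the features only, matching
    the per-level direct flow supervision used in training.
    """
    b, c, h, w = feat.data.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    sx = xx[None] + flow[:, 0]
    sy = yy[None] + flow[:, 1]
    x0 = np.floor(sx).astype(np.int64)
    y0 = np.floor(sy).astype(np.int64)
    fx = sx - x0
    fy = sy - y0
    out_data = np.zeros_like(feat.data)
    corners = []
    for dyi, dxi, wgt in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yi = y0 + dyi
        xi = x0 + dxi
        inside = (yi >= 0) & (yi < h) & (xi >= 0) & (xi < w)
        yc = np.clip(yi, 0, h - 1)
        xc = np.clip(xi, 0, w - 1)
        wgt_in = (wgt * inside).astype(np.float32)  # [B,H,W]
        bidx = np.arange(b)[:, None, None]
        out_data += feat.data[bidx, :, yc, xc].transpose(0, 3, 1, 2) * wgt_in[:, None]
        corners.append((yc, xc, wgt_in))

    def backward(g):
        if not feat.requires_grad:
            return
        dfeat = np.zeros_like(feat.data)
        bidx = np.arange(b)[:, None, None]
        flat = dfeat.reshape(b, c, h * w)
        for yc, xc, wgt_in in corners:
            contrib = g * wgt_in[:, None]  # [B,C,H,W]
            lin = (yc * w + xc).reshape(b, -1)  # [B, H*W]
            for bi in range(b):
                np.add.at(
                    flat[bi],
                    (slice(None), lin[bi]),
                    contrib[bi].reshape(c, -1),
                )
        feat._accumulate(dfeat)

    return Tensor(out_data, parents=(feat,), backward=backward)


def cost_volume(ref_w: Tensor, sam: Tensor, n_w: int = 3) -> Tensor:
    """Local correlation: channel-mean of sam(x) * ref_w(x + offset).

    Output has (2 n_w + 1)^2 channels ordered row-major over (dy, dx); zero
    fill where the offset pixel leaves the frame.
    """
    b, c, h, w = sam.data.shape
    side = 2 * n_w + 1
    out_data = np.zeros((b, side * side, h, w), dtype=np.float32)
    slices = []
    for k, (dy, dx) in enumerate(
        (dy, dx) for dy in range(-n_w, n_w + 1) for dx in range(-n_w, n_w + 1)
    ):
        ys = slice(max(0, -dy), min(h, h - dy))
        xs = slice(max(0, -dx), min(w, w - dx))
        yr = slice(max(0, dy), min(h, h + dy))
        xr = slice(max(0, dx), min(w, w + dx))
        out_data[:, k, ys, xs] = (
            sam.data[:, :, ys, xs] * ref_w.data[:, :, yr, xr]
        ).mean(axis=1)
        slices.append((k, ys, xs, yr, xr))

    def backward(g):
        inv_c = 1.0 / c
        if ref_w.requires_grad:
            dref = np.zeros_like(ref_w.data)
            for k, ys, xs, yr, xr in slices:
                dref[:, :, yr, xr] += g[:, k : k + 1, ys, xs] * sam.data[:, :, ys, xs] * inv_c
            ref_w._accumulate(dref)
        if sam.requires_grad:
            dsam = np.zeros_like(sam.data)
            for k, ys, xs, yr, xr in slices:
                dsam[:, :, ys, xs] += g[:, k : k + 1, ys, xs] * ref_w.data[:, :, yr, xr] * inv_c
            sam._accumulate(dsam)

    return Tensor(out_data, parents=(ref_w, sam), backward=backward)


def channel_znorm(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Zero-mean, unit-norm normalization along the channel axis per pixel.

    Turns the subsequent cost-volume product into an exact local
    zero-normalized correlation.
    """
    m = x.data.mean(axis=1, keepdims=True)
    centered = x.data - m
    norm = np.sqrt((centered**2).sum(axis=1, keepdims=True)) + eps
    out_data = centered / norm
    c = x.data.shape[1]

    def backward(g):
        if not x.requires_grad:
            return
        # d/dx of u/||u|| with u = x - mean(x):  P_u (g - mean_c(g)) / ||u||
        g_c = g - g.mean(axis=1, keepdims=True)
        proj = (g_c * out_data).sum(axis=1, keepdims=True)
        x._accumulate((g_c - out_data * proj) / norm)

    return Tensor(out_data, parents=(x,), backward=backward)


def mean_abs_error(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.data - target
    out_data = np.array(np.abs(diff).mean(), dtype=np.float32)
    n = diff.size

    def backward(g):
        if pred.requires_grad:
            pred._accumulate(np.sign(diff) * (float(np.asarray(g).ravel()[0]) / n))

    return Tensor(out_data, parents=(pred,), backward=backward)
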