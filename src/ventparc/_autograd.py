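"""Minimal reverse-mode differentiation engine for volumetric networks.

The package trains its segmentation network with plain numpy: each op builds
a node in a tape holding the arrays needed for its analytic backward pass.
Feature maps are single-sample ``(C, D, H, W)`` float32 arrays (the training
protocol uses batch size one; larger batches are handled upstream by gradient
accumulation).  Convolutions use im2col + BLAS matmul with "same" padding, so
a stride-s convolution maps spatial size n to ceil(n/s).
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """Array node in the computation tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "per_label_terms")

    def __init__(self, data, parents=(), backward=None):
        self.data = data
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: volumes can produce deep tapes
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float32))


def _same_pad(n: int, k: int, s: int) -> tuple[int, int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    lo = total // 2
    return out, lo, total - lo


def conv3d(x: Tensor, w: Tensor, b: Tensor, k: int, stride: int = 1) -> Tensor:
    """3D convolution, zero "same" padding; ``w`` is ``(Cin*k^3, Cout)``."""
    cin = x.data.shape[0]
    cout = w.data.shape[1]
    spatial = x.data.shape[1:]
    outs, lows, highs = zip(*(_same_pad(n, k, stride) for n in spatial))
    xp = np.pad(x.data, ((0, 0), *zip(lows, highs)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    win = win[:, ::stride, ::stride, ::stride]
    col = np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        -1, cin * k ** 3)
    y = (col @ w.data + b.data).reshape(*outs, cout).transpose(3, 0, 1, 2)
    y = np.ascontiguousarray(y)

    def backward(gy):
        g = np.ascontiguousarray(gy.transpose(1, 2, 3, 0)).reshape(-1, cout)
        gw = col.T @ g
        gb = g.sum(axis=0)
        if stride == 1:
            # Input grad = full correlation of gy with flipped kernels,
            # done with the same im2col + matmul machinery.
            wk = w.data.reshape(cin, k, k, k, cout)
            wk = wk[:, ::-1, ::-1, ::-1, :]
            wt = np.ascontiguousarray(
                wk.transpose(4, 1, 2, 3, 0)).reshape(cout * k ** 3, cin)
            gp = np.pad(gy, ((0, 0),
                             (k - 1 - lows[0],) * 2,
                             (k - 1 - lows[1],) * 2,
                             (k - 1 - lows[2],) * 2))
            gwin = np.lib.stride_tricks.sliding_window_view(
                gp, (k, k, k), axis=(1, 2, 3))
            gcolT = np.ascontiguousarray(
                gwin.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(-1, cout * k ** 3)
            gx = (gcolT @ wt).reshape(*spatial, cin).transpose(3, 0, 1, 2)
            return np.ascontiguousarray(gx), gw, gb
        gcol = (g @ w.data.T).reshape(*outs, cin, k, k, k)
        gcol = np.ascontiguousarray(gcol.transpose(4, 5, 6, 3, 0, 1, 2))
        gxp = np.zeros(xp.shape, dtype=np.float32)
        for ki in range(k):
            for kj in range(k):
                for kk in range(k):
                    gxp[:,
                        ki:ki + stride * outs[0]:stride,
                        kj:kj + stride * outs[1]:stride,
                        kk:kk + stride * outs[2]:stride] += gcol[ki, kj, kk]
        gx = gxp[:,
                 lows[0]:lows[0] + spatial[0],
                 lows[1]:lows[1] + spatial[1],
                 lows[2]:lows[2] + spatial[2]]
        return np.ascontiguousarray(gx), gw, gb

    return Tensor(y, (x, w, b), backward)


def leaky_relu(x: Tensor, slope: float) -> Tensor:
    neg = x.data < 0
    y = np.where(neg, slope * x.data, x.data)

    def backward(gy):
        return (np.where(neg, slope * gy, gy),)

    return Tensor(y.astype(np.float32), (x,), backward)


def _channel_norm(x: Tensor, mean, var, eps: float) -> Tensor:
    """Normalize each channel with the given per-channel statistics."""
    inv = 1.0 / np.sqrt(var + eps)
    mean = mean.astype(np.float32).reshape(-1, 1, 1, 1)
    inv = inv.astype(np.float32).reshape(-1, 1, 1, 1)
    y = (x.data - mean) * inv

    def backward(gy):
        # d/dx of (x - mean(x)) / sqrt(var(x) + eps), statistics over space
        gmean = gy.mean(axis=(1, 2, 3), keepdims=True)
        gproj = (gy * y).mean(axis=(1, 2, 3), keepdims=True)
        return (inv * (gy - gmean - y * gproj),)

    return Tensor(y.astype(np.float32), (x,), backward)


def instance_normalize(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Zero-mean unit-variance normalization per channel over space.

    Makes the features invariant to a positive affine rescaling of the
    input intensities, up to the ``eps`` variance floor.
    """
    if x.data[0].size < 2:
        raise ValueError("instance normalization needs more than one voxel per channel")
    x64 = x.data.astype(np.float64)
    mean = x64.mean(axis=(1, 2, 3))
    var = x64.var(axis=(1, 2, 3))
    return _channel_norm(x, mean, var, eps)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout (training mode only; inference skips the op)."""
    if rate <= 0:
        return x
    keep = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    y = x.data * keep

    def backward(gy):
        return (gy * keep,)

    return Tensor(y, (x,), backward)


def upsample_repeat(x: Tensor, factor: int = 2) -> Tensor:
    """Upsample by repeating each voxel ``factor`` times along each axis."""
    y = x.data
    for axis in (1, 2, 3):
        y = np.repeat(y, factor, axis=axis)

    def backward(gy):
        c, d, h, w = x.data.shape
        g = gy.reshape(c, d, factor, h, factor, w, factor).sum(axis=(2, 4, 6))
        return (g,)

    return Tensor(np.ascontiguousarray(y), (x,), backward)


def add(x: Tensor, y: Tensor) -> Tensor:
    def backward(gy):
        return gy, gy

    return Tensor(x.data + y.data, (x, y), backward)


def concat_channels(x: Tensor, y: Tensor) -> Tensor:
    cx = x.data.shape[0]

    def backward(gy):
        return gy[:cx], gy[cx:]

    return Tensor(np.concatenate([x.data, y.data], axis=0), (x, y), backward)


def softmax_channels(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=0, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=0, keepdims=True)

    def backward(gy):
        dot = (gy * p).sum(axis=0, keepdims=True)
        return (p * (gy - dot),)

    return Tensor(p.astype(np.float32), (x,), backward)


def mean_dice_loss(p: Tensor, t_onehot: np.ndarray, epsilon: float = 1e-3) -> Tensor:
    """One minus the mean soft Dice coefficient over all L labels.

    ``p`` holds per-voxel label probabilities ``(L, D, H, W)``; ``t_onehot``
    is the one-hot truth.  Each label's term is
    ``(eps + 2 sum_i P_il T_il) / (eps + sum_i P_il + sum_i T_il)``;
    ``epsilon`` keeps empty labels well-defined (their term tends to 1).
    """
    t = t_onehot.astype(np.float64)
    pd = p.data.astype(np.float64)
    L = pd.shape[0]
    inter = (pd * t).sum(axis=(1, 2, 3))
    num = epsilon + 2.0 * inter
    den = epsilon + pd.sum(axis=(1, 2, 3)) + t.sum(axis=(1, 2, 3))
    terms = num / den
    loss = 1.0 - terms.mean()

    def backward(gy):
        # d loss / d P_il = -(1/L) (2 T_il den_l - num_l) / den_l^2
        coeff = -(1.0 / L)
        g = coeff * (2.0 * t * den.reshape(-1, 1, 1, 1) - num.reshape(-1, 1, 1, 1))
        g = g / (den ** 2).reshape(-1, 1, 1, 1)
        return ((float(gy) * g).astype(np.float32),)

    out = Tensor(np.float64(loss), (p,), backward)
    out.per_label_terms = terms  # type: ignore[attr-defined]
    return out


class Adam:
    """Adam optimizer over a list of parameter tensors."""

    def __init__(self, params, step_size: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        if step_size <= 0 or beta1 <= 0 or beta2 <= 0 or eps <= 0:
            raise ValueError("optimizer scalars must be positive")
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = step_size, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
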