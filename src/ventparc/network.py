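"""Residual 3D U-Net for ventricle parcellation (VParNet-style architecture).

The network is an encoder-decoder CNN over single-channel 3D volumes:

* a contracting path of encoder blocks, the first at full resolution and each
  subsequent one halving the grid with a stride-2 3x3x3 convolution, with a
  short residual skip inside every block;
* an expanding path of decoder blocks that repeat-upsample coarse features
  and concatenate the matching encoder output (long skip connections);
* a classification head that projects every decoder output to L=5 channels
  with 1x1x1 convolutions and fuses the levels coarse-to-fine by
  repeat-upsampling and element-wise summation, ending in a channel softmax.

"Activation layers" throughout means instance normalization followed by a
leaky ReLU; instance normalization makes the output invariant to positive
affine rescalings of the input intensities, so no intensity normalization of
the inputs is needed.  Ablation switches reproduce the standard variants:
plain (non-residual) encoders, batch instead of instance normalization, and
a single-level (no-fusion) head.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor
from .volumes import IntensityVolume, ProbabilityVolume

__all__ = [
    "NetworkSpec", "VParNet", "build_vparnet", "instance_normalize",
    "upsample_repeat", "save_checkpoint", "load_checkpoint",
]


@dataclass
class NetworkSpec:
    """Hyperparameters fully determining the computation graph.

    ``channels`` gives the per-level output channel count (monotone
    non-decreasing, one entry per resolution level).  ``seed`` controls
    weight initialization.
    """

    n_labels: int = 5
    depth: int = 3
    channels: tuple[int, ...] = (8, 16, 32)
    leaky_slope: float = 0.1
    dropout_rate: float = 0.2
    norm_kind: str = "instance"      # "instance" | "batch"
    encoder_kind: str = "residual"   # "residual" | "plain"
    fuse_multilevel: bool = True
    upsample_kind: str = "repeat"
    decoder_mid_divisor: int = 2     # 1x1x1 conv channel reduction in decoders
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(int(c) for c in self.channels)
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if len(self.channels) != self.depth:
            raise ValueError("channels must have one entry per level")
        if any(a > b for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError("channels must be monotone non-decreasing")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.leaky_slope < 0:
            raise ValueError("leaky_slope must be >= 0")
        if self.norm_kind not in ("instance", "batch"):
            raise ValueError(f"unknown norm_kind {self.norm_kind!r}")
        if self.encoder_kind not in ("residual", "plain"):
            raise ValueError(f"unknown encoder_kind {self.encoder_kind!r}")
        if self.upsample_kind != "repeat":
            raise ValueError("only repeat upsampling is supported")


def instance_normalize(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Standalone per-channel spatial standardization of a feature map."""
    t = ag.instance_normalize(Tensor(np.asarray(x, dtype=np.float32)), eps)
    return t.data


def upsample_repeat(x: np.ndarray, factor: int = 2) -> np.ndarray:
    """Standalone repeat-upsampling of a (C, D, H, W) feature map."""
    return ag.upsample_repeat(Tensor(np.asarray(x, dtype=np.float32)), factor).data


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class _Conv:
    """3D convolution layer with variance-scaling (leaky-ReLU-aware) init."""

    def __init__(self, cin: int, cout: int, k: int, stride: int,
                 slope: float, rng: np.random.Generator):
        fan_in = cin * k ** 3
        std = np.sqrt(2.0 / ((1.0 + slope ** 2) * fan_in))
        self.w = ag.parameter(rng.normal(0.0, std, (fan_in, cout)))
        self.b = ag.parameter(np.zeros(cout))
        self.k, self.stride = k, stride

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.w, self.b, self.k, self.stride)

    def parameters(self):
        return [self.w, self.b]


class _Norm:
    """Instance or batch normalization (no affine parameters).

    Batch mode keeps running statistics: training normalizes with the current
    sample's statistics (batch size one) and updates the running estimates;
    inference normalizes with the running estimates, which is what breaks
    invariance to input intensity rescaling.
    """

    def __init__(self, channels: int, kind: str, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.kind, self.momentum, self.eps = kind, momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if self.kind == "instance":
            return ag.instance_normalize(x, self.eps)
        if training:
            x64 = x.data.astype(np.float64)
            mean = x64.mean(axis=(1, 2, 3))
            var = x64.var(axis=(1, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return ag._channel_norm(x, mean, var, self.eps)
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32)
        mean = self.running_mean.astype(np.float32)
        y = (x.data - mean.reshape(-1, 1, 1, 1)) * inv.reshape(-1, 1, 1, 1)

        def backward(gy):
            return (gy * inv.reshape(-1, 1, 1, 1),)

        return Tensor(y, (x,), backward)

    def parameters(self):
        return []


class _Activation:
    """The "activation layers": normalization then leaky ReLU."""

    def __init__(self, channels: int, spec: NetworkSpec):
        self.norm = _Norm(channels, spec.norm_kind)
        self.slope = spec.leaky_slope

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        return ag.leaky_relu(self.norm(x, training), self.slope)

    def parameters(self):
        return []


class EncoderBlock:
    """Strided conv -> activations -> conv -> activations, plus a short
    residual skip from the first activation output over the second stage."""

    def __init__(self, cin: int, cout: int, spec: NetworkSpec,
                 rng: np.random.Generator, stride: int = 2):
        self.conv1 = _Conv(cin, cout, 3, stride, spec.leaky_slope, rng)
        self.act1 = _Activation(cout, spec)
        self.conv2 = _Conv(cout, cout, 3, 1, spec.leaky_slope, rng)
        self.act2 = _Activation(cout, spec)
        self.residual = spec.encoder_kind == "residual"

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        h = self.act1(self.conv1(x), training)
        y = self.act2(self.conv2(h), training)
        return ag.add(h, y) if self.residual else y

    def parameters(self):
        return self.conv1.parameters() + self.conv2.parameters()


class DecoderBlock:
    """1x1x1 conv, activations, repeat-upsampling, 3x3x3 conv, activations,
    concatenation with the matching encoder output, dropout, 3x3x3 conv,
    activations — in exactly that order."""

    def __init__(self, cin: int, c_skip: int, cout: int, spec: NetworkSpec,
                 rng: np.random.Generator):
        mid = max(cin // spec.decoder_mid_divisor, 1)
        self.conv_in = _Conv(cin, mid, 1, 1, spec.leaky_slope, rng)
        self.act_in = _Activation(mid, spec)
        self.conv_up = _Conv(mid, mid, 3, 1, spec.leaky_slope, rng)
        self.act_up = _Activation(mid, spec)
        self.conv_out = _Conv(mid + c_skip, cout, 3, 1, spec.leaky_slope, rng)
        self.act_out = _Activation(cout, spec)
        self.dropout_rate = spec.dropout_rate

    def __call__(self, x: Tensor, skip: Tensor, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        expected = tuple(2 * s for s in x.data.shape[1:])
        if skip.data.shape[1:] != expected:
            raise ValueError(
                f"skip spatial shape {skip.data.shape[1:]} does not match "
                f"2x the coarse input {x.data.shape[1:]}")
        h = self.act_in(self.conv_in(x), training)
        h = ag.upsample_repeat(h, 2)
        h = self.act_up(self.conv_up(h), training)
        h = ag.concat_channels(h, skip)
        if training and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode dropout needs an rng")
            h = ag.dropout(h, self.dropout_rate, rng)
        return self.act_out(self.conv_out(h), training)

    def parameters(self):
        return (self.conv_in.parameters() + self.conv_up.parameters()
                + self.conv_out.parameters())


# ---------------------------------------------------------------------------
# The full network
# ---------------------------------------------------------------------------

class VParNet:
    """Callable network: 3D intensity volume -> per-voxel label probabilities."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        root = np.random.default_rng(np.random.SeedSequence(spec.seed))
        self.encoders: list[EncoderBlock] = []
        cin = 1
        for level in range(spec.depth):
            self.encoders.append(EncoderBlock(
                cin, spec.channels[level], spec, root,
                stride=1 if level == 0 else 2))
            cin = spec.channels[level]
        self.decoders: list[DecoderBlock] = []  # ordered coarse -> fine
        for level in range(spec.depth - 2, -1, -1):
            self.decoders.append(DecoderBlock(
                cin, spec.channels[level], spec.channels[level], spec, root))
            cin = spec.channels[level]
        # 1x1x1 projections to n_labels, one per fused level (coarse -> fine)
        if spec.fuse_multilevel:
            proj_channels = [spec.channels[level]
                             for level in range(spec.depth - 2, -1, -1)]
        else:
            proj_channels = [spec.channels[0]]
        self.projections = [
            _Conv(c, spec.n_labels, 1, 1, spec.leaky_slope, root)
            for c in proj_channels]
        # Prior-aware classifier init: start the softmax near the background-
        # dominated label prior instead of uniform, which removes the early
        # foreground-everywhere transient of the mean-Dice loss.
        for proj in self.projections:
            proj.b.data[1:] = -4.0 / len(self.projections)
        self._dropout_rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 0xD0]))

    # -- plumbing ----------------------------------------------------------
    def parameters(self):
        params = []
        for block in (*self.encoders, *self.decoders):
            params += block.parameters()
        for proj in self.projections:
            params += proj.parameters()
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def reset_dropout_rng(self, seed: int) -> None:
        """Reset the dropout stream (training reproducibility)."""
        self._dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD0]))

    def check_input_shape(self, shape) -> None:
        div = 2 ** (self.spec.depth - 1)
        for axis, n in enumerate(shape):
            if n % div:
                raise ValueError(
                    f"input axis {axis} has size {n}, not divisible by "
                    f"2^(depth-1) = {div}; pad or crop that axis")

    # -- forward -----------------------------------------------------------
    def forward_tensor(self, x: np.ndarray, training: bool = False) -> Tensor:
        """Forward pass on a (D, H, W) or (1, D, H, W) array; returns the
        softmax probability tensor (n_labels, D, H, W)."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        self.check_input_shape(x.shape[1:])
        t = Tensor(x)
        if self.spec.norm_kind == "instance":
            # Standardize the input channel itself: together with zero
            # padding this makes invariance to x -> a*x + b (a > 0) exact
            # rather than approximate at the volume borders.
            t = ag.instance_normalize(t, eps=1e-8)
        skips = []
        for enc in self.encoders:
            t = enc(t, training)
            skips.append(t)
        decoder_outputs = []  # coarse -> fine
        t = skips[-1]
        for dec, level in zip(self.decoders, range(self.spec.depth - 2, -1, -1)):
            t = dec(t, skips[level], training, self._dropout_rng)
            decoder_outputs.append(t)
        if self.spec.fuse_multilevel:
            fused = self.projections[0](decoder_outputs[0])
            for proj, d in zip(self.projections[1:], decoder_outputs[1:]):
                fused = ag.add(ag.upsample_repeat(fused, 2), proj(d))
        else:
            fused = self.projections[0](decoder_outputs[-1])
        return ag.softmax_channels(fused)

    def __call__(self, volume, training: bool = False) -> ProbabilityVolume:
        if isinstance(volume, IntensityVolume):
            p = self.forward_tensor(volume.data, training)
            return ProbabilityVolume(p.data, volume.affine)
        p = self.forward_tensor(np.asarray(volume), training)
        return ProbabilityVolume(p.data)

    # -- introspection -----------------------------------------------------
    def summary(self, input_shape=(32, 32, 32)) -> dict:
        """Layer shape report: per-level feature shapes and parameter count."""
        self.check_input_shape(input_shape)
        levels = []
        shape = tuple(input_shape)
        for level in range(self.spec.depth):
            if level > 0:
                shape = tuple(-(-n // 2) for n in shape)
            levels.append({
                "level": level,
                "channels": self.spec.channels[level],
                "spatial_shape": shape,
            })
        decoder_levels = []
        for level in range(self.spec.depth - 2, -1, -1):
            decoder_levels.append({
                "level": level,
                "channels": self.spec.channels[level],
                "spatial_shape": levels[level]["spatial_shape"],
            })
        return {
            "input_shape": tuple(input_shape),
            "encoder_levels": levels,
            "decoder_levels": decoder_levels,
            "output_shape": (self.spec.n_labels, *input_shape),
            "n_parameters": self.n_parameters(),
        }

    # -- state -------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {f"param_{i}": p.data for i, p in enumerate(self.parameters())}
        norms = self._norm_layers()
        for i, norm in enumerate(norms):
            state[f"norm_{i}_mean"] = norm.running_mean
            state[f"norm_{i}_var"] = norm.running_var
        return state

    def load_state_arrays(self, state) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float32).reshape(p.data.shape)
        for i, norm in enumerate(self._norm_layers()):
            if f"norm_{i}_mean" in state:
                norm.running_mean = np.asarray(state[f"norm_{i}_mean"], dtype=float)
                norm.running_var = np.asarray(state[f"norm_{i}_var"], dtype=float)

    def _norm_layers(self):
        norms = []
        for enc in self.encoders:
            norms += [enc.act1.norm, enc.act2.norm]
        for dec in self.decoders:
            norms += [dec.act_in.norm, dec.act_up.norm, dec.act_out.norm]
        return norms


def build_vparnet(spec: NetworkSpec) -> VParNet:
    """Construct the network from its spec."""
    return VParNet(spec)


# ---------------------------------------------------------------------------
# Checkpoints (weights + embedded spec, self-describing)
# ---------------------------------------------------------------------------

def save_checkpoint(model: VParNet, path, extra: dict | None = None) -> None:
    from pathlib import Path
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    buf = {"__spec__": np.frombuffer(
        json.dumps(asdict(model.spec)).encode(), dtype=np.uint8)}
    if extra:
        buf["__extra__"] = np.frombuffer(json.dumps(extra).encode(), dtype=np.uint8)
    buf.update(model.state_arrays())
    np.savez(path, **buf)


def load_checkpoint(path) -> VParNet:
    with np.load(path) as data:
        spec_dict = json.loads(bytes(data["__spec__"]).decode())
        spec_dict["channels"] = tuple(spec_dict["channels"])
        model = VParNet(NetworkSpec(**spec_dict))
        model.load_state_arrays(data)
    return model
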