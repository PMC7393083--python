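"""Deep Residual U-Net builder.

The network is an encoder / bridge / decoder stack of pre-activation
residual units (two BN -> ReLU -> 3x3-conv sub-blocks plus an identity
shortcut; a 1x1 stride-matched projection carries the shortcut across
shape changes). Downsampling is a stride of 2 on the first convolution
of a unit; the decoder mirrors the encoder with 2x nearest-neighbour
upsampling and concatenation of the matching encoder feature map, and a
final 1x1 convolution + sigmoid emits the per-pixel foreground
probability.

Two full-size specifications ship: a 9-level network at 128 x 128 for
axial patches (bridge 8 x 8 x 1024, 19 convolution layers) and a 7-level
network at 128 x 64 for coronal/sagittal patches (bridge 16 x 8 x 512,
15 convolution layers). A small spec is provided for CPU-scale training
experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm, Conv2D, ReLU, Sigmoid, Upsample2x


@dataclass(frozen=True)
class NetworkSpec:
    """Level layout of a residual U-Net.

    ``filters[:-1]`` are the encoder unit widths (the first unit keeps
    full resolution, the rest stride by 2); ``filters[-1]`` is the
    bridge width; the decoder mirrors ``filters[-2::-1]``. The total
    number of unit levels is ``2 * len(filters) - 1``.
    """

    name: str
    input_shape: tuple[int, int]
    filters: tuple[int, ...]

    @property
    def n_levels(self) -> int:
        return 2 * len(self.filters) - 1

    @property
    def n_conv_layers(self) -> int:
        """3x3 convolutions in the units plus the final 1x1 projection."""
        return 2 * self.n_levels + 1

    def __post_init__(self) -> None:
        down = 2 ** (len(self.filters) - 1)
        h, w = self.input_shape
        if h % down or w % down:
            raise ValueError(
                f"input shape {self.input_shape} not divisible by the "
                f"encoder downsampling factor {down}"
            )


#: 9-level axial network: input 128x128x1, bridge 8x8x1024.
AXIAL_SPEC = NetworkSpec("axial", (128, 128), (64, 128, 256, 512, 1024))
#: 7-level coronal/sagittal network: input 128x64x1, bridge 16x8x512.
CORONAL_SAGITTAL_SPEC = NetworkSpec("coronal_sagittal", (128, 64), (64, 128, 256, 512))
#: Small 5-level network for CPU-scale experiments and tests.
SMALL_SPEC = NetworkSpec("small", (32, 32), (8, 16, 32))


class ResidualUnit:
    """Pre-activation residual unit: 2 x (BN -> ReLU -> 3x3 conv) + shortcut."""

    def __init__(self, cin: int, cout: int, stride: int, rng: np.random.Generator):
        self.bn1 = BatchNorm(cin)
        self.relu1 = ReLU()
        self.conv1 = Conv2D(cin, cout, k=3, stride=stride, rng=rng)
        self.bn2 = BatchNorm(cout)
        self.relu2 = ReLU()
        self.conv2 = Conv2D(cout, cout, k=3, stride=1, rng=rng)
        self.proj = Conv2D(cin, cout, k=1, stride=stride, rng=rng) if (stride != 1 or cin != cout) else None
        self.cin, self.cout, self.stride = cin, cout, stride
        self.last_output_shape: tuple | None = None

    def layers(self):
        out = [self.bn1, self.conv1, self.bn2, self.conv2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1.forward(self.relu1.forward(self.bn1.forward(x, train), train), train)
        h = self.conv2.forward(self.relu2.forward(self.bn2.forward(h, train), train), train)
        s = self.proj.forward(x, train) if self.proj is not None else x
        out = h + s
        self.last_output_shape = out.shape[1:]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.conv2.backward(dout)
        d = self.bn2.backward(self.relu2.backward(d))
        d = self.conv1.backward(d)
        d = self.bn1.backward(self.relu1.backward(d))
        ds = self.proj.backward(dout) if self.proj is not None else dout
        return d + ds


class ResUNet:
    """Residual U-Net with per-pixel sigmoid output.

    ``forward`` maps ``(N, H, W, 1)`` inputs in [0, 1] to foreground
    probabilities of the same shape. ``backward`` expects the gradient
    of the loss with respect to those probabilities.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.filters
        self.encoder = [ResidualUnit(1, f[0], 1, rng)]
        self.encoder += [ResidualUnit(f[i - 1], f[i], 2, rng) for i in range(1, len(f) - 1)]
        self.bridge = ResidualUnit(f[-2], f[-1], 2, rng)
        self.decoder = [
            ResidualUnit(f[i + 1] + f[i], f[i], 1, rng) for i in range(len(f) - 2, -1, -1)
        ]
        self.ups = [Upsample2x() for _ in self.decoder]
        self.out_conv = Conv2D(f[0], 1, k=1, stride=1, rng=rng)
        self.sigmoid = Sigmoid()
        self._split: list[int] = []

    # -- plumbing ---------------------------------------------------------
    def units(self) -> list[ResidualUnit]:
        return [*self.encoder, self.bridge, *self.decoder]

    def params(self):
        out = []
        for u in self.units():
            for layer in u.layers():
                out.extend(layer.params())
        out.extend(self.out_conv.params())
        return out

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:3] != self.spec.input_shape or x.shape[3] != 1:
            raise ValueError(
                f"expected input (N, {self.spec.input_shape[0]}, {self.spec.input_shape[1]}, 1), "
                f"got {x.shape}"
            )
        skips = []
        h = x
        for unit in self.encoder:
            h = unit.forward(h, train)
            skips.append(h)
        h = self.bridge.forward(h, train)
        self._split = []
        for unit, up, skip in zip(self.decoder, self.ups, reversed(skips)):
            h = up.forward(h, train)
            self._split.append(h.shape[-1])
            h = np.concatenate([h, skip], axis=-1)
            h = unit.forward(h, train)
        logits = self.out_conv.forward(h, train)
        return self.sigmoid.forward(logits, train)

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        d = self.sigmoid.backward(dprob)
        d = self.out_conv.backward(d)
        skip_grads = [None] * len(self.encoder)
        for idx in range(len(self.decoder) - 1, -1, -1):
            d = self.decoder[idx].backward(d)
            c_up = self._split[idx]
            d_up, d_skip = d[..., :c_up], d[..., c_up:]
            enc_idx = len(self.encoder) - 1 - idx
            skip_grads[enc_idx] = d_skip
            d = self.ups[idx].backward(d_up)
        d = self.bridge.backward(d)
        for enc_idx in range(len(self.encoder) - 1, -1, -1):
            if skip_grads[enc_idx] is not None:
                d = d + skip_grads[enc_idx]
            d = self.encoder[enc_idx].backward(d)
        return d

    # -- introspection ----------------------------------------------------
    def audit(self) -> list[dict]:
        """Walk the built network level by level with a real forward pass.

        Returns one row per unit level plus the output projection:
        ``{"level", "conv_layers", "filters", "stride", "output_shape"}``
        where the output shape is ``(H, W, C)`` as observed on a dummy
        input of the spec's shape.
        """
        h, w = self.spec.input_shape
        self.forward(np.zeros((1, h, w, 1), dtype=np.float32), train=False)
        rows = []
        for lvl, unit in enumerate(self.units(), start=1):
            rows.append(
                {
                    "level": lvl,
                    "conv_layers": 2,
                    "filters": unit.cout,
                    "stride": unit.stride,
                    "output_shape": tuple(int(v) for v in unit.last_output_shape),
                }
            )
        rows.append(
            {
                "level": "output",
                "conv_layers": 1,
                "filters": 1,
                "stride": 1,
                "output_shape": (h, w, 1),
            }
        )
        return rows

    def bridge_channels(self) -> int:
        """Channel count of the bridge feature map, from a forward pass."""
        h, w = self.spec.input_shape
        self.forward(np.zeros((1, h, w, 1), dtype=np.float32), train=False)
        return int(self.bridge.last_output_shape[-1])


def build_network(spec: NetworkSpec, seed: int = 0) -> ResUNet:
    """Construct a residual U-Net for the given level specification."""
    return ResUNet(spec, seed=seed)


# -- checkpointing ---------------------------------------------------------

def save_model(model: ResUNet, path: str) -> None:
    """Save weights (npz) with a JSON sidecar describing the spec."""
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    arrays = {f"p{i}": value for i, (value, _) in enumerate(model.params())}
    bns = [l for u in model.units() for l in u.layers() if isinstance(l, BatchNorm)]
    for i, bn in enumerate(bns):
        arrays[f"rm{i}"] = bn.running_mean
        arrays[f"rv{i}"] = bn.running_var
    np.savez(path, **arrays)
    spec = model.spec
    with open(path + ".json", "w") as fh:
        json.dump(
            {"name": spec.name, "input_shape": list(spec.input_shape), "filters": list(spec.filters)},
            fh,
        )


def load_model(path: str) -> ResUNet:
    path = str(path)
    if not path.endswith(".npz"):
        path += ".npz"
    with open(path + ".json") as fh:
        meta = json.load(fh)
    spec = NetworkSpec(meta["name"], tuple(meta["input_shape"]), tuple(meta["filters"]))
    model = ResUNet(spec)
    data = np.load(path)
    for i, (value, _) in enumerate(model.params()):
        value[...] = data[f"p{i}"]
    bns = [l for u in model.units() for l in u.layers() if isinstance(l, BatchNorm)]
    for i, bn in enumerate(bns):
        bn.running_mean[...] = data[f"rm{i}"]
        bn.running_var[...] = data[f"rv{i}"]
    return model
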