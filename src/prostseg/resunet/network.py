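"""Residual U-Net: encoder/decoder of residual blocks with long skip
connections, a 1x1 output convolution, and a logistic output head.

Each residual block runs two 3x3 conv -> batch-norm -> ReLU stages on the
main path, projects the input through a 1x1 convolution on the shortcut,
adds the two, and applies a final ReLU.  Downsampling is 2x2 max pooling;
upsampling is nearest-neighbour followed by a 3x3 convolution, with the
matching encoder features concatenated before each decoder block.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .layers import BatchNorm2d, Conv2d, MaxPool2d, ReLU, Sigmoid, UpsampleNearest2d
from .losses import get_loss  # noqa: F401  (re-export convenience)

__all__ = ["NetworkSpec", "ResBlock", "ResUNet", "build_network",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class NetworkSpec:
    in_channels: int
    depth: int = 4
    base_width: int = 32
    out_channels: int = 1
    kernel: int = 3
    #: optional expected square input size, validated at build time
    input_size: int | None = None

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.in_channels not in (1, 2, 3, 4):
            raise ValueError("in_channels must be 1..4 (images plus conditioning masks)")
        if self.base_width < 1 or self.out_channels < 1:
            raise ValueError("widths must be positive")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(self.base_width * 2 ** i for i in range(self.depth))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


class ResBlock:
    """conv3-BN-ReLU x2 main path, 1x1 conv shortcut, add, ReLU."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng, dtype, name: str):
        self.conv1 = Conv2d(in_ch, out_ch, kernel, rng, dtype, f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_ch, dtype, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_ch, out_ch, kernel, rng, dtype, f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_ch, dtype, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.shortcut = Conv2d(in_ch, out_ch, 1, rng, dtype, f"{name}.shortcut")
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        main = self.relu1.forward(self.bn1.forward(self.conv1.forward(x, train), train))
        main = self.relu2.forward(self.bn2.forward(self.conv2.forward(main, train), train))
        short = self.shortcut.forward(x, train)
        return self.relu_out.forward(main + short)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        gm = self.conv2.backward(self.bn2.backward(self.relu2.backward(g)))
        gm = self.conv1.backward(self.bn1.backward(self.relu1.backward(gm)))
        gs = self.shortcut.backward(g)
        return gm + gs

    def layers(self):
        return [self.conv1, self.bn1, self.conv2, self.bn2, self.shortcut]

    def params(self) -> list[dict]:
        return [p for layer in self.layers() for p in layer.params()]


class ResUNet:
    def __init__(self, spec: NetworkSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        widths = spec.widths
        k = spec.kernel
        self.enc: list[ResBlock] = []
        self.pools: list[MaxPool2d] = []
        ch = spec.in_channels
        for i in range(spec.depth - 1):
            self.enc.append(ResBlock(ch, widths[i], k, rng, dtype, f"enc{i}"))
            self.pools.append(MaxPool2d())
            ch = widths[i]
        self.bottleneck = ResBlock(ch, widths[-1], k, rng, dtype, "bottleneck")

        self.ups: list[UpsampleNearest2d] = []
        self.upconvs: list[Conv2d] = []
        self.dec: list[ResBlock] = []
        ch = widths[-1]
        for i in range(spec.depth - 2, -1, -1):
            self.ups.append(UpsampleNearest2d())
            self.upconvs.append(Conv2d(ch, widths[i], k, rng, dtype, f"up{i}"))
            self.dec.append(ResBlock(2 * widths[i], widths[i], k, rng, dtype, f"dec{i}"))
            ch = widths[i]
        self.head = Conv2d(ch, spec.out_channels, 1, rng, dtype, "head")
        self.sigmoid = Sigmoid()

    # -- execution ---------------------------------------------------------

    def _check_size(self, x: np.ndarray) -> None:
        h, w = x.shape[2], x.shape[3]
        f = 2 ** (self.spec.depth - 1)
        if h % f or w % f:
            raise ValueError(f"spatial size {(h, w)} not divisible by {f}")
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"expected {self.spec.in_channels} input channels, got {x.shape[1]}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Per-pixel probabilities in (0, 1); deterministic in eval mode."""
        self._check_size(x)
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, upconv, dec, skip in zip(self.ups, self.upconvs, self.dec, reversed(skips)):
            x = upconv.forward(up.forward(x, train), train)
            x = dec.forward(np.concatenate([skip, x], axis=1), train)
        self._n_skip = [s.shape[1] for s in skips]
        return self.sigmoid.forward(self.head.forward(x, train))

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        g = self.head.backward(self.sigmoid.backward(dprob))
        skip_grads: list[np.ndarray] = []
        for i, (up, upconv, dec) in enumerate(zip(self.ups, self.upconvs, self.dec)):
            g = dec.backward(g)
            n_skip = self._n_skip[len(self._n_skip) - 1 - i]
            skip_grads.append(g[:, :n_skip])
            g = up.backward(upconv.backward(g[:, n_skip:]))
        g = self.bottleneck.backward(g)
        for block, pool, gskip in zip(reversed(self.enc), reversed(self.pools),
                                      skip_grads):
            g = block.backward(pool.backward(g) + gskip)
        return g

    # -- parameter plumbing ------------------------------------------------

    def params(self) -> list[dict]:
        out = []
        for b in self.enc:
            out.extend(b.params())
        out.extend(self.bottleneck.params())
        for c in self.upconvs:
            out.extend(c.params())
        for b in self.dec:
            out.extend(b.params())
        out.extend(self.head.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p["grad"][...] = 0.0

    def n_params(self) -> int:
        return sum(p["value"].size for p in self.params())

    def _bn_layers(self) -> list[BatchNorm2d]:
        blocks = self.enc + [self.bottleneck] + self.dec
        return [l for b in blocks for l in b.layers() if isinstance(l, BatchNorm2d)]

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p["name"]: p["value"].copy() for p in self.params()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"__running_mean_{i}"] = bn.running_mean.copy()
            state[f"__running_var_{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            p["value"][...] = state[p["name"]]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"__running_mean_{i}"]
            bn.running_var[...] = state[f"__running_var_{i}"]


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> ResUNet:
    """Instantiate a seeded Res-UNet; validates ``spec.input_size`` if set."""
    if spec.input_size is not None:
        f = 2 ** (spec.depth - 1)
        if spec.input_size % f:
            raise ValueError(
                f"input size {spec.input_size} not divisible by 2^(depth-1) = {f}")
    return ResUNet(spec, np.random.default_rng(seed), dtype=dtype)


def save_checkpoint(net: ResUNet, path: str | Path) -> None:
    """Weights as ``.npz`` with a JSON sidecar embedding the NetworkSpec."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(net.spec.to_dict(), indent=2) + "\n")


def load_checkpoint(path: str | Path, dtype=np.float32) -> ResUNet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing checkpoint: {path}")
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing checkpoint sidecar: {sidecar}")
    spec = NetworkSpec.from_dict(json.loads(sidecar.read_text()))
    net = build_network(spec, dtype=dtype)
    with np.load(path) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net
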