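"""Single-encoder, dual-decoder U-Net for dural-sac segmentation.

One contracting path (two conv-batchnorm-ReLU blocks per stage, 2x2 max
pooling) feeds two structurally parallel expansive paths that share the
encoder's skip connections via channel concatenation.  The decoders
differ only in how they grow the feature maps: decoder A upsamples with
2x2-stride-2 transposed convolutions, decoder B with fixed
nearest-neighbour interpolation followed by a 3x3 convolution.  During
semi-supervised training both decoders run; at inference a single,
configured decoder produces the probability map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import layers
from .layers import (
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    MaxPool2d,
    Param,
    ReLU,
    Upsample2,
    softmax,
    softmax_backward,
)

DECODERS = ("A", "B")


@dataclass(frozen=True)
class DualDecoderUNetConfig:
    input_size: tuple[int, int] = (160, 160)
    depth: int = 4
    base_channels: int = 16
    n_classes: int = 2
    inference_decoder: str = "A"

    def __post_init__(self) -> None:
        h, w = self.input_size
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {self.input_size} must be divisible by 2^depth = {f} "
                f"so every pooling stage halves it exactly"
            )
        if self.base_channels < 1 or self.n_classes < 2 or self.depth < 1:
            raise ValueError("base_channels >= 1, n_classes >= 2 and depth >= 1 required")
        if self.inference_decoder not in DECODERS:
            raise ValueError(f"inference_decoder must be one of {DECODERS}")


@dataclass
class SegmentationOutput:
    """Per-decoder class-probability maps (N, H, W, C), same H x W as the input."""

    probs: dict[str, np.ndarray]
    logits: dict[str, np.ndarray]

    def decoder(self, name: str) -> np.ndarray:
        return self.probs[name]


class _ConvBlock:
    """conv(3x3) -> batchnorm -> ReLU."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, k=3, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = ReLU()

    def params(self) -> list[Param]:
        return self.conv.params() + self.bn.params()

    def forward(self, x, train):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, d):
        return self.conv.backward(self.bn.backward(self.act.backward(d)))


class _Decoder:
    """One expansive path; ``kind`` selects how feature maps are grown."""

    def __init__(self, kind: str, depth: int, base: int, n_classes: int,
                 rng: np.random.Generator):
        self.kind = kind
        self.ups: list = []
        self.blocks: list[tuple[_ConvBlock, _ConvBlock]] = []
        ch = base * 2 ** depth
        for _ in range(depth):
            if kind == "A":
                self.ups.append(ConvTranspose2d(ch, ch // 2, rng=rng))
            else:
                self.ups.append((Upsample2(), Conv2d(ch, ch // 2, k=3, rng=rng)))
            self.blocks.append((_ConvBlock(ch, ch // 2, rng), _ConvBlock(ch // 2, ch // 2, rng)))
            ch //= 2
        self.head = Conv2d(base, n_classes, k=1, rng=rng)

    def params(self) -> list[Param]:
        out: list[Param] = []
        for up in self.ups:
            out += up.params() if not isinstance(up, tuple) else up[1].params()
        for b1, b2 in self.blocks:
            out += b1.params() + b2.params()
        return out + self.head.params()

    def _up_forward(self, i, x, train):
        up = self.ups[i]
        if isinstance(up, tuple):
            return up[1].forward(up[0].forward(x, train), train)
        return up.forward(x, train)

    def _up_backward(self, i, d):
        up = self.ups[i]
        if isinstance(up, tuple):
            return up[0].backward(up[1].backward(d))
        return up.backward(d)

    def forward(self, bottom: np.ndarray, skips: list[np.ndarray], train: bool) -> np.ndarray:
        h = bottom
        self._skip_channels = []
        for i, (b1, b2) in enumerate(self.blocks):
            u = self._up_forward(i, h, train)
            skip = skips[-(i + 1)]
            self._skip_channels.append(skip.shape[-1])
            h = np.concatenate([skip, u], axis=-1)
            h = b2.forward(b1.forward(h, train), train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Returns (d_bottom, d_skips ordered deepest-first like forward use)."""
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray] = []
        for i in reversed(range(len(self.blocks))):
            b1, b2 = self.blocks[i]
            d = b1.backward(b2.backward(d))
            c = self._skip_channels[i]
            dskips.append(d[..., :c])
            d = self._up_backward(i, d[..., c:])
        dskips.reverse()  # now aligned with forward's use order (deepest skip first)
        return d, dskips


class DualDecoderUNet:
    """The full model; see module docstring."""

    def __init__(self, config: DualDecoderUNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        base, depth = config.base_channels, config.depth
        self.enc_blocks: list[tuple[_ConvBlock, _ConvBlock]] = []
        self.pools: list[MaxPool2d] = []
        cin = 1
        ch = base
        for _ in range(depth):
            self.enc_blocks.append((_ConvBlock(cin, ch, rng), _ConvBlock(ch, ch, rng)))
            self.pools.append(MaxPool2d())
            cin, ch = ch, ch * 2
        self.bottleneck = (_ConvBlock(cin, ch, rng), _ConvBlock(ch, ch, rng))
        self.decoders = {k: _Decoder(k, depth, base, config.n_classes, rng) for k in DECODERS}

    # -- parameters -----------------------------------------------------
    def encoder_params(self) -> list[Param]:
        out: list[Param] = []
        for b1, b2 in self.enc_blocks:
            out += b1.params() + b2.params()
        out += self.bottleneck[0].params() + self.bottleneck[1].params()
        return out

    def decoder_params(self, name: str) -> list[Param]:
        return self.decoders[name].params()

    def parameters(self) -> list[Param]:
        return self.encoder_params() + self.decoder_params("A") + self.decoder_params("B")

    # -- forward / backward ---------------------------------------------
    def forward(self, x: np.ndarray, phase: str = "train") -> SegmentationOutput:
        """Run the network.

        ``phase='train'`` runs both decoders with batch statistics and
        caches activations for :meth:`backward`; ``phase='inference'``
        runs only the configured decoder with running statistics.
        """
        if phase not in ("train", "inference"):
            raise ValueError(f"unknown phase {phase!r}")
        x = np.asarray(x, dtype=layers.DTYPE)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[..., None]
        if x.shape[1:3] != tuple(self.config.input_size):
            raise ValueError(f"input {x.shape[1:3]} does not match configured {self.config.input_size}")
        train = phase == "train"
        h = x
        skips: list[np.ndarray] = []
        for (b1, b2), pool in zip(self.enc_blocks, self.pools):
            h = b2.forward(b1.forward(h, train), train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h, train), train)
        names = DECODERS if train else (self.config.inference_decoder,)
        logits = {k: self.decoders[k].forward(h, skips, train) for k in names}
        probs = {k: softmax(v) for k, v in logits.items()}
        return SegmentationOutput(probs=probs, logits=logits)

    def backward(self, dlogits: dict[str, np.ndarray]) -> None:
        """Accumulate gradients from per-decoder logit gradients."""
        d_bottom = None
        d_skips: list[np.ndarray] | None = None
        for name, dl in dlogits.items():
            db, ds = self.decoders[name].backward(dl)
            d_bottom = db if d_bottom is None else d_bottom + db
            if d_skips is None:
                d_skips = ds
            else:
                d_skips = [a + b for a, b in zip(d_skips, ds)]
        d = self.bottleneck[0].backward(self.bottleneck[1].backward(d_bottom))
        # d_skips is ordered deepest-first; skips were appended shallow-first
        for i in reversed(range(len(self.enc_blocks))):
            d = self.pools[i].backward(d)
            d = d + d_skips[len(self.enc_blocks) - 1 - i]
            b1, b2 = self.enc_blocks[i]
            d = b1.backward(b2.backward(d))

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        stats = {}
        for i, bn in enumerate(self._batchnorms()):
            stats[f"rm{i}"] = bn.running_mean
            stats[f"rv{i}"] = bn.running_var
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays, **stats)

    @classmethod
    def load(cls, path) -> "DualDecoderUNet":
        with np.load(path, allow_pickle=False) as data:
            raw = json.loads(str(data["config"]))
            raw["input_size"] = tuple(raw["input_size"])
            model = cls(DualDecoderUNetConfig(**raw))
            for i, p in enumerate(model.parameters()):
                p.value[...] = data[f"p{i}"]
            for i, bn in enumerate(model._batchnorms()):
                bn.running_mean[...] = data[f"rm{i}"]
                bn.running_var[...] = data[f"rv{i}"]
        return model

    def _batchnorms(self) -> list[BatchNorm2d]:
        bns = []
        for b1, b2 in self.enc_blocks + [self.bottleneck]:
            bns += [b1.bn, b2.bn]
        for k in DECODERS:
            for b1, b2 in self.decoders[k].blocks:
                bns += [b1.bn, b2.bn]
        return bns


def build_model(config: DualDecoderUNetConfig, seed: int = 0) -> DualDecoderUNet:
    """Construct the dual-decoder U-Net with deterministic initial weights."""
    return DualDecoderUNet(config, seed=seed)
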