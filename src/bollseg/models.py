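"""Encoder-decoder segmentation models for cotton-boll pixel labelling.

The family consists of a symmetric five-stage encoder-decoder baseline
(VGG-style SegNet: 2-2-3-3-3 convolutions per encoder stage, mirrored in
the decoder, max-pooling indices handed to the paired max-unpooling stage)
and four recombined variants that vary along two axes: the number of 3x3
convolutions per stage, and whether dilated (r = 2) convolutions are used
in the deepest stages.

=========  =========================  =============================
variant    convs per stage            dilation
=========  =========================  =============================
model1     1                          none
model2     1                          r=2 in the two deepest stages
model3     2                          none
model4     2                          r=2 on the second conv of the
                                      two deepest stages
baseline   2,2,3,3,3 (VGG-13 style)   none
=========  =========================  =============================

Dilation widens a 3x3 kernel's receptive field to ``3 + 2(r-1)`` pixels
per side without adding weights, so model2/model1 and model4/model3 are
exact parameter-count twins.  All convolutions are zero-padded to preserve
spatial size; each is followed by batch normalization and a ReLU except the
final class-scoring convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "VARIANTS",
    "ConvBlockSpec",
    "SegModelSpec",
    "SegModel",
    "receptive_field",
    "make_spec",
    "build_model",
    "parameter_count",
]

VARIANTS = ("model1", "model2", "model3", "model4", "segnet_baseline")

_ENCODER_DILATIONS: dict[str, tuple[tuple[int, ...], ...]] = {
    "model1": ((1,), (1,), (1,), (1,), (1,)),
    "model2": ((1,), (1,), (1,), (2,), (2,)),
    "model3": ((1, 1), (1, 1), (1, 1), (1, 1), (1, 1)),
    "model4": ((1, 1), (1, 1), (1, 1), (1, 2), (1, 2)),
    "segnet_baseline": ((1, 1), (1, 1), (1, 1, 1), (1, 1, 1), (1, 1, 1)),
}


def receptive_field(kernel: int, dilation: int) -> int:
    """Side length of the effective receptive field of one dilated conv.

    A kernel of size k with dilation r has taps spaced r pixels apart, so
    its support spans ``k + (k - 1)(r - 1)`` pixels: 3 -> 3 at r=1,
    3 -> 5 at r=2, 3 -> 7 at r=3.
    """
    if kernel % 2 == 0 or kernel < 1:
        raise ValueError("kernel must be a positive odd integer")
    if dilation < 1:
        raise ValueError("dilation must be >= 1")
    return kernel + (kernel - 1) * (dilation - 1)


@dataclass(frozen=True)
class ConvBlockSpec:
    """One stage's convolution stack: a dilation rate per 3x3 conv."""

    dilations: tuple[int, ...]
    channels_out: int
    kernel: int = 3
    has_bn: bool = True

    def __post_init__(self) -> None:
        if self.kernel != 3:
            raise ValueError("the block library is built from 3x3 convolutions")
        if len(self.dilations) < 1 or any(d < 1 for d in self.dilations):
            raise ValueError("each stage needs >= 1 conv with dilation >= 1")

    @property
    def n_convs(self) -> int:
        return len(self.dilations)


@dataclass(frozen=True)
class SegModelSpec:
    variant: str
    encoder: tuple[ConvBlockSpec, ...]
    decoder: tuple[ConvBlockSpec, ...]
    base_width: int = 16
    num_classes: int = 2
    in_channels: int = 3

    def __post_init__(self) -> None:
        if len(self.encoder) != len(self.decoder):
            raise ValueError("encoder and decoder must have the same number of stages")
        if self.num_classes < 2 or self.base_width < 1:
            raise ValueError("num_classes >= 2 and base_width >= 1 required")

    @property
    def n_stages(self) -> int:
        return len(self.encoder)

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "encoder": [[list(b.dilations), b.channels_out] for b in self.encoder],
                "decoder": [[list(b.dilations), b.channels_out] for b in self.decoder],
                "base_width": self.base_width,
                "num_classes": self.num_classes,
                "in_channels": self.in_channels,
            }
        )

    @staticmethod
    def from_json(text: str) -> "SegModelSpec":
        d = json.loads(text)
        enc = tuple(ConvBlockSpec(tuple(ds), ch) for ds, ch in d["encoder"])
        dec = tuple(ConvBlockSpec(tuple(ds), ch) for ds, ch in d["decoder"])
        return SegModelSpec(
            variant=d["variant"],
            encoder=enc,
            decoder=dec,
            base_width=d["base_width"],
            num_classes=d["num_classes"],
            in_channels=d["in_channels"],
        )


def _stage_widths(base_width: int, n_stages: int, cap_mult: int = 8) -> list[int]:
    """Channel width doubles per stage, capped at cap_mult * base."""
    return [min(base_width * 2**i, base_width * cap_mult) for i in range(n_stages)]


def make_spec(
    variant: str, base_width: int = 16, num_classes: int = 2, in_channels: int = 3
) -> SegModelSpec:
    """Build the spec for one named variant; decoder mirrors the encoder."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    dil = _ENCODER_DILATIONS[variant]
    widths = _stage_widths(base_width, len(dil))
    encoder = tuple(
        ConvBlockSpec(dilations=d, channels_out=wd) for d, wd in zip(dil, widths)
    )
    decoder = tuple(
        ConvBlockSpec(dilations=d, channels_out=wd)
        for d, wd in zip(reversed(dil), reversed(widths))
    )
    return SegModelSpec(
        variant=variant,
        encoder=encoder,
        decoder=decoder,
        base_width=base_width,
        num_classes=num_classes,
        in_channels=in_channels,
    )


def _conv_param_count(cin: int, cout: int, kernel: int, bn: bool) -> int:
    n = kernel * kernel * cin * cout + cout  # weight + bias
    if bn:
        n += 2 * cout  # gamma + beta
    return n


def parameter_count(spec: SegModelSpec) -> int:
    """Exact count of trainable scalars, computed from the spec alone.

    Counts convolution weights and biases plus batch-norm affine terms;
    running statistics are not trainable.  Dilation does not enter the
    count, so dilated variants are weight-for-weight twins of their
    undilated counterparts.
    """
    total = 0
    cin = spec.in_channels
    for block in spec.encoder:
        for _ in block.dilations:
            total += _conv_param_count(cin, block.channels_out, block.kernel, block.has_bn)
            cin = block.channels_out
    # decoder stage i outputs the width of the next-shallower encoder stage;
    # the last conv of the final stage scores num_classes without BN
    enc_widths = [b.channels_out for b in spec.encoder]
    for si, block in enumerate(spec.decoder):
        target = enc_widths[spec.n_stages - 2 - si] if si < spec.n_stages - 1 else None
        n_convs = block.n_convs
        for ci in range(n_convs):
            last = ci == n_convs - 1
            if si == spec.n_stages - 1 and last:
                total += _conv_param_count(cin, spec.num_classes, block.kernel, bn=False)
                cin = spec.num_classes
            else:
                cout = target if (last and target is not None) else block.channels_out
                total += _conv_param_count(cin, cout, block.kernel, block.has_bn)
                cin = cout
    return total


class _ConvBNReLU:
    def __init__(self, cin: int, cout: int, dilation: int, rng: np.random.Generator,
                 final: bool = False):
        self.conv = nn.Conv2d(cin, cout, kernel=3, dilation=dilation, rng=rng)
        self.bn = None if final else nn.BatchNorm2d(cout)
        self.act = None if final else nn.ReLU()

    def params(self) -> list[nn.Param]:
        ps = self.conv.params()
        if self.bn is not None:
            ps += self.bn.params()
        return ps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        x = self.conv.forward(x, train)
        if self.bn is not None:
            x = self.bn.forward(x, train)
            x = self.act.forward(x, train)
        return x

    def backward(self, d: np.ndarray) -> np.ndarray:
        if self.bn is not None:
            d = self.act.backward(d)
            d = self.bn.backward(d)
        return self.conv.backward(d)


class SegModel:
    """A realized encoder-decoder net: image tile -> per-pixel class scores.

    Encoder stage i max-pools after its convolutions and records the argmax
    indices; decoder stage (n_stages - i + 1) max-unpools with those indices
    before its convolutions, so the output spatial size equals the input.
    """

    def __init__(self, spec: SegModelSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        enc_widths = [b.channels_out for b in spec.encoder]
        self.enc_stages: list[list[_ConvBNReLU]] = []
        cin = spec.in_channels
        for block in spec.encoder:
            stage = []
            for d in block.dilations:
                stage.append(_ConvBNReLU(cin, block.channels_out, d, rng))
                cin = block.channels_out
            self.enc_stages.append(stage)
        self.pools = [nn.MaxPool2d() for _ in spec.encoder]
        self.unpools = [nn.MaxUnpool2d() for _ in spec.decoder]
        self.dec_stages: list[list[_ConvBNReLU]] = []
        for si, block in enumerate(spec.decoder):
            target = enc_widths[spec.n_stages - 2 - si] if si < spec.n_stages - 1 else None
            stage = []
            n_convs = block.n_convs
            for ci, d in enumerate(block.dilations):
                last = ci == n_convs - 1
                if si == spec.n_stages - 1 and last:
                    stage.append(_ConvBNReLU(cin, spec.num_classes, d, rng, final=True))
                    cin = spec.num_classes
                else:
                    cout = target if (last and target is not None) else block.channels_out
                    stage.append(_ConvBNReLU(cin, cout, d, rng))
                    cin = cout
            self.dec_stages.append(stage)

    # -- plumbing ----------------------------------------------------------
    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for stage in self.enc_stages + self.dec_stages:
            for layer in stage:
                ps += layer.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def state_dict(self) -> dict:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self.params())}
        bns = [l.bn for stage in self.enc_stages + self.dec_stages for l in stage if l.bn]
        for i, bn in enumerate(bns):
            state[f"rm{i}"] = bn.running_mean.copy()
            state[f"rv{i}"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]
        bns = [l.bn for stage in self.enc_stages + self.dec_stages for l in stage if l.bn]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = state[f"rm{i}"]
            bn.running_var[...] = state[f"rv{i}"]

    def _check_dims(self, h: int, w: int) -> None:
        f = 2**self.spec.n_stages
        if h % f or w % f:
            ph, pw = (-h) % f, (-w) % f
            raise ValueError(
                f"input {h}x{w} must be divisible by 2^{self.spec.n_stages}={f}; "
                f"pad by {ph} rows and {pw} cols (e.g. to {h + ph}x{w + pw})"
            )

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, C, H, W) float32 -> (N, num_classes, H, W) logits."""
        n, c, h, w = x.shape
        self._check_dims(h, w)
        indices = []
        for stage, pool in zip(self.enc_stages, self.pools):
            for layer in stage:
                x = layer.forward(x, train)
            x, idx = pool.forward(x)
            indices.append(idx)
        for si, (stage, unpool) in enumerate(zip(self.dec_stages, self.unpools)):
            x = unpool.forward(x, indices[self.spec.n_stages - 1 - si])
            for layer in stage:
                x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for si in range(self.spec.n_stages - 1, -1, -1):
            for layer in reversed(self.dec_stages[si]):
                d = layer.backward(d)
            d = self.unpools[si].backward(d)
        for si in range(self.spec.n_stages - 1, -1, -1):
            d = self.pools[si].backward(d)
            for layer in reversed(self.enc_stages[si]):
                d = layer.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (inference mode)."""
        return nn.softmax(self.forward(x, train=False), axis=1)


def build_model(spec: SegModelSpec, seed: int = 0) -> SegModel:
    """Realize a spec as a trainable model with seeded initialization."""
    return SegModel(spec, seed=seed)
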