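"""3D attention U-Net for tumor-subregion segmentation.

A U-shaped encoder/decoder over 3D patches.  Every decoder level
concatenates the matching encoder skip, passes the block through the
attention module, then convolves.  The attention module combines a
*spatial* gate (a 1x1x1 convolution across channels producing an
``X x Y x Z x 1`` map) and a *channel* gate (global average pooling
followed by a dense map producing a ``1 x 1 x 1 x C`` vector), both
squashed by a logistic sigmoid, with a bypass connection:

    out = F + F ⊙ spatial ⊙ channel

The additive identity path keeps gradients flowing when the gates
saturate and makes the module an exact identity for zero gate maps.

Input channels default to 5: the four enhanced modalities plus the
matched-filter energy map.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autodiff as ad
from .volume_io import DEFAULT_LABEL_SET, SegmentationMask

__all__ = [
    "AttentionUNetConfig",
    "AttentionMaps",
    "AttentionGate",
    "AttentionUNet",
    "apply_attention",
    "attention_forward",
    "build_model",
    "segment_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class AttentionUNetConfig:
    """Architecture hyperparameters; parameter count is a deterministic
    function of this config."""

    in_channels: int = 5
    out_classes: int = 4
    depth: int = 3
    base_filters: int = 8
    norm: str = "instance"  # or "none"
    upsample_mode: str = "nearest"

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        if self.norm not in ("instance", "none"):
            raise ValueError(f"unknown norm {self.norm!r}")
        if self.upsample_mode != "nearest":
            raise ValueError("only nearest-neighbor upsampling is implemented")


@dataclass
class AttentionMaps:
    """Gate maps produced by the attention module (values in (0, 1))."""

    spatial: np.ndarray  # (1, X, Y, Z)
    channel: np.ndarray  # (C, 1, 1, 1)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class _Conv:
    """3x3x3 (or 1x1x1) same-padded convolution, optional norm + ReLU."""

    def __init__(
        self,
        rng: np.random.Generator,
        cin: int,
        cout: int,
        k: int = 3,
        norm: str = "instance",
        act: bool = True,
        bias: bool = True,
    ):
        self.w = ad.Tensor(
            _he_init(rng, (cout, cin, k, k, k), cin * k**3), requires_grad=True
        )
        # bias is redundant (and gradient-dead) before instance norm
        use_bias = bias and norm == "none"
        self.b = (
            ad.Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
            if use_bias
            else None
        )
        self.norm = norm
        if norm == "instance":
            self.gamma = ad.Tensor(
                np.ones((cout, 1, 1, 1), dtype=np.float32), requires_grad=True
            )
            self.beta = ad.Tensor(
                np.zeros((cout, 1, 1, 1), dtype=np.float32), requires_grad=True
            )
        self.act = act

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        out = ad.conv3d(x, self.w, self.b, padding="same")
        if self.norm == "instance":
            out = ad.instance_norm(out, self.gamma, self.beta)
        if self.act:
            out = ad.relu(out)
        return out

    def parameters(self) -> list[ad.Tensor]:
        ps = [self.w]
        if self.b is not None:
            ps.append(self.b)
        if self.norm == "instance":
            ps += [self.gamma, self.beta]
        return ps


class _ConvBlock:
    def __init__(self, rng, cin, cout, norm):
        self.c1 = _Conv(rng, cin, cout, norm=norm)
        self.c2 = _Conv(rng, cout, cout, norm=norm)

    def __call__(self, x):
        return self.c2(self.c1(x))

    def parameters(self):
        return self.c1.parameters() + self.c2.parameters()


def apply_attention(
    features: ad.Tensor, spatial: ad.Tensor, channel: ad.Tensor
) -> ad.Tensor:
    """Bypass combination ``F + F ⊙ spatial ⊙ channel``.

    With zero gate maps this is exactly the identity (the bypass path).
    """
    return ad.add(features, ad.mul(ad.mul(features, spatial), channel))


class AttentionGate:
    """Channel + spatial attention with a bypass connection."""

    def __init__(self, rng: np.random.Generator, channels: int):
        self.channels = channels
        # spatial gate: 1x1xC convolution across channels -> one map
        self.ws = ad.Tensor(
            _he_init(rng, (1, channels, 1, 1, 1), channels), requires_grad=True
        )
        self.bs = ad.Tensor(np.zeros(1, dtype=np.float32), requires_grad=True)
        # channel gate: dense map on the pooled 1x1x1xC vector
        self.wc = ad.Tensor(
            _he_init(rng, (channels, channels, 1, 1, 1), channels),
            requires_grad=True,
        )
        self.bc = ad.Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def maps(self, features: ad.Tensor) -> tuple[ad.Tensor, ad.Tensor]:
        spatial = ad.sigmoid(ad.conv3d(features, self.ws, self.bs, padding=0))
        pooled = ad.spatial_mean(features)
        channel = ad.sigmoid(ad.conv3d(pooled, self.wc, self.bc, padding=0))
        return spatial, channel

    def __call__(self, features: ad.Tensor) -> tuple[ad.Tensor, AttentionMaps]:
        spatial, channel = self.maps(features)
        out = apply_attention(features, spatial, channel)
        return out, AttentionMaps(spatial.data.copy(), channel.data.copy())

    def parameters(self):
        return [self.ws, self.bs, self.wc, self.bc]


def attention_forward(
    features: np.ndarray, gate: AttentionGate
) -> tuple[np.ndarray, AttentionMaps]:
    """Run the attention module on a plain (C, X, Y, Z) array."""
    out, maps = gate(ad.Tensor(np.asarray(features, dtype=np.float32)))
    return out.data, maps


class AttentionUNet:
    """The assembled network; forward maps (C_in, X, Y, Z) -> logits."""

    def __init__(self, config: AttentionUNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        f = [config.base_filters * 2**i for i in range(config.depth + 1)]
        norm = config.norm

        self.encoders = []
        cin = config.in_channels
        for i in range(config.depth):
            self.encoders.append(_ConvBlock(rng, cin, f[i], norm))
            cin = f[i]
        self.bottleneck = _ConvBlock(rng, f[config.depth - 1], f[config.depth], norm)

        self.upconvs, self.attentions, self.decoders = [], [], []
        for i in reversed(range(config.depth)):
            self.upconvs.append(_Conv(rng, f[i + 1], f[i], norm=norm))
            self.attentions.append(AttentionGate(rng, 2 * f[i]))
            self.decoders.append(_ConvBlock(rng, 2 * f[i], f[i], norm))

        self.head = _Conv(
            rng, f[0], config.out_classes, k=1, norm="none", act=False
        )
        self.last_attention_maps: list[AttentionMaps] = []

    def forward(self, x: np.ndarray | ad.Tensor) -> ad.Tensor:
        if not isinstance(x, ad.Tensor):
            x = ad.Tensor(np.asarray(x, dtype=np.float32))
        if x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, "
                f"got {x.shape[0]}"
            )
        skips, h = [], x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = ad.maxpool3d(h)
        h = self.bottleneck(h)
        self.last_attention_maps = []
        for up, att, dec, skip in zip(
            self.upconvs, self.attentions, self.decoders, reversed(skips)
        ):
            h = up(ad.upsample_nearest3d(h))
            h = ad.concat([skip, h], axis=0)
            h, maps = att(h)
            self.last_attention_maps.append(maps)
            h = dec(h)
        return self.head(h)

    def forward_batch(self, batch: list[np.ndarray]) -> list[ad.Tensor]:
        return [self.forward(x) for x in batch]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x).data.astype(np.float64)
        logits -= logits.max(axis=0, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=0, keepdims=True)

    def parameters(self) -> list[ad.Tensor]:
        ps = []
        for enc in self.encoders:
            ps += enc.parameters()
        ps += self.bottleneck.parameters()
        for up, att, dec in zip(self.upconvs, self.attentions, self.decoders):
            ps += up.parameters() + att.parameters() + dec.parameters()
        ps += self.head.parameters()
        return ps

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_model(config: AttentionUNetConfig, seed: int = 0) -> AttentionUNet:
    """Construct a seeded network; same (config, seed) -> same weights."""
    return AttentionUNet(config, seed=seed)


def _window_starts(total: int, patch: int, step: int) -> list[int]:
    if total <= patch:
        return [0]
    starts = list(range(0, total - patch + 1, step))
    if starts[-1] != total - patch:
        starts.append(total - patch)
    return starts


def segment_volume(
    model: AttentionUNet,
    channels: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    label_values: tuple[int, ...] | None = None,
    patch_size: int = 32,
    overlap: float = 0.5,
) -> SegmentationMask:
    """Sliding-window inference with overlap averaging of class scores.

    ``channels`` is the stacked network input (C_in, X, Y, Z).  Class
    probabilities from overlapping windows are averaged; the per-voxel
    argmax is mapped back to the label vocabulary (index 0 =
    background).  The default window matches the training patch size so
    the instance-norm statistics seen at inference match training.
    """
    channels = np.asarray(channels, dtype=np.float32)
    if channels.shape[0] != model.config.in_channels:
        raise ValueError(
            f"volume has {channels.shape[0]} channels but model expects "
            f"{model.config.in_channels}"
        )
    if label_values is None:
        label_values = tuple(sorted(DEFAULT_LABEL_SET))
    if len(label_values) != model.config.out_classes - 1:
        raise ValueError("label_values must have out_classes - 1 entries")

    shape = channels.shape[1:]
    patch = [min(patch_size, s) for s in shape]
    step = [max(1, int(round(p * (1.0 - overlap)))) for p in patch]
    scores = np.zeros((model.config.out_classes, *shape), dtype=np.float64)
    counts = np.zeros(shape, dtype=np.float64)
    for sx in _window_starts(shape[0], patch[0], step[0]):
        for sy in _window_starts(shape[1], patch[1], step[1]):
            for sz in _window_starts(shape[2], patch[2], step[2]):
                sl = (
                    slice(sx, sx + patch[0]),
                    slice(sy, sy + patch[1]),
                    slice(sz, sz + patch[2]),
                )
                proba = model.predict_proba(channels[(slice(None),) + sl])
                scores[(slice(None),) + sl] += proba
                counts[sl] += 1.0
    scores /= counts
    cls = scores.argmax(axis=0)
    lut = np.array([0, *label_values], dtype=np.int16)
    return SegmentationMask(lut[cls], label_set=frozenset(label_values))


def save_checkpoint(model: AttentionUNet, path: str) -> None:
    """Single-file checkpoint: config JSON + parameter arrays."""
    arrays = {f"p{i}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path: str) -> AttentionUNet:
    with np.load(path, allow_pickle=False) as z:
        config = AttentionUNetConfig(**json.loads(str(z["config"])))
        model = AttentionUNet(config, seed=0)
        for i, p in enumerate(model.parameters()):
            p.data = z[f"p{i}"].astype(np.float32)
    return model
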