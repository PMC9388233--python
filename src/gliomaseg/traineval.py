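"""Training loop and BraTS-style evaluation battery.

Region metrics (Dice, HD95 Hausdorff in mm, sensitivity, specificity)
are computed per evaluation region ET/WT/TC; pixel-level metrics
(accuracy, precision, recall, F1 and the 2x2 confusion matrix) are
computed on the binary tumor / non-tumor task, i.e. any nonzero label
counts as tumor.

Conventions follow the BraTS evaluation: Dice of two empty regions is
1, Hausdorff of an empty-vs-nonempty pair returns a configured penalty
(default: the image diagonal in mm), and both events are logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .net import AttentionUNet, segment_volume
from .volume_io import SegmentationMask

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMetrics",
    "PixelConfusion",
    "TrainConfig",
    "region_masks",
    "dice",
    "hausdorff",
    "sensitivity_specificity",
    "pixel_confusion",
    "evaluate_case",
    "aggregate_metrics",
    "segmentation_loss",
    "prepare_inputs",
    "train",
]

REGIONS = ("ET", "WT", "TC")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class RegionMetrics:
    """One scalar per metric per region in {ET, WT, TC}."""

    dice: dict[str, float]
    hausdorff: dict[str, float]
    sensitivity: dict[str, float]
    specificity: dict[str, float]


@dataclass
class PixelConfusion:
    """Binary tumor/non-tumor voxel counts and derived rates."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def region_masks(mask: SegmentationMask) -> dict[str, np.ndarray]:
    """Boolean ET/WT/TC volumes from a label mask.

    Default BraTS mapping: ET = {4}, TC = {1, 4}, WT = {1, 2, 4};
    the mask's own ``region_defs`` (e.g. for the {1, 3, 4} vocabulary)
    take precedence.
    """
    return {name: mask.region(name) for name in REGIONS}


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(pred_region: np.ndarray, true_region: np.ndarray) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; both-empty pairs score 1."""
    a = np.asarray(pred_region, dtype=bool)
    b = np.asarray(true_region, dtype=bool)
    _check_shapes(a, b)
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int(np.logical_and(a, b).sum()) / (sa + sb)


def _surface(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, border_value=0)
    return mask & ~eroded


def hausdorff(
    pred_region: np.ndarray,
    true_region: np.ndarray,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    percentile: float = 95.0,
    empty_penalty: float | None = None,
) -> float:
    """Robust (95th-percentile) symmetric surface distance in mm.

    ``percentile=100`` gives the classical max-Hausdorff.  If exactly
    one region is empty the configured penalty is returned (default:
    the image diagonal in mm) with a warning; two empty regions score 0.
    """
    a = np.asarray(pred_region, dtype=bool)
    b = np.asarray(true_region, dtype=bool)
    _check_shapes(a, b)
    ea, eb = not a.any(), not b.any()
    if ea and eb:
        return 0.0
    if ea or eb:
        if empty_penalty is None:
            empty_penalty = float(
                np.linalg.norm(np.asarray(a.shape) * np.asarray(spacing))
            )
        warnings.warn(
            "hausdorff: one region is empty; returning penalty "
            f"{empty_penalty:g} mm",
            stacklevel=2,
        )
        return float(empty_penalty)
    sa, sb = _surface(a), _surface(b)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dt_b[sa]
    d_ba = dt_a[sb]
    return float(
        max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
    )


def sensitivity_specificity(
    pred_region: np.ndarray, true_region: np.ndarray
) -> tuple[float, float]:
    """``TP/(TP+FN)`` and ``TN/(TN+FP)``; empty denominators give 0."""
    a = np.asarray(pred_region, dtype=bool)
    b = np.asarray(true_region, dtype=bool)
    _check_shapes(a, b)
    tp = int((a & b).sum())
    fn = int((~a & b).sum())
    tn = int((~a & ~b).sum())
    fp = int((a & ~b).sum())
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("undefined sensitivity/specificity ratio -> 0", stacklevel=2)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    return sens, spec


def pixel_confusion(
    pred_mask: np.ndarray | SegmentationMask,
    true_mask: np.ndarray | SegmentationMask,
) -> PixelConfusion:
    """Binary tumor/non-tumor confusion counts over all voxels."""
    p = pred_mask.labels if isinstance(pred_mask, SegmentationMask) else pred_mask
    t = true_mask.labels if isinstance(true_mask, SegmentationMask) else true_mask
    p = np.asarray(p) != 0
    t = np.asarray(t) != 0
    _check_shapes(p, t)
    return PixelConfusion(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def evaluate_case(
    pred_mask: SegmentationMask,
    true_mask: SegmentationMask,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[RegionMetrics, PixelConfusion]:
    """All region metrics plus the pixel confusion for one case."""
    pr = region_masks(pred_mask)
    tr = region_masks(true_mask)
    d, h, sn, sp = {}, {}, {}, {}
    for name in REGIONS:
        d[name] = dice(pr[name], tr[name])
        h[name] = hausdorff(pr[name], tr[name], spacing)
        sn[name], sp[name] = sensitivity_specificity(pr[name], tr[name])
        if not tr[name].any() and not pr[name].any():
            logger.info("region %s empty in both masks; Dice=1 by convention",
                        name)
    return RegionMetrics(d, h, sn, sp), pixel_confusion(pred_mask, true_mask)


def aggregate_metrics(
    cases: list[RegionMetrics],
) -> dict[str, dict[str, dict[str, float]]]:
    """Mean / stddev / median per metric per region over cases."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for metric in ("dice", "hausdorff", "sensitivity", "specificity"):
        out[metric] = {}
        for region in REGIONS:
            vals = np.asarray([getattr(c, metric)[region] for c in cases])
            out[metric][region] = {
                "mean": float(vals.mean()),
                "stddev": float(vals.std(ddof=0)),
                "median": float(np.median(vals)),
            }
    return out


# ---------------------------------------------------------------------------
# Loss and training
# ---------------------------------------------------------------------------


def segmentation_loss(
    logits: ad.Tensor,
    target_onehot: np.ndarray,
    ce_weight: float = 1.0,
    dice_weight: float = 1.0,
    eps: float = 1e-6,
) -> ad.Tensor:
    """Soft-Dice + cross-entropy loss (equal weights by default).

    ``logits`` is (K, X, Y, Z); ``target_onehot`` the matching one-hot
    encoding.  Soft Dice averages over all K classes.
    """
    t = ad.Tensor(target_onehot.astype(logits.data.dtype))
    k = logits.shape[0]
    n_vox = float(np.prod(logits.shape[1:]))

    shift = ad.Tensor(logits.data.max(axis=0, keepdims=True))  # constant
    z = ad.sub(logits, shift)
    e = ad.exp(z)
    se = ad.sum_axis(e, 0, keepdims=True)
    logp = ad.sub(z, ad.log(se))
    p = ad.div(e, se)

    ce = ad.mul(
        ad.sum_all(ad.mul(t, logp)),
        ad.Tensor(np.asarray(-1.0 / n_vox, dtype=logits.data.dtype)),
    )

    inter = ad.sum_axis(ad.mul(p, t), (1, 2, 3), keepdims=False)
    card = ad.add(
        ad.sum_axis(p, (1, 2, 3), keepdims=False),
        ad.sum_axis(t, (1, 2, 3), keepdims=False),
    )
    two = ad.Tensor(np.asarray(2.0, dtype=logits.data.dtype))
    eps_t = ad.Tensor(np.asarray(eps, dtype=logits.data.dtype))
    dice_per_class = ad.div(
        ad.add(ad.mul(two, inter), eps_t), ad.add(card, eps_t)
    )
    mean_dice = ad.mul(
        ad.sum_all(dice_per_class),
        ad.Tensor(np.asarray(1.0 / k, dtype=logits.data.dtype)),
    )
    dice_loss = ad.sub(ad.Tensor(np.asarray(1.0, dtype=logits.data.dtype)),
                       mean_dice)

    return ad.add(
        ad.mul(ce, ad.Tensor(np.asarray(ce_weight, dtype=logits.data.dtype))),
        ad.mul(dice_loss,
               ad.Tensor(np.asarray(dice_weight, dtype=logits.data.dtype))),
    )


def prepare_inputs(
    channels: np.ndarray, energy: np.ndarray | None = None
) -> np.ndarray:
    """Z-score each channel and optionally append the energy map."""
    channels = np.asarray(channels, dtype=np.float32)
    out = []
    for c in channels:
        std = c.std()
        out.append((c - c.mean()) / (std if std > 0 else 1.0))
    if energy is not None:
        e = np.asarray(energy, dtype=np.float32)
        std = e.std()
        out.append((e - e.mean()) / (std if std > 0 else 1.0))
    return np.stack(out)


@dataclass
class TrainConfig:
    """Optimization hyperparameters for phantom-scale training."""

    steps: int = 400
    lr: float = 1e-3
    patch_size: int = 32
    seed: int = 0
    ce_weight: float = 1.0
    dice_weight: float = 1.0
    augment_flips: bool = True
    tumor_centered_prob: float = 0.9
    val_interval: int = 100
    label_values: tuple[int, ...] = (1, 2, 4)


def _one_hot(labels: np.ndarray, label_values: tuple[int, ...]) -> np.ndarray:
    classes = [0, *label_values]
    out = np.zeros((len(classes), *labels.shape), dtype=np.float32)
    for i, v in enumerate(classes):
        out[i] = labels == v
    return out


def _random_patch(
    channels: np.ndarray,
    labels: np.ndarray,
    patch: int,
    rng: np.random.Generator,
    tumor_centered_prob: float,
) -> tuple[np.ndarray, np.ndarray]:
    shape = labels.shape
    size = [min(patch, s) for s in shape]
    tumor = np.argwhere(labels > 0)
    if len(tumor) and rng.random() < tumor_centered_prob:
        center = tumor[rng.integers(len(tumor))]
    else:
        center = np.array([rng.integers(s) for s in shape])
    start = [
        int(np.clip(c - sz // 2, 0, s - sz))
        for c, sz, s in zip(center, size, shape)
    ]
    sl = tuple(slice(st, st + sz) for st, sz in zip(start, size))
    return channels[(slice(None),) + sl], labels[sl]


def train(
    model: AttentionUNet,
    dataset: list[tuple[np.ndarray, SegmentationMask]],
    train_config: TrainConfig | None = None,
    val_dataset: list[tuple[np.ndarray, SegmentationMask]] | None = None,
) -> tuple[AttentionUNet, dict]:
    """Patch-based training with Adam on (input channels, mask) pairs.

    ``dataset`` items are ``(channels, mask)`` with ``channels`` already
    stacked for the network (see :func:`prepare_inputs`).  The loss is
    soft-Dice + cross-entropy.  When a validation set is given, whole
    volumes are segmented every ``val_interval`` steps and the weights
    with the best validation WT Dice are restored at the end.  Fully
    deterministic for a given (seed, config).
    """
    cfg = train_config or TrainConfig()
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = ad.Adam(params, lr=cfg.lr)
    history: dict = {"loss": [], "val_dice": []}
    best = (-1.0, None)

    def validate() -> float:
        scores = []
        for channels, mask in val_dataset:
            # infer with the training window size: instance-norm
            # statistics then match what the network was optimized on
            pred = segment_volume(
                model, channels, label_values=cfg.label_values,
                patch_size=cfg.patch_size,
            )
            pred_wt = np.isin(pred.labels, cfg.label_values)
            scores.append(dice(pred_wt, mask.labels > 0))
        return float(np.mean(scores))

    for step in range(1, cfg.steps + 1):
        channels, mask = dataset[rng.integers(len(dataset))]
        x, y = _random_patch(
            channels, mask.labels, cfg.patch_size, rng, cfg.tumor_centered_prob
        )
        if cfg.augment_flips:
            for ax in range(3):
                if rng.random() < 0.5:
                    x = np.flip(x, axis=ax + 1)
                    y = np.flip(y, axis=ax)
        x = np.ascontiguousarray(x, dtype=np.float32)
        y = np.ascontiguousarray(y)

        logits = model.forward(x)
        loss = segmentation_loss(
            logits, _one_hot(y, cfg.label_values), cfg.ce_weight, cfg.dice_weight
        )
        loss_val = float(loss.data)
        if not np.isfinite(loss_val):
            raise RuntimeError(
                f"NaN/Inf loss at step {step}; lower the learning rate "
                "or check input normalization"
            )
        history["loss"].append(loss_val)
        opt.zero_grad()
        loss.backward()
        opt.step()

        if val_dataset and (step % cfg.val_interval == 0 or step == cfg.steps):
            vd = validate()
            history["val_dice"].append((step, vd))
            if vd > best[0]:
                best = (vd, [p.data.copy() for p in params])

    if best[1] is not None:
        for p, data in zip(params, best[1]):
            p.data = data
        history["best_val_dice"] = best[0]
    return model, history
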