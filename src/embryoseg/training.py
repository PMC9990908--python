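"""Dataset splitting, crop sampling, augmentation, and the training loop.

Training follows the scaled-down analog of the full pipeline: whole-volume
intensity normalization to zero mean / unit variance, random cubic crops
(optionally biased to contain foreground, which matters on small
background-dominated phantoms), augmentation by random rotation, affine
transformation, intensity shift and Gaussian noise, and AdamW on the
combined Dice + cross-entropy objective with periodic validation by full
sliding-window inference.  The checkpoint with the best validation mean
foreground Dice is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import autodiff as ad
from .core_io import LabelVolume, VolumeImage, check_paired
from .unetr import SegModel, dice_ce_loss

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "SplitSpec",
    "split_dataset",
    "normalize_intensity",
    "sample_crop",
    "augment",
    "train",
]


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of the random augmentations (0 disables a transform)."""

    rotate_deg: float = 10.0
    scale: float = 0.1
    shear: float = 0.05
    intensity_shift: float = 0.1
    noise_sd: float = 0.05

    @classmethod
    def none(cls) -> "AugmentConfig":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)

    @property
    def spatial(self) -> bool:
        return self.rotate_deg > 0 or self.scale > 0 or self.shear > 0


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; the full-scale run uses 80,000 iterations at
    lr 1e-4 with 128-voxel crops and validation every 500 steps, the tiny
    preset hundreds of iterations at a higher rate."""

    iterations: int = 80_000
    lr: float = 1e-4
    crop_size: int = 128
    val_interval: int = 500
    batch_size: int = 1
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0
    weight_decay: float = 1e-5
    adam_betas: tuple[float, float] = (0.9, 0.999)
    grad_clip: float | None = None
    prior_bias_init: bool = False
    foreground_biased: bool = True
    dice_background: bool = True
    stop_at_val_dice: float | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.val_interval < 1 or self.val_interval > self.iterations:
            raise ValueError("val_interval must be in 1..iterations")

    @classmethod
    def tiny(cls, iterations: int = 600, crop_size: int = 64, **kw) -> "TrainConfig":
        """CPU preset: short schedule at an aggressive, clipped rate with a
        fast-adapting second moment — the miniature network tolerates (and
        needs) a much hotter optimizer than the full-scale schedule."""
        kw.setdefault("lr", 1e-2)
        kw.setdefault("adam_betas", (0.9, 0.95))
        kw.setdefault("grad_clip", 1.0)
        kw.setdefault("prior_bias_init", True)
        kw.setdefault("val_interval", min(100, iterations))
        kw.setdefault("aug", AugmentConfig.none())
        return cls(iterations=iterations, crop_size=crop_size, **kw)


@dataclass(frozen=True)
class SplitSpec:
    """Specimen counts for the train/validation/test split."""

    n_train: int
    n_val: int
    n_test: int

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_val, self.n_test) < 0:
            raise ValueError("split counts must be >= 0")


def split_dataset(ids: list, spec: SplitSpec, seed: int = 0):
    """Random, disjoint, exhaustive train/val/test split of specimen IDs."""
    total = spec.n_train + spec.n_val + spec.n_test
    if total != len(ids):
        raise ValueError(f"split counts sum to {total} but got {len(ids)} IDs")
    order = list(ids)
    np.random.default_rng([int(seed), 303]).shuffle(order)
    train = order[: spec.n_train]
    val = order[spec.n_train : spec.n_train + spec.n_val]
    test = order[spec.n_train + spec.n_val :]
    return train, val, test


def normalize_intensity(v: VolumeImage) -> VolumeImage:
    """Zero-mean, unit-variance over the whole volume (constant -> zeros)."""
    data = v.data.astype(np.float32)
    mu = float(data.mean())
    sd = float(data.std())
    if sd == 0.0:
        out = np.zeros_like(data)
    else:
        out = (data - mu) / sd
    return VolumeImage(out, v.spacing.copy(), v.origin.copy())


def _pad_to(arr: np.ndarray, size: int, value) -> np.ndarray:
    pads = []
    for s in arr.shape:
        short = max(0, size - s)
        pads.append((short // 2, short - short // 2))
    if any(p != (0, 0) for p in pads):
        arr = np.pad(arr, pads, constant_values=value)
    return arr


def sample_crop(
    img: VolumeImage,
    lab: LabelVolume,
    size: int,
    seed_or_rng,
    foreground_biased: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Random axis-aligned cubic crop of a paired image/label volume.

    Volumes smaller than ``size`` are first zero-padded symmetrically
    (background label 0).  With ``foreground_biased`` the offset is
    redrawn (bounded retries) until the label crop contains foreground.
    """
    check_paired(img, lab)
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng([int(seed_or_rng), 404])
    )
    data = _pad_to(img.data, size, 0.0)
    labels = _pad_to(lab.data, size, 0)
    max_off = [s - size for s in data.shape]
    tries = 20 if foreground_biased else 1
    for attempt in range(tries):
        off = [int(rng.integers(0, m + 1)) for m in max_off]
        lc = labels[off[0]:off[0] + size, off[1]:off[1] + size, off[2]:off[2] + size]
        if not foreground_biased or lc.any() or attempt == tries - 1:
            break
    ic = data[off[0]:off[0] + size, off[1]:off[1] + size, off[2]:off[2] + size]
    return ic.copy(), lc.copy()


def _affine_matrix(aug: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Random rotation * shear * scale matrix with the config magnitudes."""
    angles = np.deg2rad(rng.uniform(-aug.rotate_deg, aug.rotate_deg, size=3))
    rot = np.eye(3)
    for axis, ang in enumerate(angles):
        c, s = np.cos(ang), np.sin(ang)
        r = np.eye(3)
        i, j = [a for a in range(3) if a != axis]
        r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
        rot = r @ rot
    scale = np.diag(rng.uniform(1 - aug.scale, 1 + aug.scale, size=3))
    shear = np.eye(3)
    pairs = [(0, 1), (0, 2), (1, 2)]
    for (i, j), v in zip(pairs, rng.uniform(-aug.shear, aug.shear, size=3)):
        shear[i, j] = v
    return rot @ shear @ scale


def affine_transform_pair(
    crop: np.ndarray, label_crop: np.ndarray, matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one affine matrix about the crop center to both grids.

    The image is resampled trilinearly, the labels nearest-neighbor (so
    no new label IDs can appear).  Right-angle rotations are exact.
    """
    center = (np.asarray(crop.shape, dtype=float) - 1) / 2.0
    inv = np.linalg.inv(matrix)
    offset = center - inv @ center
    img = ndimage.affine_transform(crop, inv, offset=offset, order=1, mode="constant")
    lab = ndimage.affine_transform(
        label_crop, inv, offset=offset, order=0, mode="constant", cval=0
    )
    return img, lab


def augment(
    crop: np.ndarray,
    label_crop: np.ndarray,
    aug: AugmentConfig,
    seed_or_rng,
) -> tuple[np.ndarray, np.ndarray]:
    """One sampled instance of each enabled augmentation.

    Spatial transforms are shared by image and labels; intensity shift and
    Gaussian noise touch the image only.  All magnitudes zero -> identity.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng([int(seed_or_rng), 505])
    )
    img, lab = crop, label_crop
    if aug.spatial:
        img, lab = affine_transform_pair(img, lab, _affine_matrix(aug, rng))
    if aug.intensity_shift > 0:
        img = img + rng.uniform(-aug.intensity_shift, aug.intensity_shift)
    if aug.noise_sd > 0:
        img = img + rng.normal(0.0, aug.noise_sd, size=img.shape)
    return np.ascontiguousarray(img, dtype=np.float32), lab


def train(
    model: SegModel,
    train_set: list[tuple[VolumeImage, LabelVolume]],
    val_set: list[tuple[VolumeImage, LabelVolume]],
    cfg: TrainConfig,
    log=None,
) -> tuple[SegModel, list[dict]]:
    """Optimize the model; returns (best model, history rows).

    History rows are dicts with ``step``, ``train_loss`` and, on
    validation steps, ``val_dice`` (mean foreground Dice over the
    validation set by sliding-window inference).  The returned model
    carries the parameters of the best validation round (the final ones
    if ``val_set`` is empty).
    """
    from .evaluation import dice_report  # local import to avoid a cycle
    from .inference import InferenceConfig, sliding_window_segment

    if not train_set:
        raise ValueError("training set is empty")
    if cfg.crop_size % model.config.patch_size:
        raise ValueError("crop_size must be divisible by the model patch size")

    norm_train = [(normalize_intensity(im), lb) for im, lb in train_set]
    norm_val = [(normalize_intensity(im), lb) for im, lb in val_set]
    if cfg.prior_bias_init:
        # start the output layer at the empirical log class priors so rare
        # structures get balanced gradients from step one
        counts = np.zeros(model.config.n_classes)
        for _, lb in train_set:
            counts += np.bincount(
                lb.data.reshape(-1), minlength=model.config.n_classes
            )[: model.config.n_classes]
        priors = counts / max(counts.sum(), 1.0)
        model.out_b.data[:] = np.log(priors + 1e-8).astype(model.out_b.dtype)
    rng = np.random.default_rng([int(cfg.seed), 606])
    opt = ad.AdamW(model.parameters(), lr=cfg.lr, betas=cfg.adam_betas,
                   weight_decay=cfg.weight_decay)
    infer_cfg = InferenceConfig(window=model.config.input_size, overlap=0.25)

    best_dice = -1.0
    best_params = None
    history: list[dict] = []
    n_classes = model.config.n_classes

    for step in range(1, cfg.iterations + 1):
        opt.zero_grad()
        loss_val = 0.0
        for _ in range(cfg.batch_size):
            idx = int(rng.integers(len(norm_train)))
            img, lab = norm_train[idx]
            ic, lc = sample_crop(img, lab, cfg.crop_size, rng, cfg.foreground_biased)
            ic, lc = augment(ic, lc, cfg.aug, rng)
            if lc.max() >= n_classes:
                raise ValueError("label ID exceeds model n_classes - 1")
            probs = model.forward_tensor(ic)
            loss = dice_ce_loss(
                probs, lc, include_background=cfg.dice_background
            ) * (1.0 / cfg.batch_size)
            loss.backward()
            loss_val += loss.item()
        if cfg.grad_clip is not None:
            total = np.sqrt(sum(float((p.grad ** 2).sum())
                                for p in model.parameters() if p.grad is not None))
            if total > cfg.grad_clip:
                scale = cfg.grad_clip / total
                for p in model.parameters():
                    if p.grad is not None:
                        p.grad *= scale
        opt.step()
        row = {"step": step, "train_loss": loss_val}

        stop = False
        if norm_val and step % cfg.val_interval == 0:
            dices = []
            for img, lab in norm_val:
                seg, _ = sliding_window_segment(model, img, infer_cfg, normalized=True)
                rep = dice_report(seg, lab, labels=range(1, n_classes))
                dices.append(rep.mean)
            val_dice = float(np.mean(dices))
            row["val_dice"] = val_dice
            if val_dice > best_dice:
                best_dice = val_dice
                best_params = [p.data.copy() for p in model.parameters()]
            if cfg.stop_at_val_dice is not None and val_dice >= cfg.stop_at_val_dice:
                stop = True
        history.append(row)
        if log is not None:
            log(row)
        if stop:
            break

    if best_params is not None:
        for p, data in zip(model.parameters(), best_params):
            p.data = data
    return model, history
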