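"""Whole-volume segmentation by sliding-window inference.

The full-resolution volume is covered by overlapping cubic windows
(stride = floor(window * (1 - overlap)), final window clamped to the
volume edge so every voxel is covered), each window is passed through the
network, and the per-voxel class probabilities are blended with either a
constant or a Gaussian window profile before the arg-max labeling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_io import LabelVolume, VolumeImage
from .unetr import SegModel

__all__ = ["InferenceConfig", "window_positions", "sliding_window_segment"]


@dataclass(frozen=True)
class InferenceConfig:
    """Window geometry and blending; the full-scale pipeline uses a
    128-voxel window with overlap 0.8."""

    window: int = 128
    overlap: float = 0.8
    blend: str = "gaussian"

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")
        if self.blend not in ("constant", "gaussian"):
            raise ValueError("blend must be 'constant' or 'gaussian'")


def _axis_positions(extent: int, window: int, stride: int) -> list[int]:
    last = extent - window
    positions = []
    p = 0
    while True:
        if p >= last:
            positions.append(last)
            break
        positions.append(p)
        p += stride
    return positions


def window_positions(
    shape: tuple[int, int, int], window: int, overlap: float
) -> list[tuple[int, int, int]]:
    """Corner indices of the sliding windows covering ``shape``.

    Stride is max(1, floor(window*(1-overlap))); the final position per
    axis is clamped to ``extent - window`` so the last voxel is covered.
    Axes shorter than the window must be padded by the caller.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if any(s < window for s in shape):
        raise ValueError("volume axes must be >= window (pad first)")
    stride = max(1, int(np.floor(window * (1.0 - overlap))))
    per_axis = [_axis_positions(s, window, stride) for s in shape]
    return list(itertools.product(*per_axis))


def _blend_profile(window: int, mode: str, dtype=np.float32) -> np.ndarray:
    if mode == "constant":
        return np.ones((window,) * 3, dtype=dtype)
    sigma = window / 8.0
    x = np.arange(window, dtype=np.float64) - (window - 1) / 2.0
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g = np.maximum(g, 1e-4)
    w = g[:, None, None] * g[None, :, None] * g[None, None, :]
    return w.astype(dtype)


def sliding_window_segment(
    model: SegModel,
    v: VolumeImage,
    cfg: InferenceConfig | None = None,
    normalized: bool = False,
) -> tuple[LabelVolume, np.ndarray]:
    """Segment a whole volume; returns (label volume, probability volume).

    The volume is intensity-normalized (unless ``normalized=True``),
    padded at the high end of any axis shorter than the window, windowed,
    blended, un-padded, and arg-maxed with ties broken toward the lower
    class ID (background wins ties).
    """
    from .training import normalize_intensity  # deferred: avoids cycle

    cfg = cfg or InferenceConfig(window=model.config.input_size)
    if cfg.window != model.config.input_size:
        raise ValueError(
            f"window {cfg.window} != model input size {model.config.input_size}"
        )
    if not normalized:
        v = normalize_intensity(v)
    data = v.data
    orig_shape = data.shape
    pad = [max(0, cfg.window - s) for s in orig_shape]
    if any(pad):
        data = np.pad(data, [(0, p) for p in pad])
    C = model.config.n_classes
    acc = np.zeros((C,) + data.shape, dtype=np.float32)
    wsum = np.zeros(data.shape, dtype=np.float32)
    profile = _blend_profile(cfg.window, cfg.blend)
    for x, y, z in window_positions(data.shape, cfg.window, cfg.overlap):
        sl = np.s_[x : x + cfg.window, y : y + cfg.window, z : z + cfg.window]
        probs = model.forward(data[sl])
        acc[(slice(None),) + sl] += probs * profile
        wsum[sl] += profile
    acc /= wsum
    sl0 = tuple(slice(0, s) for s in orig_shape)
    acc = acc[(slice(None),) + sl0]
    labels = np.argmax(acc, axis=0).astype(np.int32)  # first max -> lowest ID
    return LabelVolume(labels, v.spacing.copy(), v.origin.copy()), acc
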