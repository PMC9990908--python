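"""Synthetic contrast-CT-like embryo phantoms with exact organ labels.

Each phantom is a smooth body envelope (soft tissue over an air background)
containing ``n_organs`` non-overlapping ellipsoidal organs with distinct
mean intensities — a stand-in for an iodine-stained fetal mouse micro-CT
scan with its atlas labels.  A cohort is a set of phantoms sharing one
canonical organ layout (the "anatomy") with per-specimen jitter of organ
position, size, orientation and intensity, a smooth random deformation,
a bias field and Gaussian noise — the inter-individual variation a
segmentation model must generalize over.

"Knockout" phantoms volumetrically shrink selected organs, emulating
mutant strains whose phenotype is a reduced organ volume (the readout of
the volumetric phenotyping pipeline).  Organ base radii decrease with
label ID, so high IDs play the role of small structures such as the
adrenals and thymic rudiments.

Everything is deterministic given the configuration seed and, for cohort
members, the specimen seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_io import LabelVolume, VolumeImage, default_phantom_labels

__all__ = [
    "PhantomConfig",
    "KnockoutSpec",
    "OrganTemplate",
    "organ_template",
    "generate_phantom",
    "generate_knockout",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom family.

    Intensities are in arbitrary CT-like units (air 0, soft tissue
    ``body_intensity``, organs spread over ``organ_intensity_range``);
    the training normalizer removes absolute scale anyway.
    ``size_jitter`` is the target coefficient of variation of an organ's
    volume across a cohort; ``deform_amplitude`` is the RMS magnitude of
    the smooth random warp in voxels.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_organs: int = 10
    body_intensity: float = 100.0
    organ_intensity_range: tuple[float, float] = (150.0, 250.0)
    noise_sd: float = 5.0
    deform_amplitude: float = 1.5
    seed: int = 0
    spacing: tuple[float, float, float] = (0.05, 0.05, 0.05)
    organ_radius_frac: tuple[float, float] = (0.05, 0.14)
    pos_jitter: float = 1.5
    size_jitter: float = 0.10
    anisotropy: float = 0.25
    intensity_jitter: float = 4.0
    bias_amplitude: float = 4.0

    def __post_init__(self) -> None:
        if self.n_organs < 1:
            raise ValueError("n_organs must be >= 1")
        if len(self.shape) != 3 or min(self.shape) < 16:
            raise ValueError("shape must be 3D with every axis >= 16")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.organ_radius_frac[0] <= self.organ_radius_frac[1] < 0.5:
            raise ValueError("organ_radius_frac must satisfy 0 < lo <= hi < 0.5")


@dataclass(frozen=True)
class KnockoutSpec:
    """Volumetric reduction factors per organ label, each in (0, 1]."""

    reductions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lid, f in self.reductions.items():
            if int(lid) <= 0:
                raise ValueError(f"knockout label ID must be positive, got {lid}")
            if not 0 < f <= 1:
                raise ValueError(
                    f"volumetric factor for label {lid} must be in (0, 1], got {f}"
                )


@dataclass(frozen=True)
class OrganTemplate:
    """Canonical (cohort-level) organ layout derived from the config seed."""

    centers: np.ndarray   # (n, 3) voxel coordinates
    radii: np.ndarray     # (n,) canonical mean radii, voxels, decreasing
    intensities: np.ndarray  # (n,) mean intensity per organ
    body_center: np.ndarray
    body_axes: np.ndarray


def _body_geometry(shape: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    shape = np.asarray(shape, dtype=float)
    return shape / 2.0, 0.42 * shape


def organ_template(cfg: PhantomConfig) -> OrganTemplate:
    """Place canonical organs inside the body envelope.

    Base radii form a decreasing geometric sequence from the largest to
    the smallest ``organ_radius_frac`` (times the smallest grid axis), so
    label 1 is the biggest structure and label ``n_organs`` the smallest.
    Placement is rejection sampling with a separation margin large enough
    to absorb per-specimen jitter.
    """
    rng = np.random.default_rng([int(cfg.seed), 101])
    n = cfg.n_organs
    lo, hi = cfg.organ_radius_frac
    scale = float(min(cfg.shape))
    if n == 1:
        radii = np.array([hi * scale])
    else:
        radii = hi * scale * (lo / hi) ** (np.arange(n) / (n - 1))
    body_center, body_axes = _body_geometry(cfg.shape)
    centers = None
    # progressively relax the separation margin before giving up, so dense
    # layouts still place deterministically on awkward template seeds
    for relax in (1.0, 0.92, 0.84, 0.75):
        margin = 1.03 * relax
        clearance = (1.0 + cfg.pos_jitter) * relax
        trial = np.zeros((n, 3))
        ok = True
        for i in range(n):
            r = radii[i]
            placed = False
            for _ in range(3000):
                c = body_center + (rng.uniform(-1, 1, 3)) * body_axes
                # organ (plus clearance) must fit inside the body ellipsoid
                u = (c - body_center) / np.maximum(body_axes - r - clearance, 1.0)
                if np.sum(u * u) > 1.0:
                    continue
                d = np.linalg.norm(trial[:i] - c, axis=1) if i else np.array([])
                if i and np.any(d < margin * (radii[:i] + r) + cfg.pos_jitter * relax):
                    continue
                trial[i] = c
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            centers = trial
            break
    if centers is None:
        raise RuntimeError(
            "could not place organs without overlap; "
            "reduce n_organs or organ_radius_frac"
        )
    ilo, ihi = cfg.organ_intensity_range
    if n == 1:
        intensities = np.array([(ilo + ihi) / 2.0])
    else:
        intensities = np.linspace(ilo, ihi, n)
    return OrganTemplate(centers, radii, intensities, body_center, body_axes)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _smooth_field(coarse: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    """Upsample a coarse control grid to the full grid with cubic splines."""
    zoom = [s / c for s, c in zip(shape, coarse.shape)]
    return ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)


def generate_phantom(
    cfg: PhantomConfig,
    ko: KnockoutSpec | None = None,
    specimen_seed: int | None = None,
) -> tuple[VolumeImage, LabelVolume]:
    """Generate one phantom (intensity volume, exact label volume).

    All random draws happen in a fixed order independent of ``ko``, and the
    knockout scaling is applied to organ dimensions before rasterization
    and deformation, so a knockout phantom is voxel-comparable to the
    baseline phantom of the same seed with only the targeted organs shrunk
    (linear dimensions scaled by factor^(1/3), volume by ~factor).
    """
    tmpl = organ_template(cfg)
    n = cfg.n_organs
    if ko is not None:
        bad = [lid for lid in ko.reductions if not 1 <= lid <= n]
        if bad:
            raise ValueError(f"knockout IDs {bad} outside 1..{n}")
    seed = cfg.seed if specimen_seed is None else int(specimen_seed)
    rng = np.random.default_rng([seed, int(cfg.seed), 202])

    # specimen-level draws, fixed order
    centers = tmpl.centers + rng.normal(0.0, cfg.pos_jitter, size=(n, 3))
    size_mult = np.exp(rng.normal(0.0, cfg.size_jitter / 3.0, size=n))
    aniso = np.exp(rng.uniform(-cfg.anisotropy, cfg.anisotropy, size=(n, 3)))
    aniso /= np.cbrt(np.prod(aniso, axis=1))[:, None]  # volume-preserving
    rotations = np.stack([_random_rotation(rng) for _ in range(n)])
    intensities = tmpl.intensities + rng.normal(0.0, cfg.intensity_jitter, size=n)
    body_bump = rng.normal(size=(3, 3, 3))
    bias_coarse = rng.normal(size=(3, 3, 3))
    disp_coarse = rng.normal(size=(3, 4, 4, 4))
    noise = rng.normal(size=cfg.shape) if cfg.noise_sd > 0 else None

    radii = tmpl.radii * size_mult
    if ko is not None:
        for lid, f in ko.reductions.items():
            radii[lid - 1] *= f ** (1.0 / 3.0)

    shape = cfg.shape
    grid = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"),
        axis=-1,
    )  # (X, Y, Z, 3)

    u = (grid - tmpl.body_center) / tmpl.body_axes
    body = np.einsum("xyzc,xyzc->xyz", u, u) <= 1.0 + 0.12 * _smooth_field(body_bump, shape)

    labels = np.zeros(shape, dtype=np.int32)
    for i in range(n):
        r = radii[i]
        semi = r * aniso[i]
        lo = np.maximum(np.floor(centers[i] - r * aniso[i].max() - 1).astype(int), 0)
        hi = np.minimum(np.ceil(centers[i] + r * aniso[i].max() + 2).astype(int), shape)
        box = grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] - centers[i]
        rel = np.einsum("ab,xyzb->xyza", rotations[i], box) / semi
        inside = np.einsum("xyzc,xyzc->xyz", rel, rel) <= 1.0
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub_body = body[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside & sub_body & (sub == 0)] = i + 1

    img = np.where(body, cfg.body_intensity, 0.0)
    for i in range(n):
        img[labels == i + 1] = intensities[i]
    img = ndimage.gaussian_filter(img, 0.6)
    img += cfg.bias_amplitude * _smooth_field(bias_coarse, shape)

    if cfg.deform_amplitude > 0:
        disp = np.stack([_smooth_field(d, shape) for d in disp_coarse])
        disp *= cfg.deform_amplitude
        base = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"))
        coords = base + disp
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        labels = ndimage.map_coordinates(labels, coords, order=0, mode="constant")

    if noise is not None:
        img = img + cfg.noise_sd * noise

    spacing = np.asarray(cfg.spacing)
    return (
        VolumeImage(img.astype(np.float32), spacing.copy()),
        LabelVolume(labels, spacing.copy()),
    )


def generate_knockout(
    cfg: PhantomConfig, ko: KnockoutSpec, specimen_seed: int | None = None
) -> tuple[VolumeImage, LabelVolume]:
    """Phantom with the knockout spec's organs volumetrically reduced."""
    return generate_phantom(cfg, ko=ko, specimen_seed=specimen_seed)


def generate_cohort(
    cfg: PhantomConfig,
    n: int,
    ko: KnockoutSpec | None = None,
    base_seed: int = 0,
) -> list[tuple[VolumeImage, LabelVolume]]:
    """Generate ``n`` specimens sharing the cohort anatomy, seeds base_seed+i."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    return [generate_phantom(cfg, ko=ko, specimen_seed=base_seed + i) for i in range(n)]


def phantom_label_dictionary(cfg: PhantomConfig):
    """Label table matching the phantom's organ IDs."""
    return default_phantom_labels(cfg.n_organs)
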