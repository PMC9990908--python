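"""Core grid types and volume/label-table I/O.

Volumes are held in (x, y, z) index order with 0-based voxel indices;
physical geometry (voxel spacing and origin, both in mm) is carried
alongside but all processing happens in voxel space.  On disk the formats
of the 3D Slicer ecosystem are used: NIfTI (``.nii``/``.nii.gz``) and NRRD
(``.nrrd``), read and written through SimpleITK.  Label tables map positive
integer IDs to anatomical structure names; ID 0 is reserved for background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "VolumeImage",
    "LabelVolume",
    "LabelDictionary",
    "read_volume",
    "write_volume",
    "load_label_dictionary",
    "default_phantom_labels",
]

_SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")


def _check_grid(data: np.ndarray, spacing, origin) -> tuple[np.ndarray, np.ndarray]:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError("every grid dimension must be >= 1")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,):
        raise ValueError("spacing and origin must be length-3 vectors")
    if not np.all(spacing > 0):
        raise ValueError("voxel spacing must be strictly positive")
    return spacing, origin


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LabelVolume:
    """A 3D integer label grid; one ID per structure, 0 = background."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if np.issubdtype(arr.dtype, np.floating):
            if not np.array_equal(arr, np.round(arr)):
                raise ValueError("label volume contains non-integral voxel values")
            arr = arr.astype(np.int32)
        elif not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"label data must be integer, got {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise ValueError("label IDs must be non-negative")
        self.data = arr.astype(np.int32, copy=False)
        self.spacing, self.origin = _check_grid(self.data, self.spacing, self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def ids(self) -> list[int]:
        """Sorted non-zero label IDs present in the volume."""
        present = np.unique(self.data)
        return [int(i) for i in present if i != 0]

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def check_paired(img: VolumeImage, lab: LabelVolume) -> None:
    """Assert an image and its label map live on the same grid."""
    if img.shape != lab.shape:
        raise ValueError(f"image shape {img.shape} != label shape {lab.shape}")
    if not np.allclose(img.spacing, lab.spacing):
        raise ValueError("image and label spacing differ")


class LabelDictionary:
    """Ordered table of {positive integer ID -> structure name}.

    IDs and names are both unique; 0 (background) is never an entry.
    """

    def __init__(self, entries: dict[int, str] | list[tuple[int, str]]):
        pairs = list(entries.items()) if isinstance(entries, dict) else list(entries)
        if not pairs:
            raise ValueError("label dictionary needs at least one foreground label")
        self._entries: dict[int, str] = {}
        seen_names: set[str] = set()
        for lid, name in pairs:
            lid = int(lid)
            name = str(name)
            if lid <= 0:
                raise ValueError(f"label ID must be positive, got {lid}")
            if lid in self._entries:
                raise ValueError(f"duplicate label ID {lid}")
            if name in seen_names:
                raise ValueError(f"duplicate label name {name!r}")
            self._entries[lid] = name
            seen_names.add(name)

    @property
    def entries(self) -> dict[int, str]:
        return dict(self._entries)

    @property
    def ids(self) -> list[int]:
        return list(self._entries)

    def name(self, lid: int) -> str:
        return self._entries[int(lid)]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, lid: int) -> bool:
        return int(lid) in self._entries

    def __iter__(self):
        return iter(self._entries.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelDictionary) and self._entries == other._entries

    def validate_volume(self, lab: LabelVolume) -> None:
        """Check every non-zero ID in ``lab`` is a dictionary entry."""
        unknown = [i for i in lab.ids() if i not in self._entries]
        if unknown:
            raise ValueError(f"label volume contains unknown IDs {unknown}")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("id,name\n")
            for lid, name in self._entries.items():
                fh.write(f"{lid},{name}\n")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump([{"id": lid, "name": name} for lid, name in self._entries.items()], fh, indent=1)

    def to_ctbl(self, path: str | Path, seed: int = 0) -> None:
        """Export a 3D Slicer color table (.ctbl) with stable pseudo-random colors."""
        rng = np.random.default_rng(seed)
        with open(path, "w") as fh:
            fh.write("# Color table exported by embryoseg\n")
            fh.write("0 background 0 0 0 0\n")
            for lid, name in self._entries.items():
                r, g, b = rng.integers(32, 256, size=3)
                fh.write(f"{lid} {name.replace(' ', '_')} {r} {g} {b} 255\n")


# Default names for the shipped 10-organ phantom, ordered large to small.
_PHANTOM_ORGAN_NAMES = [
    "liver", "brain", "lungs", "heart", "stomach",
    "kidney left", "kidney right", "spleen", "thymic rudiment", "adrenal",
]


def default_phantom_labels(n_organs: int = 10) -> LabelDictionary:
    """Shipped label table for phantom organs (IDs 1..n, largest first)."""
    if n_organs < 1:
        raise ValueError("need at least one organ")
    names = [
        _PHANTOM_ORGAN_NAMES[i] if i < len(_PHANTOM_ORGAN_NAMES) else f"organ {i + 1}"
        for i in range(n_organs)
    ]
    return LabelDictionary([(i + 1, names[i]) for i in range(n_organs)])


def _suffix_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def read_volume(path: str | Path, kind: str = "image") -> VolumeImage | LabelVolume:
    """Read a NIfTI or NRRD volume.

    ``kind="label"`` forces integer interpretation and rejects files whose
    voxel values are not integral.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if _suffix_of(path) not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported volume format: {path.name}")
    if kind not in ("image", "label"):
        raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"expected a 3D volume, got {img.GetDimension()}D")
    # SimpleITK arrays come back (z, y, x); flip to our (x, y, z) layout.
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing())
    origin = np.asarray(img.GetOrigin())
    if kind == "label":
        return LabelVolume(arr, spacing, origin)
    return VolumeImage(np.ascontiguousarray(arr, dtype=np.float32), spacing, origin)


def write_volume(v: VolumeImage | LabelVolume, path: str | Path) -> None:
    """Write a volume as NIfTI or NRRD; label data is stored as integers."""
    path = Path(path)
    if _suffix_of(path) not in _SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported volume format: {path.name}")
    if path.parent and not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(v, LabelVolume):
        hi = int(v.data.max()) if v.data.size else 0
        dtype = np.uint8 if hi < 256 else (np.int16 if hi < 32768 else np.int32)
        arr = v.data.astype(dtype)
    else:
        arr = v.data.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in v.spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    sitk.WriteImage(img, str(path), useCompression=_suffix_of(path) == ".nii.gz")


def load_label_dictionary(path: str | Path) -> LabelDictionary:
    """Load a label table from CSV (``id,name`` header) or JSON."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        return LabelDictionary([(row["id"], row["name"]) for row in rows])
    pairs: list[tuple[int, str]] = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError("empty label table")
    start = 1 if lines[0].lower().replace(" ", "") == "id,name" else 0
    for ln in lines[start:]:
        lid, name = ln.split(",", 1)
        pairs.append((int(lid), name.strip()))
    return LabelDictionary(pairs)
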