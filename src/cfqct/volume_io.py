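"""Attenuation volumes, label masks, and geometric consistency checks.

The package works on 3-D CT attenuation lattices in Hounsfield units (HU).
A :class:`VolumeGrid` couples the voxel array with its physical geometry
(spacing and origin, millimetres); a :class:`RegionMask` is an integer label
lattice aligned to a grid, with a name→label map for the six lung lobes
(RUL, RML, RLL, LUL, LLi, LLL).

All volumes are held in one canonical axis order internally (the
identity-direction LPS frame ITK uses natively): array index ``[i, j, k]``
advances along +x, +y, +z with ``spacing = (sx, sy, sz)``. Files read
through SimpleITK are reoriented to this convention so that phantoms and
masks can be compared voxelwise.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

HU_MIN = -1024.0
HU_MAX = 3071.0

#: Canonical lobe label map used throughout the package.
LOBE_LABELS = {"RUL": 1, "RML": 2, "RLL": 3, "LUL": 4, "LLi": 5, "LLL": 6}
LOBE_NAMES = {v: k for k, v in LOBE_LABELS.items()}

_SUPPORTED_EXT = (".nii", ".nii.gz", ".mha", ".mhd")


class VolumeIOError(ValueError):
    """Unsupported format, undefined geometry, or missing file."""


class AlignmentError(ValueError):
    """Mask and volume do not share shape/spacing."""


@dataclass
class VolumeGrid:
    """HU voxel lattice with physical spacing and origin (mm), canonical axes."""

    data: np.ndarray                       # float array, index order (x, y, z)
    spacing: tuple[float, float, float]    # mm per voxel along x, y, z
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise VolumeIOError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be positive on all axes, got {self.spacing}")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_MIN - 1e-3 or hi > HU_MAX + 1e-3:
            raise VolumeIOError(
                f"voxel values outside the HU range [{HU_MIN}, {HU_MAX}]: min={lo}, max={hi}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        return np.asarray(idx, dtype=float) * np.asarray(self.spacing) + np.asarray(self.origin)

    def physical_to_index(self, pts_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(pts_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class RegionMask:
    """Integer label lattice aligned to a :class:`VolumeGrid`."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[str, int] = field(default_factory=lambda: dict(LOBE_LABELS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise VolumeIOError("mask labels must be integers")
            self.labels = np.round(self.labels).astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeIOError(f"spacing must be positive, got {self.spacing}")
        declared = set(self.label_map.values()) | {0}
        present = set(np.unique(self.labels).tolist())
        extra = present - declared
        if extra:
            raise VolumeIOError(f"labels {sorted(extra)} not in the declared label map")

    def region_indices(self, region: str) -> np.ndarray:
        """Boolean voxel selector for one named region (whole mask for 'total')."""
        if region == "total":
            return self.labels > 0
        if region not in self.label_map:
            raise KeyError(f"unknown region {region!r}; declared: {sorted(self.label_map)}")
        return self.labels == self.label_map[region]


def validate_alignment(grid: VolumeGrid, mask: RegionMask) -> None:
    """Raise :class:`AlignmentError` unless mask and grid share geometry."""
    if grid.shape != mask.labels.shape:
        raise AlignmentError(f"shape mismatch: volume {grid.shape} vs mask {mask.labels.shape}")
    if not np.allclose(grid.spacing, mask.spacing, atol=1e-6):
        raise AlignmentError(f"spacing mismatch: {grid.spacing} vs {mask.spacing}")


# ---------------------------------------------------------------------------
# File IO (SimpleITK backend, NIfTI-1 and MetaImage)
# ---------------------------------------------------------------------------

def _check_path(path: str) -> None:
    low = str(path).lower()
    if not low.endswith(_SUPPORTED_EXT):
        raise VolumeIOError(f"unsupported format for {path!r}; expected one of {_SUPPORTED_EXT}")


def _to_sitk(data: np.ndarray, spacing, origin) -> sitk.Image:
    # SimpleITK array order is (z, y, x); our canonical order is (x, y, z).
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def _from_sitk(img: sitk.Image):
    # canonical orientation = identity direction matrix (ITK's LPS axes), so
    # writes and reads of phantoms and masks are voxelwise comparable
    img = sitk.DICOMOrient(img, "LPS")
    arr = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    spacing = tuple(float(s) for s in img.GetSpacing())
    if any(s <= 0 for s in spacing):
        raise VolumeIOError(f"file carries non-positive spacing {spacing}")
    origin = tuple(float(o) for o in img.GetOrigin())
    return arr, spacing, origin


def read_volume(path: str) -> VolumeGrid:
    """Read a NIfTI or MetaImage attenuation volume into canonical orientation."""
    _check_path(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return VolumeGrid(arr.astype(np.float32), spacing, origin)


def write_volume(grid: VolumeGrid, path: str) -> None:
    _check_path(path)
    sitk.WriteImage(_to_sitk(grid.data.astype(np.float32), grid.spacing, grid.origin), str(path))


def read_mask(path: str, label_map: dict[str, int] | None = None) -> RegionMask:
    """Read an integer label mask; ``label_map`` defaults to the sidecar JSON or lobes."""
    _check_path(path)
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    if label_map is None:
        sidecar = _sidecar_path(path)
        if os.path.exists(sidecar):
            with open(sidecar) as fh:
                label_map = {k: int(v) for k, v in json.load(fh).items()}
        else:
            label_map = dict(LOBE_LABELS)
    return RegionMask(arr.astype(np.uint8), spacing, origin, label_map)


def write_mask(mask: RegionMask, path: str) -> None:
    _check_path(path)
    sitk.WriteImage(_to_sitk(mask.labels.astype(np.uint8), mask.spacing, mask.origin), str(path))
    with open(_sidecar_path(path), "w") as fh:
        json.dump(mask.label_map, fh, indent=1, sort_keys=True)


def _sidecar_path(path: str) -> str:
    low = str(path)
    for ext in (".nii.gz", ".nii", ".mha", ".mhd"):
        if low.lower().endswith(ext):
            return low[: -len(ext)] + ".labels.json"
    return low + ".labels.json"


# ---------------------------------------------------------------------------
# Breath-hold / lung-volume QC
# ---------------------------------------------------------------------------

def check_volume_consistency(tlv_series_cm3, threshold: float = 0.05) -> dict:
    """Flag consecutive lung-volume pairs that change more than ``threshold``.

    Serial single-breath-hold acquisitions of the same subject should agree in
    total lung volume; the default gate is a 5% relative change, with 10% a
    common permissive alternative.

    Returns a JSON-ready report with pairwise relative changes and flags.
    """
    series = [float(v) for v in tlv_series_cm3]
    if len(series) < 2:
        raise ValueError("need at least two volumes for a consistency check")
    if any(v <= 0 for v in series):
        raise ValueError("lung volumes must be positive")
    pairs = []
    for i in range(len(series) - 1):
        rel = abs(series[i + 1] - series[i]) / series[i]
        pairs.append(
            {
                "pair": [i, i + 1],
                "volumes_cm3": [series[i], series[i + 1]],
                "relative_change": rel,
                "flagged": bool(rel > threshold),
            }
        )
    return {
        "threshold": float(threshold),
        "n_volumes": len(series),
        "pairs": pairs,
        "passed": not any(p["flagged"] for p in pairs),
    }
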