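"""Volume containers, NIfTI I/O, resampling and intensity normalization.

Conventions used throughout the package:

* 0-based voxel indices; axis order is whatever the canonical NIfTI
  orientation yields on read (we only track spacing and origin, not the
  full orientation matrix).
* Displacement fields are expressed in voxel units on the fixed grid and
  serialized as 4D NIfTI with the displacement component on the last axis.
* Intensities are normalized to [0, 1]; background is 0.
* Physical distances (Hausdorff / contour distances) are derived from
  ``spacing_mm``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (D, H, W)
        Voxel intensities, finite floats.
    spacing_mm : tuple of 3 floats
        Physical voxel size along each axis, in millimetres.
    origin : tuple of 3 floats
        Physical coordinate of voxel (0, 0, 0), in millimetres.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing_mm, self.origin)


@dataclass
class LabelVolume:
    """Integer organ-label map paired with a :class:`Volume`.

    Label 0 is reserved for background; positive labels index organs via
    ``label_names``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LabelVolume data must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label data must be integral")
            self.data = rounded.astype(np.int32)
        else:
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be nonnegative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted array of positive labels present in the map."""
        vals = np.unique(self.data)
        return vals[vals > 0]

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.spacing_mm, self.origin,
                           dict(self.label_names))


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def _load_canonical(path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected a 3D volume, got a {data.ndim}D payload in {path.name}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path) -> Volume:
    """Read a scalar 3D volume from a NIfTI-1 file (.nii / .nii.gz)."""
    data, spacing, origin = _load_canonical(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(v: Volume, path) -> None:
    """Write a :class:`Volume` as NIfTI-1; spacing/origin go into the affine."""
    img = nib.Nifti1Image(v.data.astype(np.float32),
                          _affine_from(v.spacing_mm, v.origin))
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, str(path))


def read_labels(path, label_names: dict[int, str] | None = None) -> LabelVolume:
    """Read an integer label map from NIfTI-1."""
    data, spacing, origin = _load_canonical(path)
    return LabelVolume(np.rint(data).astype(np.int32), spacing, origin,
                       label_names or {})


def write_labels(lv: LabelVolume, path) -> None:
    img = nib.Nifti1Image(lv.data.astype(np.int16),
                          _affine_from(lv.spacing_mm, lv.origin))
    img.header.set_zooms(lv.spacing_mm)
    nib.save(img, str(path))


def resample_to_cube(v, side: int, mode: str = "trilinear"):
    """Resample a volume (or label map) to an isotropic ``side``³ grid.

    The physical extent is preserved: new spacing is
    ``old_spacing * old_shape / side`` per axis. Label maps must use
    ``mode='nearest'`` so no new labels are invented.
    """
    if side < 8:
        raise ValueError("cube side must be >= 8")
    is_labels = isinstance(v, LabelVolume)
    if is_labels and mode != "nearest":
        raise ValueError("label volumes must be resampled with mode='nearest'")
    if mode not in ("trilinear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    shape = np.array(v.shape, dtype=float)
    if tuple(v.shape) == (side, side, side):
        return v.copy()
    zoom = side / shape
    order = 0 if mode == "nearest" else 1
    out = ndimage.zoom(v.data.astype(np.float32), zoom, order=order,
                       mode="nearest", grid_mode=True, prefilter=False)
    # grid_mode=True aligns voxel edges, matching extent-preserving semantics
    new_spacing = tuple(float(s * n / side) for s, n in zip(v.spacing_mm, shape))
    if is_labels:
        return LabelVolume(np.rint(out).astype(np.int32), new_spacing, v.origin,
                           dict(v.label_names))
    return Volume(out, new_spacing, v.origin)


def normalize_intensity(v: Volume, lo_clip: float = 0.0,
                        hi_clip: float = 1.0) -> Volume:
    """Clip to [lo_clip, hi_clip] and rescale affinely to [0, 1].

    A constant input maps to the all-zero volume (documented behaviour,
    not an error): there is no contrast to preserve.
    """
    if not lo_clip < hi_clip:
        raise ValueError("lo_clip must be < hi_clip")
    d = np.clip(v.data, lo_clip, hi_clip)
    dmin, dmax = float(d.min()), float(d.max())
    if dmax == dmin:
        return Volume(np.zeros_like(d), v.spacing_mm, v.origin)
    out = (d - lo_clip) / (hi_clip - lo_clip)
    return Volume(out.astype(np.float32), v.spacing_mm, v.origin)


def mask_to_roi(v: Volume, labels: LabelVolume) -> Volume:
    """Zero every voxel whose label is background.

    Registration in this package acts on ROI-masked intensity volumes: the
    multi-organ mask defines the region of interest and everything outside
    it is treated as background air (intensity 0).
    """
    if v.shape != labels.shape:
        raise ValueError(
            f"volume shape {v.shape} does not match label shape {labels.shape}")
    out = np.where(labels.data > 0, v.data, 0.0).astype(np.float32)
    return Volume(out, v.spacing_mm, v.origin)
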