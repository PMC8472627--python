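"""Transformation-field algebra: affine fields, warping, composition and
Jacobian determinants.

A transform is stored as a dense displacement field ``u`` (voxel units on the
fixed grid, component axis first) with point map ``phi(x) = x + u(x)``.
An affine transform is parameterized by its *deviation* ``A`` from the
identity plus an offset ``b``: the full linear map is ``(I + A) x + b``, so
``A = 0, b = 0`` is the identity.  Zero network output therefore means "do
nothing", which also makes the orthogonality/determinant regularizers vanish
at initialization.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .volume_io import Volume, LabelVolume, _affine_from


@dataclass
class AffineParams:
    """Affine deviation matrix ``A`` (3x3) and offset ``b`` (voxel units)."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64).reshape(3, 3)
        self.b = np.asarray(self.b, dtype=np.float64).reshape(3)
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.b))):
            raise ValueError("affine parameters must be finite")

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.zeros((3, 3)), np.zeros(3))

    @property
    def matrix(self) -> np.ndarray:
        """The full linear map ``I + A``."""
        return np.eye(3) + self.A

    def compose(self, inner: "AffineParams") -> "AffineParams":
        """Affine corresponding to applying ``inner`` first, then ``self``.

        phi(x) = M_outer (M_inner x + b_inner) + b_outer.
        """
        M = self.matrix @ inner.matrix
        b = self.matrix @ inner.b + self.b
        return AffineParams(M - np.eye(3), b)


@dataclass
class DisplacementField:
    """Dense displacement field ``u`` of shape (3, D, H, W), voxel units."""

    u: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.float32)
        if self.u.ndim != 4 or self.u.shape[0] != 3:
            raise ValueError(
                f"displacement field must have shape (3, D, H, W), got {self.u.shape}")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape[1:]

    @classmethod
    def zero(cls, grid_shape) -> "DisplacementField":
        return cls(np.zeros((3, *grid_shape), dtype=np.float32))

    def copy(self) -> "DisplacementField":
        return DisplacementField(self.u.copy())


def voxel_grid(grid_shape) -> np.ndarray:
    """Voxel-index coordinates, shape (3, D, H, W), float32."""
    coords = np.indices(grid_shape, dtype=np.float32)
    return coords


def affine_to_field(p: AffineParams, grid_shape) -> DisplacementField:
    """Dense displacement of the affine map: ``u(x) = A x + b`` exactly."""
    x = voxel_grid(grid_shape)
    u = np.einsum("ij,j...->i...", p.A.astype(np.float32), x)
    u += np.asarray(p.b, dtype=np.float32)[:, None, None, None]
    return DisplacementField(u)


# ---------------------------------------------------------------------------
# trilinear / nearest sampling (shared with the autodiff grid-sample op)
# ---------------------------------------------------------------------------

def sample_trilinear(channels: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Sample ``channels`` (C, D, H, W) at continuous points ``phi`` (3, ...).

    Out-of-bounds samples contribute 0 (zero background extension). Exact
    at integer coordinates.
    """
    C = channels.shape[0]
    shape = channels.shape[1:]
    pts = phi.reshape(3, -1)
    f0 = np.floor(pts).astype(np.int64)
    w1 = (pts - f0).astype(np.float32)          # fractional part
    w0 = 1.0 - w1
    out = np.zeros((C, pts.shape[1]), dtype=np.float32)
    flat = channels.reshape(C, -1)
    strides = (shape[1] * shape[2], shape[2], 1)
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz = f0[0] + dz
                iy = f0[1] + dy
                ix = f0[2] + dx
                valid = ((iz >= 0) & (iz < shape[0]) &
                         (iy >= 0) & (iy < shape[1]) &
                         (ix >= 0) & (ix < shape[2]))
                w = ((w1[0] if dz else w0[0]) *
                     (w1[1] if dy else w0[1]) *
                     (w1[2] if dx else w0[2]))
                idx = (np.clip(iz, 0, shape[0] - 1) * strides[0] +
                       np.clip(iy, 0, shape[1] - 1) * strides[1] +
                       np.clip(ix, 0, shape[2] - 1))
                out += np.where(valid, w, 0.0)[None, :] * flat[:, idx]
    return out.reshape((C, *phi.shape[1:]))


def _sample_nearest(channels: np.ndarray, phi: np.ndarray) -> np.ndarray:
    shape = channels.shape[1:]
    pts = np.rint(phi.reshape(3, -1)).astype(np.int64)
    valid = np.ones(pts.shape[1], dtype=bool)
    for ax in range(3):
        valid &= (pts[ax] >= 0) & (pts[ax] < shape[ax])
    idx = (np.clip(pts[0], 0, shape[0] - 1) * shape[1] * shape[2] +
           np.clip(pts[1], 0, shape[1] - 1) * shape[2] +
           np.clip(pts[2], 0, shape[2] - 1))
    out = channels.reshape(channels.shape[0], -1)[:, idx]
    out = np.where(valid[None, :], out, 0)
    return out.reshape((channels.shape[0], *phi.shape[1:]))


def warp(img, f: DisplacementField, mode: str = "trilinear"):
    """Warp an image by a displacement field: ``out(x) = img(x + u(x))``.

    Trilinear interpolation for intensity volumes, nearest-neighbour for
    label maps; samples outside the grid return background (0).
    """
    is_labels = isinstance(img, LabelVolume)
    if is_labels and mode != "nearest":
        raise ValueError("label volumes must be warped with mode='nearest'")
    if img.shape != f.grid_shape:
        raise ValueError(f"image shape {img.shape} != field grid {f.grid_shape}")
    phi = voxel_grid(img.shape) + f.u
    if mode == "nearest":
        out = _sample_nearest(img.data[None].astype(np.float32), phi)[0]
        if is_labels:
            return LabelVolume(np.rint(out).astype(np.int32), img.spacing_mm,
                               img.origin, dict(img.label_names))
        return Volume(out, img.spacing_mm, img.origin)
    if mode != "trilinear":
        raise ValueError(f"unknown warp mode {mode!r}")
    out = sample_trilinear(img.data[None], phi)[0]
    return Volume(out, img.spacing_mm, img.origin)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Field of the composite map ``phi_outer(phi_inner(x))``.

    ``u(x) = u_inner(x) + u_outer(x + u_inner(x))``; the outer displacement is
    resampled trilinearly at the inner target points (zero-extended outside
    the grid).
    """
    if outer.grid_shape != inner.grid_shape:
        raise ValueError("cannot compose fields on different grids")
    phi_inner = voxel_grid(inner.grid_shape) + inner.u
    u_outer_at = sample_trilinear(outer.u, phi_inner)
    return DisplacementField(inner.u + u_outer_at)


def _forward_diff(a: np.ndarray, axis: int) -> np.ndarray:
    """Forward finite difference, one-sided (backward) at the far boundary.

    Exact for fields that are linear in the coordinate, everywhere.
    """
    d = np.empty_like(a)
    sl_lo = [slice(None)] * a.ndim
    sl_hi = [slice(None)] * a.ndim
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    d[tuple(sl_lo)] = a[tuple(sl_hi)] - a[tuple(sl_lo)]
    sl_last = [slice(None)] * a.ndim
    sl_prev = [slice(None)] * a.ndim
    sl_last[axis] = slice(-1, None)
    sl_prev[axis] = slice(-2, -1)
    d[tuple(sl_last)] = a[tuple(sl_last)] - a[tuple(sl_prev)]
    return d


def jacobian_determinant(f: DisplacementField) -> np.ndarray:
    """Pointwise determinant of ``d phi / d x`` via finite differences.

    Identically 1 for the zero field and exactly ``det(I + A)`` for affine
    fields (finite differences are exact for linear maps).
    """
    if min(f.grid_shape) < 2:
        raise ValueError("grid must have at least 2 voxels per axis")
    phi = voxel_grid(f.grid_shape).astype(np.float64) + f.u.astype(np.float64)
    # J[i, ax] = derivative of phi component i along grid axis ax
    J = np.empty((3, 3, *f.grid_shape))
    for i in range(3):
        for ax in range(3):
            J[i, ax] = _forward_diff(phi[i], ax)
    det = (J[0, 0] * (J[1, 1] * J[2, 2] - J[1, 2] * J[2, 1])
           - J[0, 1] * (J[1, 0] * J[2, 2] - J[1, 2] * J[2, 0])
           + J[0, 2] * (J[1, 0] * J[2, 1] - J[1, 1] * J[2, 0]))
    return det


def read_field(path) -> DisplacementField:
    """Read a displacement field from 4D NIfTI (last axis = component)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected a (D, H, W, 3) field, got shape {data.shape}")
    return DisplacementField(np.moveaxis(data, -1, 0).astype(np.float32))


def write_field(f: DisplacementField, path,
                spacing_mm=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    data = np.moveaxis(f.u, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from(spacing_mm, origin))
    nib.save(img, str(path))
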