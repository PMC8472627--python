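"""The unsupervised loss stack.

Total objective (coarse-to-fine):

    L_total  = L_coarse + L_fine
    L_coarse = L_sim(I_f, I_m o T_aff) + l1 * L_ortho(A) + l2 * L_det(A)
    L_fine   = L_sim(I_f, I_m o T)     + sum_k [ l3 * L_smooth(T_k)
                                                + l4 * L_topo(T_k) ]

* ``L_sim = 1 - CC`` with CC the global Pearson correlation coefficient —
  suitable for mono-modal volumes.
* ``L_ortho``/``L_det`` keep the coarse affine map close to volume- and
  angle-preserving: with mu_i the singular values of ``I + A``,
  ``L_ortho = -6 + sum(mu_i^2 + mu_i^-2)`` and ``L_det = (det(I+A) - 1)^2``.
* ``L_smooth`` is the L2 variation of the field (mean squared forward
  difference over the three axis directions).
* ``L_topo`` penalizes folding: mean over interior voxels of
  ``max(0, -J)`` where ``J`` is the finite-difference Jacobian determinant
  of ``phi = x + u``.  It is zero exactly when no interior voxel has a
  negative determinant.

Defaults l1 = l2 = 1e-1, l3 = l4 = 1e-5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .deform import AffineParams, DisplacementField, jacobian_determinant
from .volume_io import Volume


@dataclass
class LossWeights:
    """Weights of the four regularization terms."""

    lambda1: float = 1e-1   # orthogonality of the affine map
    lambda2: float = 1e-1   # determinant of the affine map
    lambda3: float = 1e-5   # L2 variation (smoothness) per cascade field
    lambda4: float = 1e-5   # folding penalty per cascade field

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class LossReport:
    """Per-step loss decomposition; ``total = coarse_total + fine_total``."""

    total: float = 0.0
    coarse_total: float = 0.0
    fine_total: float = 0.0
    sim_coarse: float = 0.0
    sim_fine: float = 0.0
    ortho: float = 0.0
    det: float = 0.0
    smooth: float = 0.0
    topo: float = 0.0

    CSV_COLUMNS = ("step", "total", "coarse", "fine", "sim_coarse",
                   "sim_fine", "LR1", "LR2", "LR3", "LR4")

    def row(self, step: int) -> dict:
        return {"step": step, "total": self.total, "coarse": self.coarse_total,
                "fine": self.fine_total, "sim_coarse": self.sim_coarse,
                "sim_fine": self.sim_fine, "LR1": self.ortho, "LR2": self.det,
                "LR3": self.smooth, "LR4": self.topo}


def _as_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume) else np.asarray(v)


def correlation_coefficient(a, b) -> float:
    """Global Pearson correlation of two equally-shaped volumes, in [-1, 1].

    Defined as 0 (with a warning) when either input has zero variance,
    which avoids a division by zero on empty or fully-masked patches.
    """
    x = _as_array(a).astype(np.float64).ravel()
    y = _as_array(b).astype(np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("inputs must have the same shape")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        warnings.warn("correlation undefined on constant input; returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))


def similarity_loss(fixed, warped) -> float:
    """``1 - CC``; 0 for identical non-constant volumes, 2 for negated ones."""
    return 1.0 - correlation_coefficient(fixed, warped)


def orthogonality_loss(p: AffineParams) -> float:
    """``-6 + sum(mu_i^2 + mu_i^-2)`` over singular values of ``I + A``.

    Nonnegative, zero iff all singular values are 1 (i.e. ``I + A`` is
    orthogonal). Grows when the affine map shears or scales.
    """
    M = p.matrix
    mu = np.linalg.svd(M, compute_uv=False)
    if np.any(mu <= 0) or not np.all(np.isfinite(1.0 / mu)):
        raise ValueError("I + A is singular; orthogonality loss undefined")
    return float(-6.0 + np.sum(mu ** 2 + mu ** -2))


def determinant_loss(p: AffineParams) -> float:
    """``(det(I + A) - 1)^2`` — penalizes volume change and reflections."""
    return float((np.linalg.det(p.matrix) - 1.0) ** 2)


def smoothness_loss(f: DisplacementField) -> float:
    """Mean squared forward-difference of the displacement field.

    Average over the three axis directions of the mean (over voxels with a
    valid forward neighbour along that axis) squared vector difference.
    Differences that would leave the grid are omitted.
    """
    if min(f.grid_shape) < 2:
        raise ValueError("grid must have at least 2 voxels per axis")
    u = f.u.astype(np.float64)
    total = 0.0
    for ax in range(3):
        sl_lo = [slice(None)] * 4
        sl_hi = [slice(None)] * 4
        sl_lo[ax + 1] = slice(0, -1)
        sl_hi[ax + 1] = slice(1, None)
        d = u[tuple(sl_hi)] - u[tuple(sl_lo)]
        total += float(np.sum(d * d)) / d[0].size
    return total / 3.0


def topology_loss(f: DisplacementField) -> float:
    """Mean over interior voxels of ``max(0, -J)``.

    Zero iff the finite-difference Jacobian determinant is nonnegative on
    every interior voxel (no folding); for a one-axis reflection (J = -1
    everywhere) the loss is exactly 1.
    """
    J = jacobian_determinant(f)[:-1, :-1, :-1]
    return float(np.mean(np.maximum(0.0, -J)))


def coarse_loss(fixed, warped_affine, p: AffineParams,
                w: LossWeights | None = None) -> dict:
    """Coarse-stage loss: similarity on the affine-warped image plus the
    two affine regularizers."""
    w = w or LossWeights()
    sim = similarity_loss(fixed, warped_affine)
    lr1 = orthogonality_loss(p)
    lr2 = determinant_loss(p)
    total = sim + w.lambda1 * lr1 + w.lambda2 * lr2
    return {"coarse_total": total, "sim_coarse": sim, "ortho": lr1, "det": lr2}


def fine_loss(fixed, final_warped, fields, w: LossWeights | None = None) -> dict:
    """Fine-stage loss: similarity on the final warped image; smoothness and
    folding penalties summed over the cascade fields."""
    w = w or LossWeights()
    if len(fields) < 1:
        raise ValueError("fine_loss requires at least one cascade field")
    sim = similarity_loss(fixed, final_warped)
    lr3 = sum(smoothness_loss(f) for f in fields)
    lr4 = sum(topology_loss(f) for f in fields)
    total = sim + w.lambda3 * lr3 + w.lambda4 * lr4
    return {"fine_total": total, "sim_fine": sim, "smooth": lr3, "topo": lr4}


def total_loss(fixed, warped_affine, p: AffineParams, final_warped, fields,
               w: LossWeights | None = None) -> LossReport:
    """Full decomposition; ``fields`` may be empty (coarse-only model)."""
    w = w or LossWeights()
    c = coarse_loss(fixed, warped_affine, p, w)
    rep = LossReport(**{k: v for k, v in c.items()})
    if fields:
        f = fine_loss(fixed, final_warped, fields, w)
        for k, v in f.items():
            setattr(rep, k, v)
    rep.total = rep.coarse_total + rep.fine_total
    return rep
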