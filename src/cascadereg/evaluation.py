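"""Nine-index registration evaluation over intensity volumes and organ masks.

Intensity indices (on normalized [0, 1] volumes, so the peak value MAXI
defaults to 1):

* RMSE  — root mean squared intensity difference.
* PSNR  — ``10 log10(MAXI^2 / MSE)``; +inf when the volumes are identical.
* SSIM  — the global structural similarity index, computed from the
  whole-volume means, variances and covariance with the usual constants
  ``c_i = (k_i L)^2``, ``k1 = 0.01``, ``k2 = 0.03``, ``L`` the intensity
  range (no sliding window).

Mask indices, per positive label and averaged over labels:

* DICE, IOU, SS (sensitivity), SC (specificity) from the TP/TN/FP/FN
  contingency of the binarized masks.  ``SC`` is standard specificity
  ``TN / (TN + FP)``; ``sc_as_printed=True`` switches to the literal
  variant ``TP / (TN + FP)`` for cross-checking against sources that
  print it that way.
* HD — symmetric Hausdorff distance over the *full* voxel sets, in mm.
* CMD — the same max-of-directed-max distances over the *boundary* voxel
  sets (a boundary voxel is a foreground voxel with at least one
  background face-neighbour); a mean-surface-distance variant is
  available via ``reduction='mean'``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelVolume, Volume

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricReport:
    """All nine indices for one registered case."""

    rmse: float
    psnr: float
    ssim: float
    dice: dict[int, float]
    iou: dict[int, float]
    ss: dict[int, float]
    sc: dict[int, float]
    hd_mm: dict[int, float]
    cmd_mm: dict[int, float]
    label_set: tuple[int, ...]

    def _mean(self, d: dict[int, float]) -> float:
        vals = [v for v in d.values() if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def as_dict(self) -> dict:
        """Flat means over labels, CSV-serializable."""
        return {"RMSE": self.rmse, "PSNR": self.psnr, "SSIM": self.ssim,
                "DICE": self._mean(self.dice), "IOU": self._mean(self.iou),
                "SS": self._mean(self.ss), "SC": self._mean(self.sc),
                "HD (mm)": self._mean(self.hd_mm),
                "CMD (mm)": self._mean(self.cmd_mm)}


def rmse_psnr(fixed: Volume, warped: Volume,
              max_intensity: float = 1.0) -> tuple[float, float]:
    """Root mean squared error and peak signal-to-noise ratio."""
    a, b = fixed.data, warped.data
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    mse = float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))
    rmse = float(np.sqrt(mse))
    psnr = float("inf") if mse == 0 else \
        float(10.0 * np.log10(max_intensity ** 2 / mse))
    return rmse, psnr


def ssim(fixed: Volume, warped: Volume, intensity_range: float = 1.0,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Global (whole-volume) structural similarity index, in [-1, 1]."""
    a = fixed.data.astype(np.float64)
    b = warped.data.astype(np.float64)
    if a.shape != b.shape:
        raise ValueError("volumes must share a grid")
    c1 = (k1 * intensity_range) ** 2
    c2 = (k2 * intensity_range) ** 2
    mu_a, mu_b = a.mean(), b.mean()
    var_a, var_b = a.var(), b.var()
    cov = ((a - mu_a) * (b - mu_b)).mean()
    return float(((2 * mu_a * mu_b + c1) * (2 * cov + c2)) /
                 ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)))


def _label_union(x: LabelVolume, y: LabelVolume) -> list[int]:
    return sorted(set(x.labels().tolist()) | set(y.labels().tolist()))


def overlap_metrics(fixed_labels: LabelVolume, warped_labels: LabelVolume,
                    labels=None, sc_as_printed: bool = False):
    """Per-label DICE / IOU / sensitivity / specificity from TP/TN/FP/FN.

    ``labels`` defaults to the union of labels present in either map.
    A requested label absent from both maps is skipped with a warning; a
    label absent from exactly one map scores 0 overlap.
    """
    if fixed_labels.shape != warped_labels.shape:
        raise ValueError("label maps must share a grid")
    dice, iou, ss, sc = {}, {}, {}, {}
    n_vox = fixed_labels.data.size
    for lab in (labels if labels is not None
                else _label_union(fixed_labels, warped_labels)):
        X = fixed_labels.data == lab
        Y = warped_labels.data == lab
        nx, ny = int(X.sum()), int(Y.sum())
        if nx == 0 and ny == 0:
            warnings.warn(f"label {lab} absent from both volumes; skipped",
                          stacklevel=2)
            continue
        tp = int(np.count_nonzero(X & Y))
        fp = int(np.count_nonzero(~X & Y))
        fn = int(np.count_nonzero(X & ~Y))
        tn = n_vox - tp - fp - fn
        dice[lab] = 2 * tp / (nx + ny)
        iou[lab] = tp / (tp + fn + fp)
        ss[lab] = tp / (tp + fn) if tp + fn else 0.0
        if sc_as_printed:
            sc[lab] = tp / (tn + fp) if tn + fp else 0.0
        else:
            sc[lab] = tn / (tn + fp) if tn + fp else 0.0
    return dice, iou, ss, sc


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground voxels with at least one background face-neighbour.

    Voxels on the volume edge count as boundary (the outside is background).
    """
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT,
                                    border_value=0)
    return mask & ~eroded


def _directed_distances(src: np.ndarray, dst: np.ndarray,
                        spacing) -> np.ndarray:
    """Distance (mm) from every voxel of ``src`` to the nearest of ``dst``."""
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dt[src]


def surface_distances(fixed_labels: LabelVolume, warped_labels: LabelVolume,
                      spacing_mm=None, reduction: str = "max",
                      sc_as_printed: bool = False):
    """Per-label Hausdorff (full voxel sets) and contour distance (mm).

    ``reduction='max'`` gives the symmetric max-of-directed-max form for
    both; ``reduction='mean'`` replaces the directed maxima of the contour
    distance with directed means (average symmetric surface distance
    style).  Empty masks yield NaN ("missing").
    """
    if reduction not in ("max", "mean"):
        raise ValueError("reduction must be 'max' or 'mean'")
    spacing = tuple(spacing_mm) if spacing_mm is not None \
        else fixed_labels.spacing_mm
    hd, cmd = {}, {}
    for lab in _label_union(fixed_labels, warped_labels):
        X = fixed_labels.data == lab
        Y = warped_labels.data == lab
        if not (X.any() and Y.any()):
            hd[lab] = float("nan")
            cmd[lab] = float("nan")
            continue
        dxy = _directed_distances(X, Y, spacing)
        dyx = _directed_distances(Y, X, spacing)
        hd[lab] = float(max(dxy.max(), dyx.max()))
        Xb, Yb = _boundary(X), _boundary(Y)
        bxy = _directed_distances(Xb, Yb, spacing)
        byx = _directed_distances(Yb, Xb, spacing)
        if reduction == "max":
            cmd[lab] = float(max(bxy.max(), byx.max()))
        else:
            cmd[lab] = float(max(bxy.mean(), byx.mean()))
    return hd, cmd


def evaluate_case(fixed: Volume, warped: Volume,
                  fixed_labels: LabelVolume, warped_labels: LabelVolume,
                  max_intensity: float = 1.0,
                  sc_as_printed: bool = False,
                  cmd_reduction: str = "max") -> MetricReport:
    """All nine indices for one case; mask metrics averaged over labels."""
    rmse, psnr = rmse_psnr(fixed, warped, max_intensity)
    s = ssim(fixed, warped, intensity_range=max_intensity)
    dice, iou, ss_, sc = overlap_metrics(fixed_labels, warped_labels,
                                         sc_as_printed=sc_as_printed)
    hd, cmd = surface_distances(fixed_labels, warped_labels,
                                reduction=cmd_reduction)
    labels = tuple(sorted(dice))
    return MetricReport(rmse=rmse, psnr=psnr, ssim=s, dice=dice, iou=iou,
                        ss=ss_, sc=sc, hd_mm=hd, cmd_mm=cmd,
                        label_set=labels)
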