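"""Quantitative-map handling: R2* fitting, smoothing, masks and ROI averages.

R2* is estimated voxel-wise by ordinary least squares of log signal
intensity on echo time (the slope is -R2*).  Maps are smoothed with a
3 mm FWHM Gaussian kernel, tissue masks are thresholded probability
volumes (grey matter > 0.2, white matter > 0.8, strict inequality), and
ROI values are arithmetic means over the GM-masked ROI voxels.  The
pipeline order is fixed: smooth, then mask, then average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...


class QMRIError(ValueError):
    pass


class EmptyROIError(QMRIError):
    pass


@dataclass
class QuantitativeMap:
    """A 3-D quantitative volume with its voxel-to-world (RAS mm) affine."""

    values: np.ndarray
    map_type: str
    affine: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        self.affine = np.asarray(self.affine, float)
        if self.values.ndim != 3:
            raise QMRIError("map values must be a 3-D array")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise QMRIError("affine must be an invertible 4x4 matrix")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img_or_path, map_type: str) -> "QuantitativeMap":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) else nib.load(img_or_path)
        return cls(np.asarray(img.dataobj, float), map_type, img.affine)

    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class ROIDefinition:
    """A named ROI: either an atlas label id or a sphere in world mm."""

    label: str
    atlas_label: int | None = None
    centre_mm: np.ndarray | None = None
    radius_mm: float = 5.0

    def __post_init__(self):
        if (self.atlas_label is None) == (self.centre_mm is None):
            raise QMRIError("define the ROI by exactly one of atlas label or sphere")
        if self.centre_mm is not None:
            self.centre_mm = np.asarray(self.centre_mm, float)
            if self.radius_mm <= 0:
                raise QMRIError("sphere radius must be positive")


def fit_r2star(signals: np.ndarray, echo_times_s: np.ndarray):
    """Voxel-wise log-linear R2* estimation.

    Parameters
    ----------
    signals : (n_echoes, n_voxels) array
        Multi-echo magnitudes; non-positive samples flag the voxel invalid.
    echo_times_s : (n_echoes,) increasing echo times in seconds.

    Returns
    -------
    r2star : (n_voxels,) R2* in 1/s (NaN where invalid).
    log_amplitude : (n_voxels,) OLS intercept, log signal at TE = 0.
    valid : (n_voxels,) boolean mask of voxels with all-positive signal.
    """
    signals = np.atleast_2d(np.asarray(signals, float))
    te = np.asarray(echo_times_s, float)
    if te.size < 3:
        raise QMRIError("need at least 3 echoes")
    if np.any(np.diff(te) <= 0):
        raise QMRIError("echo times must be strictly increasing")
    if signals.shape[0] != te.size:
        raise QMRIError("signals first axis must match the echo grid")
    valid = np.all(signals > 0, axis=0)
    n_vox = signals.shape[1]
    r2s = np.full(n_vox, np.nan)
    amp = np.full(n_vox, np.nan)
    if valid.any():
        logs = np.log(signals[:, valid])
        tc = te - te.mean()
        slope = tc @ (logs - logs.mean(axis=0)) / (tc @ tc)
        intercept = logs.mean(axis=0) - slope * te.mean()
        r2s[valid] = -slope
        amp[valid] = intercept
    return r2s, amp, valid


def smooth_map(qmap: QuantitativeMap, fwhm_mm: float = 3.0) -> QuantitativeMap:
    """Separable Gaussian smoothing with the kernel width given as FWHM in mm."""
    if fwhm_mm < 0:
        raise QMRIError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return QuantitativeMap(qmap.values.copy(), qmap.map_type, qmap.affine)
    R = qmap.affine[:3, :3]
    scales = np.linalg.norm(R, axis=0)
    # separable smoothing needs voxel axes aligned with world axes
    if not np.allclose(R - np.diag(np.diag(R)), 0, atol=1e-6 * scales.max()):
        raise QMRIError("sheared or oblique affines are not supported for smoothing")
    sigma_vox = (fwhm_mm / FWHM_TO_SD) / scales
    out = ndimage.gaussian_filter(qmap.values, sigma=sigma_vox, mode="nearest")
    return QuantitativeMap(out, qmap.map_type, qmap.affine)


def make_tissue_mask(prob_map: QuantitativeMap, mode: str, threshold: float | None = None):
    """Binary tissue mask by strict thresholding of a probability volume.

    mode 'GM' uses prob > 0.2, mode 'WM' prob > 0.8 unless a threshold
    is given explicitly.
    """
    vals = prob_map.values
    if vals.min() < 0 or vals.max() > 1:
        raise QMRIError("probability map must lie in [0, 1]")
    if threshold is None:
        threshold = {"GM": 0.2, "WM": 0.8}.get(mode.upper())
        if threshold is None:
            raise QMRIError("mode must be 'GM' or 'WM' when no threshold is given")
    if not 0 < threshold < 1:
        raise QMRIError("threshold must be in (0, 1)")
    mask = vals > threshold
    if not mask.any():
        warnings.warn(f"{mode} mask at threshold {threshold} is empty")
    return mask


def _world_coordinates(shape, affine):
    idx = np.indices(shape).reshape(3, -1)
    hom = np.vstack([idx, np.ones(idx.shape[1])])
    return (affine @ hom)[:3]  # 3 x n_voxels, world mm


def roi_mask(roi: ROIDefinition, shape, affine, atlas: np.ndarray | None = None) -> np.ndarray:
    """Binary voxel mask of an ROI (voxel-centre containment for spheres)."""
    if roi.atlas_label is not None:
        if atlas is None:
            raise QMRIError(f"ROI {roi.label} needs an atlas volume")
        if roi.atlas_label not in np.unique(atlas):
            raise QMRIError(f"label {roi.atlas_label} absent from atlas")
        return np.asarray(atlas) == roi.atlas_label
    world = _world_coordinates(shape, np.asarray(affine, float))
    d2 = np.sum((world - roi.centre_mm[:, None]) ** 2, axis=0)
    return (d2 <= roi.radius_mm**2).reshape(shape)


def roi_mean(qmap: QuantitativeMap, roi_vox: np.ndarray, gm_mask: np.ndarray,
             roi_label: str = "") -> float:
    """Arithmetic mean of the map over the GM-masked ROI voxels."""
    if roi_vox.shape != qmap.values.shape or gm_mask.shape != qmap.values.shape:
        raise QMRIError("masks must share the map grid")
    sel = roi_vox & gm_mask
    if not sel.any():
        raise EmptyROIError(
            f"ROI {roi_label or '<unnamed>'} has no voxels inside the grey-matter mask"
        )
    return float(qmap.values[sel].mean())


def extract_roi_table(
    maps: dict[str, QuantitativeMap],
    gm_prob: QuantitativeMap,
    rois: list[ROIDefinition],
    atlas: np.ndarray | None = None,
    fwhm_mm: float = 3.0,
):
    """Smooth each map, GM-mask, and average over every ROI.

    Returns a dict ``(map_type, roi_label) -> mean`` following the fixed
    smooth -> mask -> average order.
    """
    gm = make_tissue_mask(gm_prob, "GM")
    shape, affine = gm_prob.values.shape, gm_prob.affine
    masks = {roi.label: roi_mask(roi, shape, affine, atlas) for roi in rois}
    out = {}
    for mtype, qmap in maps.items():
        sm = smooth_map(qmap, fwhm_mm)
        for roi in rois:
            out[(mtype, roi.label)] = roi_mean(sm, masks[roi.label], gm, roi.label)
    return out
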