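"""Preprocessing: volume discarding, motion screening, smoothing, detrending.

Mirrors a conventional resting-state pipeline operating on already-registered
data: drop initial non-steady-state volumes (default 5), exclude subjects
whose head motion exceeds 2 mm translation on any axis or 1 degree rotation
(strict inequality, displacement relative to the first volume), smooth with an
isotropic Gaussian (default 8 mm FWHM), then per-voxel linear detrend and
variance normalization of the masked data matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.signal import detrend as _linear_detrend

from .nifti_io import DataMatrix, VolumeSeries

__all__ = ["MotionTable", "MotionCheck", "load_motion_table",
           "discard_initial_volumes", "check_motion", "smooth_gaussian",
           "detrend_and_standardize"]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_AXES = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class MotionTable:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (deg)."""

    values: np.ndarray            # (n_volumes, 6)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise ValueError("motion table must have 6 columns "
                             "(3 translations mm, 3 rotations deg)")
        if not np.isfinite(self.values).all():
            raise ValueError("motion table contains non-finite values")


@dataclass(frozen=True)
class MotionCheck:
    passed: bool
    offending_axis: str | None = None
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0


def load_motion_table(path, rotations_in_radians: bool = True) -> MotionTable:
    """Read an SPM-style rp_*.txt motion file (whitespace or comma separated).

    SPM writes rotations in radians; they are converted to degrees unless
    ``rotations_in_radians`` is False.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    vals = df.to_numpy(dtype=float)
    if vals.shape[1] != 6:
        raise ValueError(f"expected 6 columns in motion file, got {vals.shape[1]}")
    if rotations_in_radians:
        vals = vals.copy()
        vals[:, 3:] = np.degrees(vals[:, 3:])
    return MotionTable(vals)


def discard_initial_volumes(vs: VolumeSeries, n: int = 5) -> VolumeSeries:
    """Remove the first ``n`` time points (steady-state magnetization)."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= vs.n_volumes:
        raise ValueError(
            f"cannot discard {n} of {vs.n_volumes} volumes")
    if n == 0:
        return vs
    return replace(vs, data=vs.data[..., n:])


def check_motion(mt: MotionTable, trans_limit_mm: float = 2.0,
                 rot_limit_deg: float = 1.0) -> MotionCheck:
    """Apply the motion-exclusion rule.

    A subject fails iff, relative to the first volume, |translation| on any
    axis is strictly greater than ``trans_limit_mm`` or |rotation| on any axis
    strictly greater than ``rot_limit_deg``. A value exactly at a limit passes.
    """
    disp = np.abs(mt.values - mt.values[0])
    max_per_axis = disp.max(axis=0)
    max_t = float(max_per_axis[:3].max())
    max_r = float(max_per_axis[3:].max())
    limits = np.array([trans_limit_mm] * 3 + [rot_limit_deg] * 3)
    over = max_per_axis > limits
    if over.any():
        worst = int(np.argmax(max_per_axis - limits))
        return MotionCheck(False, _AXES[worst], max_t, max_r)
    return MotionCheck(True, None, max_t, max_r)


def smooth_gaussian(vs: VolumeSeries, fwhm_mm: float = 8.0,
                    mask: np.ndarray | None = None) -> VolumeSeries:
    """Isotropic Gaussian smoothing of each volume.

    Sigma per axis is ``fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size``; anisotropic
    voxels therefore get per-axis sigmas. The kernel is truncated at 4 sigma
    with edge-replicating boundary, which preserves a constant image exactly.
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return vs
    sigma_vox = [fwhm_mm / _FWHM_TO_SIGMA / v for v in vs.voxel_size_mm]
    out = np.empty_like(vs.data)
    for t in range(vs.n_volumes):
        out[..., t] = gaussian_filter(vs.data[..., t], sigma=sigma_vox,
                                      mode="nearest", truncate=4.0)
    if mask is not None:
        out = out * np.asarray(mask, dtype=bool)[..., None]
    return replace(vs, data=out)


def detrend_and_standardize(dm: DataMatrix) -> tuple[DataMatrix, np.ndarray]:
    """Per voxel: remove mean and linear trend, then scale to unit variance.

    Voxels with residual standard deviation below 1e-10 are set to zero and
    flagged. Returns the new matrix and the boolean flag vector.
    """
    if dm.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    vals = _linear_detrend(dm.values, axis=0, type="linear")
    sd = vals.std(axis=0, ddof=0)
    degenerate = sd < 1e-10
    sd_safe = np.where(degenerate, 1.0, sd)
    vals = vals / sd_safe
    vals[:, degenerate] = 0.0
    return DataMatrix(values=vals, voxel_index=dm.voxel_index,
                      tr_s=dm.tr_s), degenerate
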