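"""NIfTI-1 input/output and volume <-> matrix conversion.

A 4D BOLD run is held as a :class:`VolumeSeries`; masked data are held as a
:class:`DataMatrix` whose columns are the in-mask voxels in C-order (row-major)
flatten order of the (x, y, z) grid. That ordering is the single convention
used throughout the package: column ``j`` corresponds to voxel
``voxel_index[j]`` (a 0-based ``(x, y, z)`` triple), and the round trip
volume -> matrix -> volume is the identity on in-mask voxels.

Volumes are assumed co-registered; affines are carried through unchanged and
never used to resample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries", "DataMatrix", "load_series", "save_series",
           "save_map", "to_matrix", "from_matrix", "load_mask", "save_mask"]


@dataclass
class VolumeSeries:
    """One subject's 4D BOLD data plus voxel geometry and TR."""

    data: np.ndarray                      # (x, y, z, t)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.0
    subject_id: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(
                f"VolumeSeries requires 4D data, got {self.data.ndim}D")
        if self.data.shape[3] < 1:
            raise ValueError("VolumeSeries needs at least one time point")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("VolumeSeries data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class DataMatrix:
    """Masked 2D view of a volume series: rows = time, columns = voxels."""

    values: np.ndarray                    # (t, n_voxels)
    voxel_index: np.ndarray               # (n_voxels, 3) int, 0-based
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix values must be 2D (time x voxel)")
        if self.voxel_index.shape != (self.values.shape[1], 3):
            raise ValueError("voxel_index must be (n_voxels, 3)")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


def load_series(path, tr_s: float | None = None,
                subject_id: str = "") -> VolumeSeries:
    """Load a 4D NIfTI-1 file.

    TR is taken from the header ``pixdim[4]``; a positive ``tr_s`` argument
    overrides it (and is required when the header TR is missing or zero).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got {data.ndim}D: {path}")
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite values in {path}")
    zooms = img.header.get_zooms()
    header_tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    tr = float(tr_s) if tr_s is not None else header_tr
    if tr <= 0:
        raise ValueError(
            f"TR not available from header of {path}; pass tr_s explicitly")
    return VolumeSeries(data=data, voxel_size_mm=tuple(float(z) for z in zooms[:3]),
                        tr_s=tr, subject_id=subject_id, affine=img.affine)


def save_series(vs: VolumeSeries, path) -> None:
    """Write a VolumeSeries as 4D NIfTI-1, recording voxel size and TR."""
    img = nib.Nifti1Image(vs.data.astype(np.float32), vs.affine)
    img.header.set_zooms(tuple(vs.voxel_size_mm) + (vs.tr_s,))
    nib.save(img, str(path))


def save_map(map_3d: np.ndarray, path, voxel_size_mm=(3.0, 3.0, 3.0),
             affine: np.ndarray | None = None) -> None:
    """Write a 3D (or component x voxel stacked 4D) map as NIfTI-1."""
    arr = np.asarray(map_3d, dtype=np.float32)
    img = nib.Nifti1Image(arr, np.eye(4) if affine is None else affine)
    img.header.set_zooms(tuple(voxel_size_mm) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    mask = np.asanyarray(img.dataobj)
    if mask.ndim != 3:
        raise ValueError(f"expected a 3D mask, got {mask.ndim}D: {path}")
    return mask > 0


def save_mask(mask: np.ndarray, path, voxel_size_mm=(3.0, 3.0, 3.0)) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4))
    img.header.set_zooms(tuple(voxel_size_mm))
    nib.save(img, str(path))


def to_matrix(vs: VolumeSeries, mask: np.ndarray) -> DataMatrix:
    """Extract in-mask time series: ``values[t, j] = data[voxel_index[j], t]``.

    Columns follow C-order flattening of the mask, i.e. ``np.argwhere(mask)``
    order, which is stable across calls.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vs.shape:
        raise ValueError(
            f"mask shape {mask.shape} != volume spatial shape {vs.shape}")
    values = vs.data[mask].T                     # (t, n_voxels), C-order
    return DataMatrix(values=values, voxel_index=np.argwhere(mask),
                      tr_s=vs.tr_s)


def from_matrix(dm: DataMatrix | np.ndarray, mask: np.ndarray,
                shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Scatter matrix columns back into a volume; out-of-mask voxels are 0.

    Accepts a DataMatrix (returns a 4D ``(x, y, z, t)`` array), a 1D row
    (returns a 3D map) or a 2D ``(t, n_voxels)`` array.
    """
    mask = np.asarray(mask, dtype=bool)
    if shape is not None and tuple(shape) != mask.shape:
        raise ValueError(f"shape {shape} != mask shape {mask.shape}")
    n_in = int(mask.sum())
    values = dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, dtype=float)
    if values.ndim == 1:
        if values.shape[0] != n_in:
            raise ValueError(
                f"column count {values.shape[0]} != mask true-count {n_in}")
        out = np.zeros(mask.shape, dtype=float)
        out[mask] = values
        return out
    if values.shape[1] != n_in:
        raise ValueError(
            f"column count {values.shape[1]} != mask true-count {n_in}")
    out = np.zeros(mask.shape + (values.shape[0],), dtype=float)
    out[mask, :] = values.T
    return out
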