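"""Dual regression: back-reconstruct subject time courses and spatial maps.

Stage 1 regresses each subject's data on the group spatial maps (spatial
regressors, demeaned over voxels) to obtain subject-specific component time
courses; stage 2 regresses the data on those time courses (demeaned over
time) to obtain subject-specific spatial maps, which are then z-scored over
in-mask voxels.
"""

from __future__ import annotations

import numpy as np

from .group_ica import ComponentSet, zscore_maps
from .nifti_io import DataMatrix

__all__ = ["stage1_timecourses", "stage2_maps", "dual_regress"]


def _check_full_rank(G: np.ndarray, what: str) -> None:
    """G is a Gram matrix of regressors; raise naming collinear pairs."""
    K = G.shape[0]
    if np.linalg.matrix_rank(G, tol=1e-10 * np.trace(G) / max(K, 1)) < K:
        d = np.sqrt(np.clip(np.diag(G), 1e-30, None))
        C = G / np.outer(d, d)
        pairs = [(i, j) for i in range(K) for j in range(i + 1, K)
                 if abs(C[i, j]) > 1 - 1e-8]
        raise np.linalg.LinAlgError(
            f"rank-deficient {what}; collinear pairs: {pairs or 'degenerate'}")


def stage1_timecourses(dm: DataMatrix | np.ndarray,
                       group_maps: np.ndarray) -> np.ndarray:
    """OLS of each time point's voxel vector on the K group maps.

    Maps are demeaned over voxels before use. Returns (time, K).
    """
    Y = dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, float)
    M = np.asarray(group_maps, dtype=float)
    if Y.shape[1] != M.shape[1]:
        raise ValueError(
            f"voxel counts differ: data {Y.shape[1]}, maps {M.shape[1]}")
    Md = M - M.mean(axis=1, keepdims=True)
    G = Md @ Md.T
    _check_full_rank(G, "group maps")
    return Y @ Md.T @ np.linalg.inv(G)


def stage2_maps(dm: DataMatrix | np.ndarray,
                tc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of each voxel's time series on the K subject time courses.

    Time courses are demeaned over time before use. Returns the raw
    (K, n_voxels) maps and their z-scored version.
    """
    Y = dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, float)
    T = np.asarray(tc, dtype=float)
    if Y.shape[0] != T.shape[0]:
        raise ValueError(
            f"time points differ: data {Y.shape[0]}, time courses {T.shape[0]}")
    Td = T - T.mean(axis=0, keepdims=True)
    G = Td.T @ Td
    _check_full_rank(G, "time courses")
    maps = np.linalg.inv(G) @ Td.T @ Y
    return maps, zscore_maps(maps)


def dual_regress(dm: DataMatrix | np.ndarray, group_maps: np.ndarray,
                 normalize_tc: bool = False) -> ComponentSet:
    """Full dual regression of one subject against the group maps.

    ``normalize_tc`` scales the stage-1 time courses to unit variance before
    stage 2 (off by default). Returns a subject-level ComponentSet with
    z-scored maps.
    """
    tc = stage1_timecourses(dm, group_maps)
    if normalize_tc:
        sd = tc.std(axis=0, keepdims=True)
        sd[sd < 1e-12] = 1.0
        tc = tc / sd
    _, zmaps = stage2_maps(dm, tc)
    return ComponentSet(maps=zmaps, timecourses=tc,
                        K=np.asarray(group_maps).shape[0], level="subject")
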