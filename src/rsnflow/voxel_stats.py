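"""Voxelwise group statistics on subject z-maps with FDR control.

One-sample t-tests define each group's network extent; two-sample pooled-
variance t-tests compare groups, restricted to a network mask derived from
the control group's one-sample result (positive, FDR-significant voxels).
Multiple testing is controlled by Benjamini-Hochberg FDR over the in-mask
voxels. Tests are two-sided; direction is read from the sign of t
(group1 - group2 for two-sample tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["StatMap", "one_sample_t", "two_sample_t", "fdr_bh",
           "make_network_mask"]


@dataclass
class StatMap:
    """Voxelwise t/p/q arrays over the voxels of ``mask_used``."""

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    df: int
    mask_used: np.ndarray | None = None     # 3D boolean, or None for flat input
    sign_convention: str = "group1 - group2"
    zero_variance: np.ndarray = field(default=None)  # flagged voxels


def fdr_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (reject, q-values).

    ``q_i = min_{j >= i} m p_(j) / j`` on the sorted p-values, mapped back to
    the input order; rejection at level ``alpha``.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return reject.reshape(p.shape), q.reshape(p.shape)


def one_sample_t(maps: np.ndarray, alpha: float = 0.05,
                 mask: np.ndarray | None = None) -> StatMap:
    """Random-effects one-sample t-test per voxel across subjects.

    ``maps`` is (n_subjects, n_voxels). Zero-variance voxels get t = 0,
    p = 1 and are flagged.
    """
    X = np.asarray(maps, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd < 1e-12
    sd_safe = np.where(zero, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(n))
    t[zero] = 0.0
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero] = 1.0
    _, q = fdr_bh(p, alpha)
    return StatMap(t=t, p=p, q=q, df=df, mask_used=mask,
                   sign_convention="mean vs 0", zero_variance=zero)


def two_sample_t(maps_a: np.ndarray, maps_b: np.ndarray,
                 restrict_mask: np.ndarray | None = None,
                 alpha: float = 0.05) -> StatMap:
    """Pooled-variance two-sample t-test per voxel, sign = a - b.

    ``restrict_mask`` is a boolean vector over voxels; the test and the FDR
    correction run only inside it. Outside voxels get t = 0, p = q = 1.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups disagree on voxel count")
    n_vox = A.shape[1]
    if restrict_mask is None:
        idx = np.arange(n_vox)
    else:
        restrict_mask = np.asarray(restrict_mask, dtype=bool).ravel()
        if restrict_mask.shape[0] != n_vox:
            raise ValueError("restrict_mask length mismatch")
        if not restrict_mask.any():
            raise ValueError("restrict_mask is empty")
        idx = np.flatnonzero(restrict_mask)
    na, nb = A.shape[0], B.shape[0]
    df = na + nb - 2
    t_sub, p_sub = stats.ttest_ind(A[:, idx], B[:, idx], axis=0,
                                   equal_var=True)
    zero_sub = ~np.isfinite(t_sub)
    t_sub = np.where(zero_sub, 0.0, t_sub)
    p_sub = np.where(zero_sub, 1.0, p_sub)
    _, q_sub = fdr_bh(p_sub, alpha)
    t = np.zeros(n_vox); p = np.ones(n_vox); q = np.ones(n_vox)
    zero = np.zeros(n_vox, dtype=bool)
    t[idx], p[idx], q[idx], zero[idx] = t_sub, p_sub, q_sub, zero_sub
    return StatMap(t=t, p=p, q=q, df=df, mask_used=restrict_mask,
                   sign_convention="group1 - group2", zero_variance=zero)


def make_network_mask(sm: StatMap, alpha: float = 0.05) -> np.ndarray:
    """Network extent from a one-sample result: q < alpha and t > 0."""
    return (sm.q < alpha) & (sm.t > 0)
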