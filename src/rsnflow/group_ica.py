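"""Group spatial ICA: two-stage PCA reduction, MDL order selection, infomax.

The decomposition follows the GIFT-style group ICA recipe for multi-subject
resting-state fMRI:

1. each subject's (time x voxel) matrix is reduced by temporal PCA to ``p1``
   dimensions;
2. the reduced matrices are concatenated along the (reduced) temporal axis and
   reduced again to ``K`` dimensions;
3. ``K`` spatially independent components are estimated from the group-reduced
   data by natural-gradient infomax ICA with a logistic nonlinearity, which
   favors the super-Gaussian (sparse, positive-tailed) spatial sources typical
   of resting-state networks.

The model order ``K`` may be chosen by the minimum description length (MDL)
criterion on the temporal covariance eigen-spectrum (Wax-Kailath form), or
fixed by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import skew

from .nifti_io import DataMatrix

__all__ = ["PcaReduction", "ComponentSet", "estimate_order_mdl",
           "reduce_subject", "reduce_group", "whiten", "infomax",
           "zscore_maps", "amari_distance"]


@dataclass
class PcaReduction:
    """Temporal PCA reduction of a (time x voxel) matrix."""

    basis: np.ndarray          # (t, p) orthonormal columns
    eigenvalues: np.ndarray    # (p,) descending
    reduced_data: np.ndarray   # (p, n_voxels)
    level: str = "subject"     # "subject" | "group"


@dataclass
class ComponentSet:
    """K spatial maps (z-scored over in-mask voxels) and their time courses."""

    maps: np.ndarray           # (K, n_voxels)
    timecourses: np.ndarray    # (time-or-reduced-dims, K)
    K: int
    level: str = "group"       # "group" | "subject"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.maps.shape[0] != self.K or self.timecourses.shape[1] != self.K:
            raise ValueError("maps/timecourses inconsistent with K")


def zscore_maps(maps: np.ndarray) -> np.ndarray:
    """Standardize each map to zero mean, unit variance over in-mask voxels."""
    maps = np.asarray(maps, dtype=float)
    mu = maps.mean(axis=1, keepdims=True)
    sd = maps.std(axis=1, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return (maps - mu) / sd


# ---------------------------------------------------------------------------
# model order
# ---------------------------------------------------------------------------

def estimate_order_mdl(dm: DataMatrix | np.ndarray) -> int:
    """MDL (Wax-Kailath) estimate of the number of signal components.

    Treats voxels as samples (N) and time points as dimensions (p):
    ``MDL(k) = -N (p - k) ln(g_k / a_k) + 0.5 k (2p - k) ln N`` with ``g_k``
    and ``a_k`` the geometric and arithmetic means of the ``p - k`` smallest
    eigenvalues of the temporal covariance. Returns the minimizing k in
    [1, p - 1].
    """
    X = dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, dtype=float)
    t, n_vox = X.shape
    if t < 3:
        raise ValueError("need at least 3 time points")
    if n_vox < t:
        raise ValueError("need at least as many voxels as time points")
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / n_vox
    lam = np.linalg.eigvalsh(cov)[::-1]
    lam = np.clip(lam, 1e-15, None)
    if lam[0] / lam[-1] < 1 + 1e-9:
        warnings.warn("degenerate covariance: all eigenvalues equal; returning 1")
        return 1
    p, N = t, n_vox
    log_lam = np.log(lam)
    # suffix means over the p-k smallest eigenvalues
    ks = np.arange(1, p)
    mdl = np.empty(p - 1)
    for i, k in enumerate(ks):
        tail = lam[k:]
        log_g = log_lam[k:].mean()
        a = tail.mean()
        mdl[i] = -N * (p - k) * (log_g - np.log(a)) \
            + 0.5 * k * (2 * p - k) * np.log(N)
    return int(ks[np.argmin(mdl)])


# ---------------------------------------------------------------------------
# two-stage PCA
# ---------------------------------------------------------------------------

def _temporal_pca(X: np.ndarray, p_keep: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the (rows x rows) covariance, top ``p_keep``."""
    cov = X @ X.T / X.shape[1]
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    return vec[:, :p_keep], np.clip(lam, 0.0, None)


def reduce_subject(dm: DataMatrix | np.ndarray, p1: int) -> PcaReduction:
    """First-stage (subject-level) temporal PCA to ``p1`` dimensions."""
    X = dm.values if isinstance(dm, DataMatrix) else np.asarray(dm, dtype=float)
    if p1 > X.shape[0]:
        raise ValueError(f"p1={p1} exceeds number of time points {X.shape[0]}")
    if p1 < 1:
        raise ValueError("p1 must be >= 1")
    basis, lam = _temporal_pca(X, p1)
    return PcaReduction(basis=basis, eigenvalues=lam,
                        reduced_data=basis.T @ X, level="subject")


def reduce_group(reductions: list[PcaReduction], K: int) -> PcaReduction:
    """Second-stage PCA on the temporally concatenated subject reductions."""
    if not reductions:
        raise ValueError("need at least one subject reduction")
    n_vox = reductions[0].reduced_data.shape[1]
    for r in reductions:
        if r.reduced_data.shape[1] != n_vox:
            raise ValueError("subjects disagree on voxel count")
    X = np.vstack([r.reduced_data for r in reductions])
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds concatenated dimensions {X.shape[0]}")
    basis, lam = _temporal_pca(X, K)
    return PcaReduction(basis=basis, eigenvalues=lam,
                        reduced_data=basis.T @ X, level="group")


# ---------------------------------------------------------------------------
# infomax ICA
# ---------------------------------------------------------------------------

def whiten(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whiten rows of X: returns (X_white, sphering, unsphering) with
    ``X_white = sphering @ X`` and identity covariance."""
    cov = X @ X.T / X.shape[1]
    lam, vec = np.linalg.eigh(cov)
    lam = np.clip(lam, 1e-12, None)
    sph = (vec / np.sqrt(lam)) @ vec.T
    unsph = (vec * np.sqrt(lam)) @ vec.T
    return sph @ X, sph, unsph


def _infomax_run(Xw: np.ndarray, W0: np.ndarray, lr: float, max_iter: int,
                 tol: float, batch_size: int,
                 rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """One annealed natural-gradient pass from initial weights ``W0``."""
    K, n = Xw.shape
    eye = np.eye(K)
    W = W0.copy()
    prev_delta = None
    for _ in range(max_iter):
        W_old = W.copy()
        perm = rng.permutation(n)
        for start in range(0, n, batch_size):
            xb = Xw[:, perm[start:start + batch_size]]
            u = W @ xb
            y = 1.0 / (1.0 + np.exp(-np.clip(u, -500, 500)))
            W = W + lr * (eye + (1.0 - 2.0 * y) @ u.T / xb.shape[1]) @ W
            if not np.isfinite(W).all() or np.linalg.norm(W) > 1e8:
                return W, True
        delta = W - W_old
        dnorm = np.linalg.norm(delta)
        if prev_delta is not None:
            denom = np.linalg.norm(prev_delta) * dnorm
            if denom > 0 and np.sum(prev_delta * delta) / denom < 0.5:
                lr *= 0.9                     # angle > 60 degrees
        prev_delta = delta
        if dnorm < tol:
            break
    return W, False


def _logistic_loglik(W: np.ndarray, Xw: np.ndarray) -> float:
    """Per-sample infomax objective: E[log y(1-y)] + log|det W|."""
    u = np.clip(W @ Xw, -500, 500)
    y = 1.0 / (1.0 + np.exp(-u))
    return float(np.log(y * (1.0 - y) + 1e-300).sum() / Xw.shape[1]
                 + np.linalg.slogdet(W)[1])


def infomax(reduced: PcaReduction | np.ndarray, lr0: float | None = None,
            max_iter: int = 512, tol: float = 1e-7, seed: int = 0,
            batch_size: int | None = None, n_init: int = 3,
            ) -> tuple[np.ndarray, ComponentSet]:
    """Natural-gradient infomax ICA with logistic nonlinearity.

    The update over a mini-batch of whitened columns ``x`` is
    ``dW = lr (I + (1 - 2y) u^T / n) W`` with ``u = W x`` and
    ``y = 1/(1 + e^-u)``. The learning rate anneals by 0.9 whenever the angle
    between successive epoch weight changes exceeds 60 degrees; iteration
    stops when the epoch weight-change norm falls below ``tol``. On
    divergence (``||W|| > 1e8``) a run restarts at half the learning rate,
    at most 3 times.

    The objective is not convex: ``n_init`` runs are performed (identity
    init, then random orthogonal inits) and the one with the highest
    per-sample log-likelihood is kept, which makes the estimate robust to
    the occasional trapped basin. All randomness derives from ``seed``.

    Returns the unmixing matrix (acting on the whitened data) and a group
    ComponentSet: maps are z-scored sources with positive skewness; the
    timecourses field holds the mixing of the sources back into the reduced
    temporal dimensions.
    """
    X = reduced.reduced_data if isinstance(reduced, PcaReduction) else np.asarray(reduced, float)
    K, n = X.shape
    Xw, sph, unsph = whiten(X)
    if lr0 is None:
        lr0 = 0.01 / np.log(K) if K >= 2 else 0.01
    if batch_size is None:
        # small batches give many natural-gradient steps per pass; large
        # batches stall the stochastic search long before max_iter
        batch_size = min(n, 128)

    init_rng = np.random.default_rng(seed)
    inits = [np.eye(K)]
    inits += [np.linalg.qr(init_rng.normal(size=(K, K)))[0]
              for _ in range(max(0, n_init - 1))]

    best_W, best_ll = None, -np.inf
    for i, W0 in enumerate(inits):
        for restart in range(4):
            rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
            W, diverged = _infomax_run(Xw, W0, lr0 / (2 ** restart),
                                       max_iter, tol, batch_size, rng)
            if not diverged:
                break
        else:
            raise RuntimeError("infomax diverged after 3 restarts")
        ll = _logistic_loglik(W, Xw)
        if ll > best_ll:
            best_W, best_ll = W, ll
    W = best_W

    sources = W @ Xw                                       # (K, n_voxels)
    # sign convention: activation blobs are positive-tailed
    signs = np.where(skew(sources, axis=1) < 0, -1.0, 1.0)
    W = W * signs[:, None]
    sources = sources * signs[:, None]
    # mixing from sources back to the reduced temporal dimensions
    mixing = unsph @ np.linalg.inv(W)                      # (K_reduced, K)
    return W, ComponentSet(maps=zscore_maps(sources), timecourses=mixing,
                           K=K, level="group")


def amari_distance(W: np.ndarray, A: np.ndarray) -> float:
    """Amari permutation-invariant distance between an unmixing W and a
    mixing A; 0 iff ``W @ A`` is a scaled permutation."""
    P = np.abs(W @ A)
    m = P.shape[0]
    term1 = (P.sum(axis=1) / P.max(axis=1) - 1).sum()
    term2 = (P.sum(axis=0) / P.max(axis=0) - 1).sum()
    return float((term1 + term2) / (2 * m * (m - 1)))
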