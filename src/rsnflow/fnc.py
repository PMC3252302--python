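"""Functional network connectivity by constrained maximal lagged correlation.

For every unordered pair of selected component time courses the pipeline:

1. cubic-spline interpolates each course from the TR grid onto a 1 s grid (to
   resolve sub-TR hemodynamic delays);
2. band-pass filters to 0.01-0.1 Hz (zero-phase Butterworth, order 5) and
   removes the mean;
3. circularly shifts one course over integer lags in [-5 s, +5 s] — 11 lags on
   the 1 s grid — computes the Pearson correlation at each lag, and keeps the
   coefficient of maximal absolute value together with its signed value and
   lag.

``lag(i, j) > 0`` means component j lags component i; the lag matrix is
antisymmetric and the correlation matrix symmetric by construction. Group
inference runs on Fisher-z transformed values: one-sample t per pair within a
group, pooled two-sample t between groups, both BH-FDR corrected over the
K(K-1)/2 pairs. A subsystem partition classifies each significant edge as
intra- or inter-system and tabulates edges preserved/lost/gained relative to
a reference group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from scipy.signal import butter, filtfilt

from .voxel_stats import fdr_bh

__all__ = [
    "FncResult", "FncGroupResult", "SubsystemPartition",
    "DEFAULT_SUBSYSTEMS", "interpolate_tc", "bandpass", "max_lagged_corr",
    "n_lags", "fnc_subject", "fnc_cohort", "fnc_group_test",
    "fnc_between_groups", "subsystem_summary", "fnc_age_correlation",
]

#: Subsystem partition of the 8 canonical networks (0-based component ids):
#: integration/modulation = {posterior DMN, anterior DMN, self-referential},
#: higher cognition = {left, right frontoparietal/DAN},
#: primary function = {sensorimotor, visual, auditory}.
DEFAULT_SUBSYSTEMS: dict[int, str] = {
    0: "integration_modulation", 1: "integration_modulation",
    3: "integration_modulation",
    4: "higher_cognition", 5: "higher_cognition",
    2: "primary_function", 6: "primary_function", 7: "primary_function",
}


@dataclass
class FncResult:
    """Per-subject maximal lagged correlations and their lags."""

    subjects: list[str]
    r_max: np.ndarray        # (n_subjects, K, K) symmetric, diag NaN
    lag_s: np.ndarray        # (n_subjects, K, K) antisymmetric
    component_ids: list[int]

    @property
    def K(self) -> int:
        return self.r_max.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.K * (self.K - 1) // 2

    def pairs(self) -> list[tuple[int, int]]:
        return list(combinations(range(self.K), 2))

    def pair_values(self) -> np.ndarray:
        """(n_subjects, n_pairs) matrix of r_max in pair order."""
        iu = np.triu_indices(self.K, k=1)
        return self.r_max[:, iu[0], iu[1]]

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        ids = self.component_ids
        for s, sid in enumerate(self.subjects):
            for i, j in self.pairs():
                rows.append({"subject": sid, "i": ids[i], "j": ids[j],
                             "r_max": self.r_max[s, i, j],
                             "lag_s": self.lag_s[s, i, j]})
        return pd.DataFrame(rows)


@dataclass
class FncGroupResult:
    """Per-pair group-level statistics over the K(K-1)/2 combinations."""

    table: pd.DataFrame      # i, j, mean_z, t, p, q, significant
    alpha: float = 0.05

    def significant_pairs(self) -> set[tuple[int, int]]:
        sig = self.table[self.table["significant"]]
        return {(int(r.i), int(r.j)) for r in sig.itertuples()}


@dataclass
class SubsystemPartition:
    """Maps component id -> subsystem label; must cover all components."""

    mapping: dict[int, str] = field(
        default_factory=lambda: dict(DEFAULT_SUBSYSTEMS))

    def label(self, comp: int) -> str:
        if comp not in self.mapping:
            raise KeyError(f"component {comp} has no subsystem label")
        return self.mapping[comp]

    def is_intra(self, i: int, j: int) -> bool:
        return self.label(i) == self.label(j)


# ---------------------------------------------------------------------------
# per-pair machinery
# ---------------------------------------------------------------------------

def interpolate_tc(tc: np.ndarray, tr_s: float,
                   target_dt_s: float = 1.0) -> np.ndarray:
    """Cubic-spline interpolation onto a uniform ``target_dt_s`` grid spanning
    the original duration (endpoints preserved)."""
    x = np.asarray(tc, dtype=float)
    if x.ndim != 1:
        raise ValueError("tc must be 1D")
    if tr_s <= target_dt_s:
        if tr_s < target_dt_s:
            warnings.warn("TR <= target grid spacing; returning input unchanged")
        return x.copy()
    t_orig = np.arange(x.shape[0]) * tr_s
    t_new = np.arange(0.0, t_orig[-1] + 1e-9, target_dt_s)
    return CubicSpline(t_orig, x)(t_new)


def bandpass(tc: np.ndarray, dt_s: float, low_hz: float = 0.01,
             high_hz: float = 0.1, order: int = 5) -> np.ndarray:
    """Zero-phase Butterworth band-pass; output is demeaned."""
    x = np.asarray(tc, dtype=float)
    nyq = 0.5 / dt_s
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(
            f"invalid band [{low_hz}, {high_hz}] Hz for Nyquist {nyq} Hz")
    b, a = butter(order, [low_hz / nyq, high_hz / nyq], btype="band")
    y = filtfilt(b, a, x)
    return y - y.mean()


def n_lags(max_lag_s: float = 5.0, dt_s: float = 1.0) -> int:
    """Number of lagged correlation coefficients evaluated per pair."""
    return 2 * int(np.floor(max_lag_s / dt_s + 1e-9)) + 1


def max_lagged_corr(tc_i: np.ndarray, tc_j: np.ndarray, dt_s: float = 1.0,
                    max_lag_s: float = 5.0) -> tuple[float, float]:
    """Constrained maximal time-lagged Pearson correlation of a pair.

    Evaluates ``corr(tc_i(t), tc_j(t + lag))`` (tc_j circularly shifted) for
    each integer lag on the ``dt_s`` grid in [-max_lag_s, +max_lag_s] and
    returns the coefficient of maximal absolute value with its sign and lag.
    Ties break toward the smallest |lag|, then the negative lag. A positive
    lag means tc_j lags tc_i.
    """
    x = np.asarray(tc_i, dtype=float)
    y = np.asarray(tc_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("time courses must be 1D and of equal length")
    L = int(np.floor(max_lag_s / dt_s + 1e-9))
    if x.shape[0] < 2 * L:
        raise ValueError("time courses too short for the lag window")
    if x.std() < 1e-14 or y.std() < 1e-14:
        raise ValueError("zero-variance time course")
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    n = x.shape[0]
    best_r, best_lag = 0.0, 0.0
    first = True
    # tie-break order: |lag| ascending, negative before positive
    for a in range(0, L + 1):
        for step in ([-a, a] if a else [0]):
            # corr(x(t), y(t + lag)): advance y by `step` samples
            r = float(xz @ np.roll(yz, -step) / n)
            if first or abs(r) > abs(best_r) + 1e-15:
                best_r, best_lag, first = r, step * dt_s, False
    return best_r, best_lag


def fnc_subject(tcs: np.ndarray, tr_s: float, selected: list[int] | None = None,
                target_dt_s: float = 1.0, band: tuple[float, float] = (0.01, 0.1),
                max_lag_s: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs FNC for one subject's (time, K) component time courses.

    Applies interpolate -> bandpass -> max_lagged_corr to every unordered
    pair of the selected components. Returns the symmetric (K, K) r_max
    matrix (diagonal NaN) and the antisymmetric lag matrix.
    """
    tcs = np.asarray(tcs, dtype=float)
    if selected is None:
        selected = list(range(tcs.shape[1]))
    if len(selected) < 2:
        raise ValueError("need at least 2 selected components")
    dt = target_dt_s if tr_s > target_dt_s else tr_s
    prepped = []
    for k in selected:
        z = interpolate_tc(tcs[:, k], tr_s, target_dt_s)
        prepped.append(bandpass(z, dt, *band))
    K = len(selected)
    r = np.full((K, K), np.nan)
    lag = np.zeros((K, K))
    for i, j in combinations(range(K), 2):
        rij, lij = max_lagged_corr(prepped[i], prepped[j], dt, max_lag_s)
        r[i, j] = r[j, i] = rij
        lag[i, j], lag[j, i] = lij, -lij
    return r, lag


def fnc_cohort(subject_tcs: dict[str, np.ndarray], tr_s: float,
               selected: list[int] | None = None, **kwargs) -> FncResult:
    """FNC matrices for every subject; see :func:`fnc_subject`."""
    subjects = list(subject_tcs)
    if not subjects:
        raise ValueError("no subjects")
    first = subject_tcs[subjects[0]]
    sel = selected if selected is not None else list(range(first.shape[1]))
    K = len(sel)
    r = np.empty((len(subjects), K, K))
    lag = np.empty((len(subjects), K, K))
    for s, sid in enumerate(subjects):
        r[s], lag[s] = fnc_subject(subject_tcs[sid], tr_s, sel, **kwargs)
    return FncResult(subjects=subjects, r_max=r, lag_s=lag,
                     component_ids=list(sel))


# ---------------------------------------------------------------------------
# group inference
# ---------------------------------------------------------------------------

_Z_CLIP = np.arctanh(1.0 - 1e-12)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.clip(np.arctanh(np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)),
                   -_Z_CLIP, _Z_CLIP)


def fnc_group_test(fr: FncResult, alpha: float = 0.05,
                   use_fisher_z: bool = True) -> FncGroupResult:
    """One-sample t-test of each pair's (Fisher-z) correlation against zero,
    BH-FDR corrected over the K(K-1)/2 pairs."""
    vals = fr.pair_values()
    if vals.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    z = _fisher_z(vals) if use_fisher_z else vals
    n = z.shape[0]
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    sd[sd < 1e-12] = 1e-12
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    reject, q = fdr_bh(p, alpha)
    ids = fr.component_ids
    rows = [{"i": ids[i], "j": ids[j], "mean_z": mean[k], "t": t[k],
             "p": p[k], "q": q[k], "significant": bool(reject[k])}
            for k, (i, j) in enumerate(fr.pairs())]
    return FncGroupResult(table=pd.DataFrame(rows), alpha=alpha)


def fnc_between_groups(fr_a: FncResult, fr_b: FncResult, alpha: float = 0.05,
                       use_fisher_z: bool = True) -> FncGroupResult:
    """Pooled-variance two-sample t-test per pair on (Fisher-z) values,
    sign = group a - group b, BH-FDR over pairs."""
    if fr_a.component_ids != fr_b.component_ids:
        raise ValueError("groups disagree on component ids")
    za = _fisher_z(fr_a.pair_values()) if use_fisher_z else fr_a.pair_values()
    zb = _fisher_z(fr_b.pair_values()) if use_fisher_z else fr_b.pair_values()
    if za.shape[0] < 2 or zb.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    t, p = stats.ttest_ind(za, zb, axis=0, equal_var=True)
    t = np.where(np.isfinite(t), t, 0.0)
    p = np.where(np.isfinite(p), p, 1.0)
    reject, q = fdr_bh(p, alpha)
    ids = fr_a.component_ids
    rows = [{"i": ids[i], "j": ids[j],
             "mean_z_diff": za[:, k].mean() - zb[:, k].mean(),
             "t": t[k], "p": p[k], "q": q[k], "significant": bool(reject[k])}
            for k, (i, j) in enumerate(fr_a.pairs())]
    return FncGroupResult(table=pd.DataFrame(rows), alpha=alpha)


def subsystem_summary(sig_sets: dict[str, set[tuple[int, int]]],
                      part: SubsystemPartition,
                      reference: str) -> pd.DataFrame:
    """Classify each group's significant edges as intra-/inter-system and
    tabulate preserved/lost/gained counts relative to the reference group.

    ``sig_sets`` maps group label -> set of significant (i, j) pairs.
    """
    if reference not in sig_sets:
        raise KeyError(f"reference group {reference!r} missing")
    ref = {tuple(sorted(p)) for p in sig_sets[reference]}
    rows = []
    for group, pairs in sig_sets.items():
        cur = {tuple(sorted(p)) for p in pairs}
        for kind_name, edge_set in (("preserved", cur & ref),
                                    ("lost", ref - cur),
                                    ("gained", cur - ref)):
            intra = sum(part.is_intra(i, j) for i, j in edge_set)
            rows.append({"group": group, "status": kind_name,
                         "intra": intra, "inter": len(edge_set) - intra,
                         "total": len(edge_set)})
    return pd.DataFrame(rows)


def fnc_age_correlation(fr: FncResult, ages: np.ndarray,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each pair's r_max with subject age, BH-FDR
    corrected over pairs."""
    ages = np.asarray(ages, dtype=float)
    if ages.shape[0] != len(fr.subjects):
        raise ValueError("ages length must match subject count")
    if ages.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(ages).all():
        raise ValueError("ages must be finite")
    if ages.std() < 1e-12:
        raise ValueError("ages are constant; correlation undefined")
    vals = fr.pair_values()
    rs = np.empty(vals.shape[1]); ps = np.empty(vals.shape[1])
    for k in range(vals.shape[1]):
        rs[k], ps[k] = stats.pearsonr(vals[:, k], ages)
    reject, q = fdr_bh(ps, alpha)
    ids = fr.component_ids
    return pd.DataFrame(
        [{"i": ids[i], "j": ids[j], "r": rs[k], "p": ps[k], "q": q[k],
          "significant": bool(reject[k])}
         for k, (i, j) in enumerate(fr.pairs())])
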