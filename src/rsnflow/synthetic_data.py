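"""Synthetic multi-subject resting-state cohorts with known ground truth.

The generator emulates spatially registered, smoothed BOLD data: K spatially
fixed networks (sums of Gaussian blobs on a 3 mm grid), per-subject network
time courses band-limited to the slow BOLD band (0.01-0.1 Hz at TR = 2 s) with
specified pairwise lagged coupling, i.i.d. Gaussian sensor noise, and two kinds
of planted group effects:

* attenuated within-network voxel loadings (``loading_scale`` < 1), the
  operationalization of reduced functional connectivity within a network;
* severed inter-network couplings (pairs present in the control coupling list
  but absent from a patient group's list), the analogue of lost
  between-network connectivity.

Time courses are synthesized on a 1 s grid — the same grid the FNC stage
interpolates onto — so planted and recovered lags share one convention:
``lag_s > 0`` means the second network of the pair lags the first.
Band-limiting uses a zero-phase Butterworth band-pass (order 5), the same
filter family as the analysis side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .nifti_io import VolumeSeries

__all__ = [
    "NetworkSpec", "CouplingSpec", "CohortSpec", "GroundTruth",
    "make_mask", "make_network_maps", "make_coupled_timecourses",
    "render_subject", "generate_cohort", "default_network_specs",
    "BASELINE_OFFSET", "AGE_RANGE_YEARS",
]

#: Constant added to rendered data so voxel values are positive (removed by
#: detrending downstream).
BASELINE_OFFSET = 100.0

#: Uniform age range (years) for simulated subjects.
AGE_RANGE_YEARS = (8.0, 35.0)

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class NetworkSpec:
    """Spatial layout of one planted network: Gaussian blobs on the grid."""

    network_id: int
    blob_centers: tuple[tuple[int, int, int], ...]
    blob_fwhm_mm: float = 15.0
    loading_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.blob_fwhm_mm <= 0:
            raise ValueError("blob_fwhm_mm must be positive")
        if self.loading_scale <= 0:
            raise ValueError("loading_scale must be positive")


@dataclass(frozen=True)
class CouplingSpec:
    """Planted lagged coupling between a pair of networks.

    ``strength`` is the correlation planted between the two time courses and
    ``lag_s`` the delay of the second network behind the first, in seconds.
    """

    pair: tuple[int, int]
    strength: float
    lag_s: float = 0.0

    def __post_init__(self) -> None:
        i, j = self.pair
        if not i < j:
            raise ValueError(f"coupling pair must have first < second, got {self.pair}")
        if abs(self.strength) > 1:
            raise ValueError(f"|strength| must be <= 1, got {self.strength}")
        if abs(self.lag_s) > 5:
            raise ValueError(f"|lag_s| must be <= 5 s, got {self.lag_s}")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level acquisition parameters for the simulator."""

    n_subjects_per_group: int = 14
    group_labels: tuple[str, ...] = ("control",)
    n_volumes: int = 205
    tr_s: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1:
            raise ValueError("n_subjects_per_group must be positive")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class GroundTruth:
    """True maps, time courses and group effects of a generated cohort."""

    true_maps: np.ndarray                                  # (K, n_voxels)
    true_timecourses: dict[str, np.ndarray]                # subject -> (t, K)
    couplings: dict[str, list[CouplingSpec]]               # group -> list
    loading_scales: dict[str, np.ndarray]                  # group -> (K,)
    mask: np.ndarray = field(default=None)                 # (x, y, z) bool
    network_ids: list[int] = field(default_factory=list)

    def coupled_pairs(self, group: str) -> set[tuple[int, int]]:
        return {c.pair for c in self.couplings[group]}

    def support(self, k: int, rel_threshold: float = 0.5) -> np.ndarray:
        """Voxels where network ``k``'s planted map exceeds ``rel_threshold`` of
        its peak; the default is the blob's half-maximum extent."""
        m = self.true_maps[k]
        return m > rel_threshold * np.abs(m).max()

    def to_json(self, path) -> None:
        obj = {
            "network_ids": list(self.network_ids),
            "couplings": {g: [{"pair": list(c.pair), "strength": c.strength,
                               "lag_s": c.lag_s} for c in cs]
                          for g, cs in self.couplings.items()},
            "loading_scales": {g: list(map(float, s))
                               for g, s in self.loading_scales.items()},
            "true_maps": self.true_maps.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


# ---------------------------------------------------------------------------
# mask and spatial maps
# ---------------------------------------------------------------------------

def make_mask(shape: tuple[int, int, int], radius_vox: float) -> np.ndarray:
    """Ellipsoidal (spherical) analysis mask centred in a voxel grid.

    True where the Euclidean distance from the grid centre is <= radius_vox.
    """
    if radius_vox <= 0:
        raise ValueError("radius_vox must be positive")
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask = dist2 <= radius_vox ** 2
    if not mask.any():
        raise ValueError("mask is empty; increase radius_vox")
    return mask


def make_network_maps(specs: list[NetworkSpec], mask: np.ndarray,
                      voxel_size_mm: float = 3.0) -> np.ndarray:
    """Evaluate each network's Gaussian-blob pattern at in-mask voxels.

    Returns a (K, n_in_mask_voxels) matrix, each row rescaled to unit maximum
    absolute value. Columns follow the package's C-order voxel convention.
    """
    if not specs:
        raise ValueError("need at least one NetworkSpec")
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(float) * voxel_size_mm   # (V, 3) in mm
    maps = np.zeros((len(specs), coords.shape[0]))
    for row, spec in enumerate(specs):
        sigma = spec.blob_fwhm_mm / _FWHM_TO_SIGMA
        for center in spec.blob_centers:
            cv = tuple(int(c) for c in center)
            if not mask[cv]:
                raise ValueError(
                    f"network {spec.network_id}: blob center {cv} is outside the mask")
            d2 = ((coords - np.asarray(cv, dtype=float) * voxel_size_mm) ** 2).sum(axis=1)
            maps[row] += np.exp(-d2 / (2.0 * sigma ** 2))
        maps[row] /= np.abs(maps[row]).max()
    return maps


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def _band_limited_noise(n: int, dt_s: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """Zero-mean unit-variance Gaussian process band-limited by a zero-phase
    Butterworth band-pass of order 5."""
    low, high = band
    nyq = 0.5 / dt_s
    if not 0 < low < high < nyq:
        raise ValueError(f"band {band} invalid for dt {dt_s}s (Nyquist {nyq} Hz)")
    # generate with padding so filter transients do not touch the kept window
    pad = int(round(4.0 / low / dt_s))
    x = rng.standard_normal(n + 2 * pad)
    b, a = butter(5, [low / nyq, high / nyq], btype="band")
    y = filtfilt(b, a, x)[pad:pad + n]
    y = y - y.mean()
    sd = y.std()
    if sd < 1e-12:
        raise ValueError("degenerate band-limited draw")
    return y / sd


def make_coupled_timecourses(cohort: CohortSpec,
                             couplings: list[CouplingSpec],
                             K: int,
                             band: tuple[float, float] = (0.01, 0.1),
                             rng: np.random.Generator | None = None,
                             internal_dt_s: float = 1.0) -> np.ndarray:
    """One subject's (n_volumes, K) network time courses with planted coupling.

    Signals are synthesized on the ``internal_dt_s`` (1 s) grid; for a coupling
    (i, j, rho, delta) the second course is ``rho * tc_i(t - delta)`` (circular
    shift) plus ``sqrt(1 - rho^2)`` of fresh band-limited noise. All courses
    are standardized, then decimated to the TR grid.
    """
    if rng is None:
        rng = np.random.default_rng(cohort.seed)
    step = cohort.tr_s / internal_dt_s
    if abs(step - round(step)) > 1e-9:
        raise ValueError("tr_s must be an integer multiple of internal_dt_s")
    step = int(round(step))
    n_fine = cohort.n_volumes * step

    target: dict[int, CouplingSpec] = {}
    for c in couplings:
        if abs(c.strength) > 1:
            raise ValueError(f"|strength| > 1 in coupling {c.pair}")
        shift = c.lag_s / internal_dt_s
        if abs(shift - round(shift)) > 1e-9:
            raise ValueError(
                f"lag {c.lag_s}s not representable on the {internal_dt_s}s grid")
        if c.pair[1] >= K or c.pair[0] < 0:
            raise ValueError(f"coupling {c.pair} references a network >= K={K}")
        if c.pair[1] in target:
            raise ValueError(f"network {c.pair[1]} is the target of two couplings")
        target[c.pair[1]] = c

    fine = np.zeros((n_fine, K))
    for k in range(K):
        c = target.get(k)
        if c is None:
            fine[:, k] = _band_limited_noise(n_fine, internal_dt_s, band, rng)
            continue
        src = fine[:, c.pair[0]]
        shifted = np.roll(src, int(round(c.lag_s / internal_dt_s)))
        noise = _band_limited_noise(n_fine, internal_dt_s, band, rng)
        y = c.strength * shifted + np.sqrt(1.0 - c.strength ** 2) * noise
        sd = y.std()
        fine[:, k] = (y - y.mean()) / sd if sd > 1e-12 else y
    tc = fine[::step, :][:cohort.n_volumes]
    tc = tc - tc.mean(axis=0)
    sd = tc.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return tc / sd


# ---------------------------------------------------------------------------
# rendering and the full cohort
# ---------------------------------------------------------------------------

def render_subject(maps: np.ndarray, timecourses: np.ndarray,
                   loading_scales: np.ndarray, noise_sd: float,
                   rng: np.random.Generator, mask: np.ndarray,
                   tr_s: float = 2.0, voxel_size_mm: float = 3.0,
                   subject_id: str = "") -> VolumeSeries:
    """Render one subject's 4D volume: ``tc @ diag(scales) @ maps`` inside the
    mask, plus i.i.d. Gaussian noise and a positive baseline offset."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    maps = np.asarray(maps, dtype=float)
    timecourses = np.asarray(timecourses, dtype=float)
    scales = np.asarray(loading_scales, dtype=float)
    if maps.shape[0] != timecourses.shape[1] or scales.shape[0] != maps.shape[0]:
        raise ValueError("maps, timecourses and loading_scales disagree on K")
    signal = (timecourses * scales) @ maps          # (t, V)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    signal = signal + BASELINE_OFFSET
    mask = np.asarray(mask, dtype=bool)
    data = np.zeros(mask.shape + (timecourses.shape[0],))
    data[mask, :] = signal.T
    return VolumeSeries(data=data, voxel_size_mm=(voxel_size_mm,) * 3,
                        tr_s=tr_s, subject_id=subject_id)


def default_network_specs(mask: np.ndarray, K: int = 8,
                          blob_fwhm_mm: float = 15.0,
                          rng: np.random.Generator | None = None
                          ) -> list[NetworkSpec]:
    """K well-separated single-blob networks spread through the mask.

    Centers are picked greedily (farthest-point) from the in-mask voxels so
    networks overlap little, which keeps the planted sources identifiable.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask)
    if rng is None:
        rng = np.random.default_rng(0)
    # start from the voxel nearest the center of mass, then farthest-point
    com = coords.mean(axis=0)
    chosen = [int(np.argmin(((coords - com) ** 2).sum(axis=1)))]
    d2 = ((coords - coords[chosen[0]]) ** 2).sum(axis=1).astype(float)
    while len(chosen) < K:
        nxt = int(np.argmax(d2))
        chosen.append(nxt)
        d2 = np.minimum(d2, ((coords - coords[nxt]) ** 2).sum(axis=1))
    # 0-based network ids, matching component indices everywhere downstream
    return [NetworkSpec(network_id=k,
                        blob_centers=(tuple(int(v) for v in coords[c]),),
                        blob_fwhm_mm=blob_fwhm_mm)
            for k, c in enumerate(chosen)]


def generate_cohort(cohort: CohortSpec,
                    specs: list[NetworkSpec],
                    couplings_by_group: dict[str, list[CouplingSpec]],
                    seed: int | None = None,
                    loading_scales_by_group: dict[str, np.ndarray] | None = None,
                    mask: np.ndarray | None = None,
                    band: tuple[float, float] = (0.01, 0.1),
                    voxel_size_mm: float = 3.0,
                    ) -> tuple[list[VolumeSeries], pd.DataFrame, GroundTruth]:
    """Generate a full multi-group cohort plus metadata and ground truth.

    Group effects: each group's coupling list plants its between-network
    structure; each group's loading-scale vector attenuates (or not) the
    within-network voxel loadings. Ages are drawn uniform over
    ``AGE_RANGE_YEARS``. The same seed yields bit-identical output.
    """
    if seed is None:
        seed = cohort.seed
    for g in cohort.group_labels:
        if g not in couplings_by_group:
            raise KeyError(f"no coupling list for group {g!r}")
    K = len(specs)
    if loading_scales_by_group is None:
        loading_scales_by_group = {
            g: np.array([s.loading_scale for s in specs], dtype=float)
            for g in cohort.group_labels}
    for g in cohort.group_labels:
        if g not in loading_scales_by_group:
            raise KeyError(f"no loading scales for group {g!r}")
    if mask is None:
        mask = make_mask((20, 20, 20), 8.0)
    maps = make_network_maps(specs, mask, voxel_size_mm=voxel_size_mm)

    ss = np.random.SeedSequence(seed)
    meta_rng = np.random.default_rng(ss.spawn(1)[0])
    volumes: list[VolumeSeries] = []
    rows = []
    truth_tcs: dict[str, np.ndarray] = {}
    sub_seqs = ss.spawn(len(cohort.group_labels) * cohort.n_subjects_per_group)
    idx = 0
    for g in cohort.group_labels:
        for s in range(cohort.n_subjects_per_group):
            sid = f"{g}_{s + 1:02d}"
            rng = np.random.default_rng(sub_seqs[idx]); idx += 1
            tc = make_coupled_timecourses(cohort, couplings_by_group[g], K,
                                          band=band, rng=rng)
            vs = render_subject(maps, tc, loading_scales_by_group[g],
                                cohort.noise_sd, rng, mask,
                                tr_s=cohort.tr_s, voxel_size_mm=voxel_size_mm,
                                subject_id=sid)
            volumes.append(vs)
            truth_tcs[sid] = tc
            age = float(meta_rng.uniform(*AGE_RANGE_YEARS))
            rows.append({"subject_id": sid, "group": g, "age": age})
    meta = pd.DataFrame(rows)
    truth = GroundTruth(true_maps=maps, true_timecourses=truth_tcs,
                        couplings={g: list(c) for g, c in couplings_by_group.items()},
                        loading_scales={g: np.asarray(v, dtype=float)
                                        for g, v in loading_scales_by_group.items()},
                        mask=mask,
                        network_ids=[s.network_id for s in specs])
    return volumes, meta, truth
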