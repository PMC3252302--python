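"""End-to-end orchestration: simulate -> preprocess -> group ICA -> dual
regression -> component selection -> voxelwise stats -> FNC -> subsystem
report, driven by one validated configuration, with a hashed output manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from . import component_select, dual_regression, fnc, group_ica, nifti_io, \
    preprocess, synthetic_data, voxel_stats

log = logging.getLogger("rsnflow")

__all__ = ["RunConfig", "run_pipeline", "simulate_demo_cohort", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration; serialized verbatim into the run dir."""

    out_dir: str = "rsnflow_run"
    seed: int = 0
    tr_s: float = 2.0
    discard_n: int = 5
    smooth_fwhm_mm: float = 8.0
    n_components: int | str = 8          # integer K or "mdl"
    selection_cutoff_hz: float = 0.1
    selection_max_fraction: float = 0.5
    lag_window_s: float = 5.0
    band_hz: tuple[float, float] = (0.01, 0.1)
    alpha: float = 0.05
    # simulation (used when subject_paths is empty)
    simulate: bool = True
    n_subjects_per_group: int = 4
    group_labels: tuple[str, ...] = ("control", "patient_a", "patient_b")
    n_volumes: int = 205
    noise_sd: float = 1.0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    mask_radius_vox: float = 8.0
    # inputs (used when simulate is False)
    subject_paths: dict[str, str] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)
    mask_path: str | None = None
    motion_paths: dict[str, str] = field(default_factory=dict)
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 1.0
    subsystem_partition: dict[int, str] | None = None
    reference_group: str = "control"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.discard_n < 0:
            raise ValueError("discard_n must be nonnegative")
        if isinstance(self.n_components, str) and self.n_components != "mdl":
            raise ValueError("n_components must be an integer or 'mdl'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        low, high = self.band_hz
        if not 0 < low < high:
            raise ValueError("band_hz must satisfy 0 < low < high")
        if not self.simulate and not self.subject_paths:
            raise ValueError("either simulate=True or subject_paths required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_demo_cohort(cfg: RunConfig, K: int = 8):
    """Bundled demo cohort: K planted networks, control couplings spanning
    both intra- and inter-system edges; patient groups lose designated
    inter-system couplings and have attenuated loadings on some networks."""
    mask = synthetic_data.make_mask(cfg.grid_shape, cfg.mask_radius_vox)
    specs = synthetic_data.default_network_specs(mask, K=K)
    part = fnc.SubsystemPartition(cfg.subsystem_partition or dict(fnc.DEFAULT_SUBSYSTEMS))
    # control: couple within subsystems and across them (no network is the
    # target of two couplings; lags on the 1 s grid)
    control = [
        synthetic_data.CouplingSpec((0, 1), 0.55, 1.0),    # intra
        synthetic_data.CouplingSpec((0, 3), 0.50, -2.0),   # intra
        synthetic_data.CouplingSpec((4, 5), 0.55, 0.0),    # intra
        synthetic_data.CouplingSpec((2, 6), 0.50, 2.0),    # intra
        synthetic_data.CouplingSpec((2, 7), 0.50, 1.0),    # intra
        synthetic_data.CouplingSpec((1, 4), 0.50, 3.0),    # inter
    ]
    severed_a = {(1, 4)}
    couplings = {}
    scales = {}
    for g in cfg.group_labels:
        if g == cfg.reference_group:
            couplings[g] = control
            scales[g] = np.ones(K)
        else:
            couplings[g] = [c for c in control if c.pair not in severed_a]
            s = np.ones(K)
            s[:K // 2] = 0.6                  # attenuated within-network loading
            scales[g] = s
    cohort = synthetic_data.CohortSpec(
        n_subjects_per_group=cfg.n_subjects_per_group,
        group_labels=tuple(cfg.group_labels), n_volumes=cfg.n_volumes,
        tr_s=cfg.tr_s, noise_sd=cfg.noise_sd, seed=cfg.seed)
    volumes, meta, truth = synthetic_data.generate_cohort(
        cohort, specs, couplings, seed=cfg.seed,
        loading_scales_by_group=scales, mask=mask, band=cfg.band_hz)
    return volumes, meta, truth, mask, part


def _cluster_table(sig: np.ndarray, t_map: np.ndarray,
                   mask: np.ndarray) -> pd.DataFrame:
    """Connected-component clusters of significant voxels with peak stats."""
    vol_sig = nifti_io.from_matrix(sig.astype(float), mask) > 0
    vol_t = nifti_io.from_matrix(t_map, mask)
    labels, n = ndimage.label(vol_sig)
    rows = []
    for lab in range(1, n + 1):
        where = labels == lab
        tvals = np.where(where, vol_t, 0.0)
        peak = np.unravel_index(np.argmax(np.abs(tvals)), tvals.shape)
        rows.append({"cluster": lab, "size_vox": int(where.sum()),
                     "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2],
                     "peak_t": float(vol_t[peak])})
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order; returns the manifest dictionary.

    Any stage failure raises :class:`PipelineError` naming the stage, after
    writing the partial manifest.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.__dict__ | {
        "group_labels": list(cfg.group_labels),
        "band_hz": list(cfg.band_hz), "grid_shape": list(cfg.grid_shape)},
        "files": {}, "stages": []}

    def record(path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    def save_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(manifest["config"], fh)
    record(out / "config.yaml")

    stage = "simulate"
    try:
        # ------------------------------------------------------------ inputs
        if cfg.simulate:
            volumes, meta, truth, mask, part = simulate_demo_cohort(
                cfg, K=cfg.n_components if isinstance(cfg.n_components, int) else 8)
            nifti_io.save_mask(mask, out / "mask.nii.gz")
            record(out / "mask.nii.gz")
            meta.to_csv(out / "metadata.csv", index=False)
            record(out / "metadata.csv")
            truth.to_json(out / "ground_truth.json")
            record(out / "ground_truth.json")
            for vs in volumes:
                p = out / f"sub-{vs.subject_id}_bold.nii.gz"
                nifti_io.save_series(vs, p)
                record(p)
            groups = dict(zip(meta["subject_id"], meta["group"]))
        else:
            stage = "load"
            mask = nifti_io.load_mask(cfg.mask_path)
            part = fnc.SubsystemPartition(
                cfg.subsystem_partition or dict(fnc.DEFAULT_SUBSYSTEMS))
            volumes = []
            for sid, paths in cfg.subject_paths.items():
                # a subject may have several runs; they are concatenated
                # temporally after per-run detrending
                for path in ([paths] if isinstance(paths, str) else paths):
                    if not Path(path).exists():
                        raise FileNotFoundError(f"subject {sid}: missing {path}")
                    volumes.append(nifti_io.load_series(path, tr_s=cfg.tr_s,
                                                        subject_id=sid))
            groups = dict(cfg.groups)
            meta = pd.DataFrame({"subject_id": list(groups),
                                 "group": list(groups.values()),
                                 "age": np.nan})
        manifest["stages"].append(stage)

        # -------------------------------------------------------- preprocess
        stage = "preprocess"
        excluded = []
        for sid, mpath in cfg.motion_paths.items():
            mt = preprocess.load_motion_table(mpath)
            res = preprocess.check_motion(mt, cfg.trans_limit_mm,
                                          cfg.rot_limit_deg)
            if not res.passed:
                excluded.append({"subject_id": sid, "axis": res.offending_axis})
        if excluded:
            bad = {e["subject_id"] for e in excluded}
            volumes = [v for v in volumes if v.subject_id not in bad]
            log.info("motion exclusion removed %d subjects", len(bad))
        pd.DataFrame(excluded, columns=["subject_id", "axis"]).to_csv(
            out / "motion_exclusions.csv", index=False)
        record(out / "motion_exclusions.csv")

        matrices: dict[str, nifti_io.DataMatrix] = {}
        for vs in volumes:
            vs = preprocess.discard_initial_volumes(vs, cfg.discard_n)
            vs = preprocess.smooth_gaussian(vs, cfg.smooth_fwhm_mm, mask)
            dm = nifti_io.to_matrix(vs, mask)
            dm, _ = preprocess.detrend_and_standardize(dm)
            if vs.subject_id in matrices:
                # multi-run subject: concatenate detrended runs in time
                prev = matrices[vs.subject_id]
                dm = nifti_io.DataMatrix(
                    values=np.vstack([prev.values, dm.values]),
                    voxel_index=prev.voxel_index, tr_s=prev.tr_s)
            matrices[vs.subject_id] = dm
        manifest["stages"].append(stage)

        # --------------------------------------------------------- group ICA
        stage = "group_ica"
        if cfg.n_components == "mdl":
            K = int(np.median([group_ica.estimate_order_mdl(dm)
                               for dm in matrices.values()]))
            log.info("MDL model order: %d", K)
        else:
            K = int(cfg.n_components)
        t_len = next(iter(matrices.values())).n_timepoints
        p1 = min(math.ceil(1.5 * K), t_len - 1)
        reductions = [group_ica.reduce_subject(dm, p1)
                      for dm in matrices.values()]
        greduced = group_ica.reduce_group(reductions, K)
        W, gset = group_ica.infomax(greduced, seed=cfg.seed)
        nifti_io.save_map(
            np.stack([nifti_io.from_matrix(m, mask) for m in gset.maps], axis=-1),
            out / "group_maps.nii.gz")
        record(out / "group_maps.nii.gz")
        np.savez(out / "group_ica.npz", W=W, eigenvalues=greduced.eigenvalues)
        record(out / "group_ica.npz")
        manifest["stages"].append(stage)

        # --------------------------------------------------- dual regression
        stage = "dual_regression"
        subject_sets: dict[str, group_ica.ComponentSet] = {}
        for sid, dm in matrices.items():
            cs = dual_regression.dual_regress(dm, gset.maps)
            subject_sets[sid] = cs
            pd.DataFrame(cs.timecourses,
                         columns=[f"ic{k}" for k in range(K)]).to_csv(
                out / f"sub-{sid}_timecourses.csv", index=False)
            record(out / f"sub-{sid}_timecourses.csv")
        manifest["stages"].append(stage)

        # ------------------------------------------------ component selection
        stage = "component_select"
        report = component_select.select_components(
            [cs.timecourses for cs in subject_sets.values()], cfg.tr_s,
            cutoff_hz=cfg.selection_cutoff_hz,
            max_fraction=cfg.selection_max_fraction)
        report.table.to_csv(out / "component_selection.csv", index=False)
        record(out / "component_selection.csv")
        selected = report.kept
        manifest["stages"].append(stage)

        # ------------------------------------------------------- voxel stats
        stage = "voxel_stats"
        by_group: dict[str, list[str]] = {}
        for sid in matrices:
            by_group.setdefault(groups[sid], []).append(sid)
        ref = cfg.reference_group if cfg.reference_group in by_group \
            else next(iter(by_group))
        others = sorted(g for g in by_group if g != ref)
        comparisons = [(g, ref) for g in others]
        comparisons += [(a, b) for i, a in enumerate(others)
                        for b in others[i + 1:]]
        for k in selected:
            zmaps = {g: np.stack([subject_sets[s].maps[k] for s in sids])
                     for g, sids in by_group.items()}
            ref_stat = voxel_stats.one_sample_t(zmaps[ref], cfg.alpha)
            net_mask = voxel_stats.make_network_mask(ref_stat, cfg.alpha)
            nifti_io.save_map(nifti_io.from_matrix(ref_stat.t, mask),
                              out / f"ic{k}_{ref}_onesample_t.nii.gz")
            record(out / f"ic{k}_{ref}_onesample_t.nii.gz")
            for a, b in comparisons:
                if not net_mask.any():
                    continue
                sm = voxel_stats.two_sample_t(zmaps[a], zmaps[b], net_mask,
                                              cfg.alpha)
                tag = f"ic{k}_{a}_vs_{b}"
                nifti_io.save_map(nifti_io.from_matrix(sm.t, mask),
                                  out / f"{tag}_t.nii.gz")
                record(out / f"{tag}_t.nii.gz")
                ct = _cluster_table(sm.q < cfg.alpha, sm.t, mask)
                ct.to_csv(out / f"{tag}_clusters.csv", index=False)
                record(out / f"{tag}_clusters.csv")
        manifest["stages"].append(stage)

        # --------------------------------------------------------------- FNC
        stage = "fnc"
        sig_sets: dict[str, set] = {}
        fnc_results: dict[str, fnc.FncResult] = {}
        for g, sids in by_group.items():
            fr = fnc.fnc_cohort({s: subject_sets[s].timecourses for s in sids},
                                cfg.tr_s, selected, band=cfg.band_hz,
                                max_lag_s=cfg.lag_window_s)
            fnc_results[g] = fr
            fr.to_long_frame().to_csv(out / f"fnc_{g}_subjects.csv", index=False)
            record(out / f"fnc_{g}_subjects.csv")
            gt = fnc.fnc_group_test(fr, cfg.alpha)
            gt.table.to_csv(out / f"fnc_{g}_group.csv", index=False)
            record(out / f"fnc_{g}_group.csv")
            sig_sets[g] = gt.significant_pairs()
            ages = meta.set_index("subject_id").loc[sids, "age"].to_numpy()
            if np.isfinite(ages).all() and len(sids) >= 3 and np.std(ages) > 1e-12:
                fnc.fnc_age_correlation(fr, ages).to_csv(
                    out / f"fnc_{g}_age_corr.csv", index=False)
                record(out / f"fnc_{g}_age_corr.csv")
        for a, b in comparisons:
            bt = fnc.fnc_between_groups(fnc_results[a], fnc_results[b], cfg.alpha)
            bt.table.to_csv(out / f"fnc_{a}_vs_{b}.csv", index=False)
            record(out / f"fnc_{a}_vs_{b}.csv")
        manifest["stages"].append(stage)

        # ------------------------------------------------- subsystem report
        stage = "report"
        # partition is defined over selected-component positions 0..len-1
        part_sel = fnc.SubsystemPartition(
            {i: part.mapping.get(c, part.mapping.get(i, "unassigned"))
             for i, c in enumerate(selected)})
        pos_sets = {g: {(selected.index(i), selected.index(j)) for i, j in s}
                    for g, s in sig_sets.items()}
        summary = fnc.subsystem_summary(pos_sets, part_sel, ref)
        summary.to_csv(out / "subsystem_report.csv", index=False)
        record(out / "subsystem_report.csv")
        counts = {g: len(s) for g, s in sig_sets.items()}
        with open(out / "fnc_significant_counts.json", "w") as fh:
            json.dump(counts, fh)
        record(out / "fnc_significant_counts.json")
        manifest["stages"].append(stage)
    except Exception as exc:
        save_manifest()
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    save_manifest()
    record_missing = [f for f in manifest["files"] if not (out / f).exists()]
    assert not record_missing, f"manifest lists missing files: {record_missing}"
    return manifest
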