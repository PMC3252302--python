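# rsnflow

Group spatial ICA, dual regression, and lagged functional network
connectivity (FNC) for resting-state fMRI — with a synthetic multi-subject
cohort generator that plants known spatial networks, lagged couplings and
group effects, so every stage of the analysis can be validated against
ground truth.

## Who this is for

Researchers analyzing multi-subject resting-state BOLD data who want the
classic GIFT-style decomposition chain — and a way to test it. The package
implements the full path from 4D NIfTI volumes to group-level network
statistics:

1. **Preprocessing** — discard initial volumes (default 5), exclude subjects
   with head motion > 2 mm translation or > 1° rotation (relative to the
   first volume, strict inequality), isotropic Gaussian smoothing
   (default 8 mm FWHM), per-voxel linear detrend + variance normalization.
2. **Group spatial ICA** — two-stage PCA (subject-level temporal reduction,
   then reduction of the temporally concatenated cohort to K dimensions),
   model order by the Wax–Kailath MDL criterion (or a fixed K), and
   natural-gradient **infomax** ICA with a logistic nonlinearity:

   ΔW = η (I + (1 − 2y) uᵀ/n) W,  u = Wx,  y = σ(u)

3. **Dual regression** — stage 1: OLS of each time point on the K group maps
   → subject time courses; stage 2: OLS of each voxel's series on those time
   courses → subject maps, z-scored over in-mask voxels.
4. **Component selection** — a component is discarded when more than 50% of
   its time-course power lies above 0.1 Hz (median across subjects), with a
   manual override list replacing visual inspection.
5. **Voxelwise statistics** — one-sample t per group; pooled two-sample t
   between groups restricted to the control group's network mask
   (one-sample q < 0.05, t > 0); Benjamini–Hochberg FDR throughout.
6. **FNC** — per subject and component pair: cubic-spline interpolation to a
   1 s grid, 0.01–0.1 Hz zero-phase Butterworth band-pass, then the
   *constrained maximal time-lagged correlation*: Pearson correlations at the
   11 circular lags in ±5 s, keeping the coefficient of maximal absolute
   value and its lag. With 8 components this yields 28 pairs per subject.
   Group inference runs on Fisher-z values (one- and two-sample t, FDR over
   pairs), plus an age–FNC Pearson screen.
7. **Subsystem reorganization** — the 8 networks partition into three
   subsystems (integration/modulation, higher cognition, primary function:
   7 intra-system and 21 inter-system pairs); significant edges are
   classified intra/inter and tabulated as preserved/lost/gained against a
   reference group.

## Worked example

Run the bundled synthetic demo (three groups of 4 subjects, 8 planted
networks on a 20³ voxel grid, 205 volumes at TR = 2 s; the patient-like
groups have attenuated network loadings and one severed inter-system
coupling):

```bash
rsnflow all --out demo_run --seed 1
rsnflow report demo_run
```

which prints (abridged):

```
    group    status  intra  inter  total
  control preserved      1      8      9
patient_a preserved      1      3      4
patient_a      lost      0      5      5
patient_b preserved      0      5      5
patient_b      lost      1      3      4
```

Reading: the control group shows 9 FDR-significant FNC edges; the
patient-like groups retain their intra-system edges but lose inter-system
ones — the hierarchical disconnection pattern the pipeline is designed to
expose. `demo_run/` also contains the group component maps
(`group_maps.nii.gz`), per-subject time courses and z-maps, per-component
voxelwise t/q maps with cluster tables, per-group FNC matrices, and a
`manifest.json` with a SHA-256 hash of every artifact (reruns with the same
config and seed reproduce the hashes).

A library session for one stage:

```python
from rsnflow import fnc
r, lag = fnc.fnc_subject(tcs, tr_s=2.0)   # tcs: (time, 8) component courses
# r[i, j]  : maximal lagged correlation of pair (i, j)   (symmetric)
# lag[i, j]: lag of that maximum, seconds; > 0 means j lags i (antisymmetric)
```

## Scope

Volumes are assumed co-registered (no realignment, slice timing or spatial
normalization); no anatomical labeling; no dynamic or directed connectivity.
See `docs/methods.md` for the model, parameter defaults and limitations.
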