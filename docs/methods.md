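# Methods

This note records the model behind each stage, the defaults and why, the
numerical choices, and what the synthetic validation does and does not show.

## Data model and conventions

A subject's run is a 4D array (x, y, z, t) with voxel size 3 mm (configurable)
and TR = 2 s. Masked data live in a time × voxel matrix whose columns are the
in-mask voxels in C-order (row-major) flatten order of the grid; this single
ordering is used by every stage, and volume → matrix → volume is the identity
on in-mask voxels. Affines are carried through but never used to resample:
inputs are assumed co-registered.

## Synthetic cohort generator

The generator emulates registered, spatially smooth multi-subject BOLD data
with planted ground truth:

- **Spatial networks.** K = 8 maps, each a sum of isotropic Gaussian blobs
  (σ = FWHM / 2√(2 ln 2)) evaluated at in-mask voxels and rescaled to unit
  peak. Default blob FWHM is 15 mm: a network must carry enough spatial
  energy that its temporal eigenvalue stands clear of the Marchenko–Pastur
  noise bulk, otherwise no covariance-based reduction could recover it; very
  small blobs (≲ 3 voxels FWHM) do not emulate a resting-state network in
  this sense. Default centers are farthest-point–spread through a spherical
  mask (radius 8 voxels in a 20³ grid).
- **Time courses.** Band-limited Gaussian processes, synthesized on a 1 s
  grid by zero-phase Butterworth band-pass (order 5, 0.01–0.1 Hz) of white
  noise — the same filter family the analysis side uses — then decimated to
  the TR grid. A coupling (i, j, ρ, δ) sets tc_j(t) = ρ·tc_i(t − δ) +
  √(1 − ρ²)·independent noise, with δ realized as a circular shift on the 1 s
  grid. Because the analysis interpolates back onto the same grid and scans
  circular lags, planted and recovered lags share one convention: lag(i, j) >
  0 means j lags i. Each course is standardized.
- **Rendering.** In-mask signal = tc · diag(loading) · maps + i.i.d. Gaussian
  noise + a constant baseline of 100 (removed by detrending). Default
  noise_sd = 1.0, i.e. voxel SNR 1 at a blob peak.
- **Group effects.** Reduced within-network connectivity is operationalized
  as a loading scale < 1 on designated networks (one defensible choice among
  several — it scales the network's voxel loadings uniformly); lost
  between-network connectivity as couplings removed from a group's list.
  Ages are drawn uniform on [8, 35] years and used only by the age screen.
- **Determinism.** One `SeedSequence` drives per-subject generators; the same
  seed yields bit-identical cohorts.

What the generator does **not** emulate: hemodynamic response convolution,
physiological noise spectra, spatial noise correlation, subject-to-subject
anatomical variability, motion artifacts (a motion table can be injected
separately to exercise the exclusion rule). Passing the planted-recovery
suite therefore shows the analysis machinery is correct, not that it is
robust to every property of real data.

## Preprocessing

- Discard n = 5 initial volumes (steady-state magnetization).
- Motion rule: fail iff any-axis |translation| > 2 mm or |rotation| > 1°,
  displacements taken relative to the first volume (common realignment
  convention), strict inequality so a value exactly at the limit passes.
  SPM-style rp_*.txt files carry rotations in radians and are converted on
  load.
- Smoothing: per-axis σ = FWHM / 2√(2 ln 2) / voxel size, truncated at 4σ.
  The boundary is edge-replicating, which preserves a constant image exactly
  (a conservation property the suite asserts); zero-padding would darken the
  rim. FWHM 0 is the identity.
- Detrend + variance normalization per voxel; voxels with residual sd below
  1e−10 are zeroed and flagged.

## Group ICA

- **Order selection.** Wax–Kailath MDL on the temporal covariance
  eigenvalues, voxels as samples:
  MDL(k) = −N(p−k)·ln(g_k/a_k) + ½k(2p−k)·ln N. The i.i.d.-sample assumption
  is violated after spatial smoothing (neighboring voxels are correlated), so
  on smoothed data MDL overestimates the order — on the demo data it picks
  near-maximal k. The pipeline therefore accepts a fixed `n_components`
  (default 8) and treats `"mdl"` as an opt-in; MDL recovers the true order
  reliably on spatially independent noise (the validation scenario).
- **Two-stage PCA.** Subject-level temporal PCA to p1 = min(⌈1.5K⌉, t−1)
  (headroom above K), concatenation along the reduced temporal axis, second
  PCA to K.
- **Infomax.** Natural-gradient updates with logistic nonlinearity on
  whitened data; lr0 = 0.01/ln K, mini-batch 128, anneal ×0.9 when the angle
  between successive epoch weight changes exceeds 60°, stop at
  ‖ΔW‖ < 1e−7 or 512 epochs; divergence restarts at half the rate (max 3).
  Small batches matter: with only a few updates per pass the stochastic
  search stalls far from the optimum. The objective is non-convex and an
  identity init occasionally lands in a trapped basin (verified by comparing
  the logistic log-likelihood against the true unmixing on simulated
  mixtures), so 3 seeded inits (identity + 2 random orthogonal) are run and
  the highest-likelihood solution kept. Map sign is fixed by positive
  skewness (activation blobs are positive-tailed); maps are z-scored over
  in-mask voxels.

## Dual regression

Stage 1 demeans the spatial regressors over voxels; stage 2 demeans the
temporal regressors over time (standard practice; an optional flag variance-
normalizes stage-1 courses before stage 2). Rank-deficient regressor sets
raise an error naming the collinear pairs. On noise-free factorizable data
the two stages reproduce the planted factors exactly; under isotropic noise
stage-1 estimates are unbiased — both are asserted in the suite. A caveat the
validation surfaced: when spatial maps overlap, (MMᵀ)⁻¹ correlates the
stage-1 estimation noise across components, which can induce small spurious
FNC between overlapping networks; the FNC-stage validation therefore runs on
true time courses, and cross-network leakage is a property to keep in mind
when interpreting estimated-course FNC.

## Component selection

Periodogram of the demeaned course; power normalized so the non-DC sum equals
the time-domain variance (Parseval, asserted to 1e−6). Discard iff the median
across subjects of the power fraction above 0.1 Hz exceeds 0.5 (strictly —
exactly half keeps the component). The subject-level median is used because
the aggregation level is genuinely open; the median is robust to a few noisy
subjects. Visual inspection is not automatable; a force-keep/force-discard
override list stands in for it and is logged in the report.

## Voxelwise statistics

One-sample and pooled-variance (Student) two-sample t-tests, two-sided, with
Benjamini–Hochberg FDR (q_i = min_{j≥i} m·p_(j)/j) over in-mask voxels.
Pooled rather than Welch variance matches classic SPM defaults. Between-group
tests run only inside the control group's network mask (one-sample q < 0.05
and t > 0; the positive side defines the network since loadings are
positive). Zero-variance voxels get t = 0, p = 1, and a flag.

## FNC

Interpolation to a 1 s grid (cubic spline, not-a-knot ends — boundary error
≈ 4e−3 on a 0.05 Hz tone, interior < 1e−3), band-pass 0.01–0.1 Hz, then for
each pair the Pearson correlation at the 11 integer-second circular lags in
±5 s. "Maximal" is read as maximal absolute value with sign retained; ties
break toward |lag| = 0, then the negative lag. Circular shifting loses no
samples at the window edges. Group tests use Fisher z (variance-stabilizing;
`use_fisher_z=False` reproduces raw-r testing), |r| clipped at 1 − 1e−12.
The max-over-lags statistic has an inflated null relative to the lag-0
correlation (asserted empirically in the suite); the signed statistic remains
symmetric under independence, so the one-sample group test keeps its nominal
level. The subsystem partition maps the 8 networks to
{integration/modulation, higher cognition, primary function} = {1st, 2nd,
4th}, {5th, 6th}, {3rd, 7th, 8th} components, giving 7 intra- and 21
inter-system pairs of the 28.

## Validation scenario sizes

Chosen to exercise each property at the cohort scale the method targets while
keeping the suite quick: planted-graph FNC recovery at 14 subjects × 200
volumes; group-difference detection at 14 vs 16 subjects, loading 0.5,
noise_sd 1; ICA recovery on 3 Laplace sources × 5000 samples over 10 seeds;
MDL on 60 × 4000 matrices at SNR 10 over 20 seeds; the demo pipeline at 3
groups × 4 subjects × 205 volumes. Synthetic volumes are analyzed without
re-smoothing in the planted-effect scenarios: the planted maps are already
smooth and the render noise is i.i.d., and smoothing would saturate
within-network voxel–course correlations toward 1, erasing the z-map
expression of a loading attenuation. The pipeline keeps 8 mm smoothing as its
default for real data (and it is essential before ICA at low SNR). The
"planted support" used for the Dice score is the blob's half-maximum extent.

## Known limitations

- MDL without a spatial-decorrelation correction overestimates K on smoothed
  data (see above); set `n_components` explicitly for real data.
- The FNC lag grid is 1 s; sub-second delays quantize to the nearest lag.
- Estimated-course FNC inherits dual-regression leakage between overlapping
  maps.
- The spectral selection rule cannot distinguish a low-frequency artifact
  (e.g. slow drift residue) from a network; the override list exists for
  that reason.
- Multiple runs per subject are handled by temporal concatenation after
  per-run detrending; run-level nuisance structure is not modeled.
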