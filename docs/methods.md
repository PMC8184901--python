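# Methods

This note documents the models implemented in `voxdose`, the defaults
and why they were chosen, what the synthetic phantom does and does not
emulate, and the numerical decisions a maintainer would want written
down.

## The dosimetry chain

The target workflow is per-cycle kidney dosimetry for ¹⁷⁷Lu radiopeptide
therapy from one diagnostic CT plus four quantitative SPECT/low-dose-CT
pairs acquired at 0.5, 6, 24 and 72 h post injection.

1. **Segmentation.** Organs are delineated on CT slice-by-slice. A
   per-slice backend receives a 2.5D stack of 2k+1 adjacent slices
   (default k=1, i.e. three slices — enough axial context to
   disambiguate kidney from neighbouring soft tissue without committing
   to a full 3D model) and returns a binary mask, a confidence score, a
   bounding box and a success flag for the centre slice. The volume
   machinery is backend-agnostic: a trained CNN plugs in through the
   `SegmenterBackend` protocol. The shipped `reference_backend` is a
   deterministic classical pipeline (HU window [−100, 200] → threshold
   0.4 on the windowed scale → binary closing → connected components ≥
   10 px) so the chain runs, and is testable, without trained weights.
   It reports slices with no surviving component as failures, which
   exercises the same repair path a detection miss in a learned backend
   would.
2. **Consensus.** Independent axial, sagittal and coronal runs are
   combined by per-voxel 2-of-3 majority vote — the minimal pixel-wise
   consensus; score-weighted voting was considered and rejected because
   the reference backend's scores are not calibrated across planes.
3. **Failure repair.** Failed slices are replaced by interpolating the
   two nearest successful slices. Interpolation acts on signed Euclidean
   distance fields (positive outside, negative inside), thresholded at
   the zero level set, not on the raw {0,1} indicators: indicator
   interpolation degenerates at the 0.5 tie (a slice midway between a
   small and a large disc would collapse to one of them under any tie
   rule), whereas distance-field interpolation morphs smoothly (the
   midway slice becomes the mid-sized disc). Failure runs touching the
   volume ends copy the nearest successful slice — there is no second
   anchor to interpolate towards. Repaired slices are accepted
   unconditionally; they are not re-scored.
4. **Mask resizing.** Backends that predict at reduced resolution
   (e.g. 256×256 masks against 512×512 ground truth) are upsampled by
   bilinear interpolation of the indicator and re-binarised at 0.5.
5. **Mass.** Organ mass = voxel count × voxel volume × 1.06 g/cc (soft
   tissue).
6. **Activity retrieval.** The CT mask is extended outward by a
   spill-out margin before being applied to the SPECT frame, to
   recapture counts pushed over the anatomical border by the system
   point-spread function (partial-volume effect). Two extension
   semantics are provided: `dilate` (default) — morphological dilation
   with a spherical element of radius `margin_mm` in world units, exact
   and threshold-free; `gaussian` — convolution of the mask with an
   isotropic Gaussian of σ = `margin_mm` keeping voxels above an
   inclusion threshold (default 0.05 — the level at which a planar
   border extends by ≈1.6σ, comfortably past the bulk of the spill).
   Default margin 3 mm, matching a ≈3 mm-σ SPECT PSF; 6 mm is the
   recommended retry when SPECT-vs-CT misalignment is suspected.
   Dilation distances are centre-to-centre, which makes the single-voxel
   dilation a lattice-ball (123 voxels at 3 mm on a 1 mm grid) and is
   only a faithful 3 mm shell when the grid is finer than the margin —
   one reason the phantom default is 1.5 mm spacing.
7. **Kinetics.** The four retrieved activities are fitted to
   A(t) = A₁e^(−λ₁t) + A₂e^(−λ₂t) by bounded nonlinear least squares
   (unweighted by default; 1/A weighting available). Initialisation is
   classical curve stripping: the terminal slope of the last two samples
   seeds (A₂, λ₂), the head residual seeds (A₁, λ₁). When stripping
   leaves a non-positive head residual the data are effectively
   mono-exponential and the fit falls back to a single exponential
   (reported as A₂ = 0, λ₂ = λ); the simpler model is also preferred
   whenever it matches the bi-exponential residual to within numerical
   noise. λ may optionally be bounded below by the physical ¹⁷⁷Lu decay
   constant ln 2 / (6.647 d) — effective clearance cannot be slower than
   physical decay — off by default since clinical fits are not always so
   constrained. The cumulated activity is analytic,
   Ã = (A₁/λ₁ + A₂/λ₂)·3600 Bq·s, integrated to infinity; a truncated
   integral is available but not default, because the fitted curve is
   the model of record beyond the last sample.
8. **Dose.** The dose map is the 3D convolution of the voxelised
   cumulated activity with a voxel S-value kernel (Gy per Bq·s),
   zero-padded at the edges (organs are interior in all phantoms). The
   default kernel is single-voxel local deposition,
   s₀ = E_per_decay/voxel mass, appropriate because the ¹⁷⁷Lu electron
   range is below the voxel sizes in play; the default energy per decay
   (0.1479 MeV, mean β⁻ + conversion + Auger from standard decay
   compilations) is a configuration value, overridable per study, and
   externally computed voxel-S tables load from CSV (octant-stored
   tables are mirrored). Photon cross-dose is out of scope: reported
   kidney doses are self-dose.
9. **DVH.** DVH-x is the minimum dose received by the hottest x% of the
   organ volume (so DVH-30 ≥ DVH-70), read from the cumulative
   histogram of in-mask voxel doses.

### Where the cumulated activity is deposited

The extended mask is a *retrieval* region only. The per-voxel cumulated
activity is distributed over the anatomical organ mask, weighted by the
measured activity at a reference time point (default 24 h — the latest
point with strong signal), normalised so the voxel map sums exactly to
the organ Ã. Rationale: the spilled counts are a measurement artifact
of the PSF, and ¹⁷⁷Lu electron self-dose deposits where the activity
physically is — inside the organ. This choice also reproduces the
qualitative clinical behaviour that motivates margin tuning: a
SPECT-vs-CT misalignment depresses the retrieved Ã and hence the dose,
and enlarging the margin from 3 to 6 mm recovers part of the loss.
Distributing Ã over the extended mask instead makes the margin cancel
out of the mean organ dose identically, which contradicts that
behaviour. A `per_voxel` mode (independent bi-exponential fit per
voxel, organ-shape fallback, renormalised to the organ Ã) is retained
for fidelity to literal voxel-wise integration, but it is fragile with
only four samples per voxel and is not the default.

## The synthetic phantom

The phantom emulates the *structure* of a single-cycle dosimetry
acquisition — one diagnostic CT plus four SPECT/LDCT pairs with known
masks and known kinetics — so every stage has an exact oracle.

Defaults (fixed once, at design time):

| parameter | default | why |
|---|---|---|
| grid | 96³ at 1.5 mm | fine enough that a 3 mm dilation is a real shell and ellipsoid volumes voxelise within 2% |
| organs | two kidney ellipsoids, semi-axes 25/20/45 and 24/19/42 mm | ≈100 g and ≈85 g at 1.06 g/cc, inside the clinically observed range |
| CT values | kidneys 40 HU on −50 HU background | soft-tissue contrast the [−100, 200] window separates |
| kinetics | (2.0×10⁸ Bq, 0.35 h⁻¹, 4.0×10⁷ Bq, 0.012 h⁻¹) and (1.8×10⁸, 0.40, 3.0×10⁷, 0.010) | ≈0.45 GBq renal A(0) for a 7.5 GBq administration; slow effective half-lives 58/69 h, faster than physical decay; mean doses 3–4 Gy |
| time points | 0.5, 6, 24, 72 h p.i. | the acquisition schedule of the emulated study |
| PSF σ | 0 mm (default), 3 mm for realism | blur-free default keeps every bookkeeping identity exact; tests that exercise spill-out construct the 3 mm variant explicitly |
| noise | none (default); Poisson with a counts-per-Bq scale otherwise | deterministic acceptance runs |
| misalignment | none; per-time-point rigid shift available | emulates a co-registration failure |

SPECT frames put A(t)/V uniformly inside each voxelised organ (so the
unblurred total equals the analytic A(t) exactly), then blur, shift and
resample. Everything is deterministic given the spec and seed.

**What the phantom does not emulate** — and therefore what passing
tests do *not* show about patient data: anatomical shape variability
and organ contact (ellipsoids never touch), CT texture/noise and
contrast phases, non-uniform intra-organ uptake (renal cortex vs
pelvis, the filtrate problem), collimator-distance-dependent and
non-Gaussian PSFs, scatter and attenuation residuals, and
reconstruction artefacts. The classical reference backend scores
near-perfect Dice here precisely because the phantom's contrast is
clean; that number validates the *machinery* (stacking, voting, repair,
bookkeeping), not CT segmentation difficulty.

## The comparison arithmetic

The published 8-patient cohort tables (kidney masses and mean doses,
expert vs automated) ship as package data and are regenerated by the
report module: per-side signed difference Di = round(100·(AI−Ex)/Ex) to
the nearest integer (half away from zero, negative = underestimation),
per-patient mean of the absolute per-side integers (exact multiples of
0.5; a missing kidney contributes nothing), cohort mean at one decimal.
Rounding per side *first* is the only order that reproduces the
published half-integer cells. Two printed values are not reachable from
their own tables and are reported at their recomputed values with a
note in the rounding trace: the mass-table cohort average (printed 7.5,
cells give 7.5625 → 7.6) and the dose Di of patient 7's left kidney
(printed −20, doses 1.74 vs 2.19 Gy give −20.55 → −21, which propagates
to that patient's mean and the dose cohort average). The spill-out
re-analysis uses its own printed precision: per-side underestimation
100·(Ex−AI)/Ex truncated toward zero at two decimals (2.7397 → 2.73),
average at one decimal.

## Numerical choices and degenerate inputs

- Mask re-binarisation after any interpolation: threshold 0.5 (≥).
- Dice of two empty masks is defined as 1.0.
- `consensus` requires identical geometry; `dice`, `mean_dose`, `dvh`
  and `extract_activity` refuse mismatched grids rather than resampling
  silently — resampling is the caller's explicit step.
- Empty organ mask: mass warns and returns 0 g; mean dose and DVH
  raise.
- All-zero SPECT: threshold segmentation raises; all-zero TAC raises.
- Fit bounds: amplitudes ≥ 0, rates ≥ 10⁻⁹ h⁻¹ (or the physical decay
  constant when constrained); tolerances 10⁻¹⁵ so the noiseless
  four-point system is inverted to machine precision.
- Convolution edge handling: zero padding; energy conservation holds to
  0.5% for sources ≥ 3σ from the boundary, and phantom organs are
  placed accordingly.
- Problem sizes in the test suite (96³ phantom grids, 200-replicate
  noise studies, 50-draw quadrature checks) were chosen as the smallest
  sizes at which the statistical assertions are stable.

## Known limitations

- The trained-CNN backend is an interface, not an artifact: no weights
  are shipped or trained here, and LiTS/KiTS19-style benchmark accuracy
  is out of scope.
- The expert practice of manually excluding the renal-pelvis filtrate
  at early time points is not modelled (no filtrate compartment in the
  phantom, no manual-edit hook in the pipeline).
- Rigid misalignment only; no elastic motion.
- Single-organ self-dose; no cross-organ photon dose, no tumour or
  bone-marrow dosimetry.
- DICOM series reading is not implemented; NIfTI/MetaImage (plus a YAML
  intensity sidecar) are the interchange formats.
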