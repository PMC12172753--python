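# Methods notes

This note records the model assumptions, parameter choices and numerical
conventions behind `tmsmap`, and what the synthetic cohorts do and do
not establish about real data.

## Pipeline overview

Per subject: stimulation-locked EMG → zero-phase 30 Hz high-pass →
MEP/non-MEP classification → projection of MEP-positive coil positions
to the nearest subject-mesh vertex → masking to the "precentral L"
atlas region on the subject surface → sphere-registration warp to the
template → geodesic inverse-distance interpolation to an MEP-weighted
vertex map → centroid, weighted area, pairwise overlap. Cohort level:
two-way repeated-measures ANOVAs with sphericity handling and
Bonferroni post-hocs.

## EMG model and detection

- **Filter.** 2nd-order Butterworth high-pass at 30 Hz, applied
  forward-backward (`scipy.signal.filtfilt`) so the phase response is
  zero and MEP peaks are not shifted. Reflective padding of 3× the
  filter length; traces too short for the padding are rejected rather
  than zero-padded.
- **Classification.** Peak-to-peak amplitude in a [15, 50] ms
  post-stimulus window (standard for hand/forearm MEPs; configurable —
  published motor-mapping protocols rarely print their exact window).
  Acceptance requires `p2p > 20 × baseline SD` and `p2p < 10 mV`, both
  strict; the 10 mV bound is read as artifact rejection and takes
  precedence in the recorded rejection reason. Baseline SD is the
  population (1/N) SD of the filtered trace over [−200, 0) ms.
- **RMT.** Lowest tested intensity with > 50 µV amplitudes in ≥ 5 of
  exactly 10 trials; a missing threshold raises rather than
  extrapolates.

## Surface warping

- Sphere registrations are consumed as inputs (FreeSurfer-convention
  per-vertex unit vectors); computing an inflation from scratch is out
  of scope. Synthetic meshes carry analytic registrations: radial
  projection for hemispheres, an azimuthal-equidistant embedding for
  flat patches.
- The warp cost is additive: great-circle distance plus
  `lambda_curv × |Δ z-scored curvature|`, default λ = 1. Z-scoring (per
  surface) makes both terms dimensionless and comparable; the functional
  form combining angular distance with curvature matching is a design
  choice of this package — a hard curvature constraint or multi-scale
  registration would be defensible alternatives.
- Ties in nearest-vertex projection and in the warp argmin go to the
  lowest index, making runs bit-reproducible.
- Masking precedes warping, always: atlas labels are only trustworthy on
  the surface they were drawn on.
- Coil orientation is registered but deliberately unused; nearest-vertex
  projection uses the coil's focal position only.

## Maps and metrics

- **Interpolation.** Inverse-distance weighting of stimulation
  amplitudes over geodesic distances within `radius_mm` (default 5 mm).
  Geodesics are shortest edge paths (Dijkstra on the edge graph), which
  at the mesh resolutions used here differ negligibly from exact
  polyhedral geodesics. Stimulation vertices keep their own amplitude
  exactly (mean when several pulses project to one vertex); vertices
  beyond every stimulation's radius are excluded from the map.
- **Area.** Heron's formula per triangle whose three vertices all belong
  to the map (a conservative membership rule avoiding fractional
  triangles), scaled by the triangle's mean vertex MEP. Floating-point
  negative radicands are clipped to zero. With unit weights the size
  equals the cross-product geometric area to 1e-9 relative — this is a
  tested invariant.
- **Overlap.** Intersection = triangles complete in both maps; union =
  complete in at least one. The primary mode is `geometric` (weight 1
  per triangle, an area Jaccard index); mode `weighted` max-normalises
  each muscle's weights per subject, then uses the mean of the two
  muscles' triangle weights in the intersection and the available
  muscle's weight elsewhere. Which weighting published motor-mapping
  analyses use inside the intersection is generally ambiguous, so both
  are provided and the mode is recorded in the output tables. Raw µV
  weights are kept for centroids and sizes (centroid is
  weight-scale-invariant, size scale-covariant).
- An empty union raises rather than returning 0: two maps with no
  complete triangle have no defined overlap.

## Statistics

- Fully within-subject two-way ANOVA on the balanced (n, a, b) cell
  array; each effect is tested against its subject-interaction error
  term. Replicated cells (the two repetition blocks) are averaged within
  subject × condition first.
- Mauchly's W is computed on the covariance of orthonormal-contrast
  scores with the chi-square approximation; Greenhouse-Geisser epsilon
  from the same covariance's eigenvalues, clipped to
  [1/(k−1), 1]. The correction is applied when Mauchly rejects at
  α = .05 (configurable). With two levels sphericity is automatic
  (W = 1, ε = 1).
- When the contrast covariance is singular (fewer than levels−1 degrees
  of freedom between subjects, e.g. 8 muscles with small n), Mauchly's
  test is reported as NaN and the GG correction is applied
  unconditionally — the uncorrected test is not trustworthy there
  either. The direct `mauchly_sphericity` API raises instead, naming the
  deficiency.
- Sums of squares below 1e-12 of the total are treated as exactly zero
  so constant-effect data yields F = 0 rather than a ratio of rounding
  noise.
- Post-hocs are Bonferroni-corrected paired t-tests; the family is the
  k(k−1)/2 comparisons within one effect. Paired t (rather than
  simple-effect ANOVAs) is this package's choice and is cross-checked
  against scipy.
- The implementation is cross-validated against pingouin (`rm_anova`,
  `sphericity`, `epsilon`) in the test suite and calibrated on simulated
  null cohorts: type-I error at α = .05 within [0.036, 0.064] over 2000
  replicates of 12 subjects.

## Synthetic cohorts: what they emulate, and what they don't

The generator reproduces the study-scale design: 20 subjects, 8 muscles,
3 intensity conditions (labelled 105%-RMT-FDI/-EDC/-FCR), 120 pulses per
block, 2 repetitions (720 pulses per subject), 5 s inter-stimulus
interval, coil positions pseudo-random-uniform over a 5 × 5 cm grid
centred on the hotspot, EMG at 2 kHz.

Choices the literature does not fix, made once and exposed in config:

- **Excitability fields.** Isotropic Gaussians on the precentral band;
  σ = 5 mm and peaks of 400–600 µV, typical of just-above-threshold
  mapping; hand muscles lateral (FDI +12, APB +9, FPB +6, ADM +2 mm
  along the band — thumb muscles lateral to ADM), forearm muscles medial
  (EDC −5, ECR −8, FDS −13, FCR −16 mm) with synergist pairs adjacent.
  Amplitude is a pure geometric function of coil-to-centre distance; no
  electric-field or conduction biophysics.
- **Intensity conditions** scale field peaks by 1.0 / 1.15 / 1.3
  (FDI/EDC/FCR-referenced thresholds), so the highest condition produces
  the largest, most overlapping maps.
- **Inter-subject variability.** Field centres jittered tangentially
  (Gaussian, SD 2 mm); subject meshes get out-of-plane vertex noise
  (SD 0.3 mm) while keeping the template's sphere registration, as a
  surface registration aligning anatomy would. In-plane vertex noise is
  avoided deliberately: it can flip grid triangles.
- **MEP waveform.** A Gabor-like biphasic wavelet (150 Hz carrier,
  3 ms envelope, 20 ms latency) scaled so its sampled peak-to-peak
  equals the requested amplitude exactly; trial-to-trial amplitude noise
  is Gaussian (SD 20 µV) clipped at zero.
- **Synthetic atlas.** Vertices within ±10 mm of the band's midline are
  labelled "precentral L", the rest "other", so M1 masking removes a
  realistic fraction (~55%) of the 5 × 5 cm grid.

Recorded ground truth: per-subject field parameters, the mask- and
detectability-restricted field centroid per condition (the estimand of
the centroid pipeline, which only ever sees MEP-positive pulses above
20 × the 5 µV baseline, i.e. 100 µV, within the masked band), and
analytic disc overlaps at 2σ radius per muscle pair.

What passing recovery tests does **not** show about real data: real
excitability fields are neither Gaussian nor isotropic, real curvature
drives the warp (synthetic patches have constant curvature, so the
curvature penalty is exercised separately on constructed fixtures), real
registrations carry errors the analytic registrations lack, and EMG
artifacts are richer than Gaussian noise plus one wavelet. The tests
establish that the *implementation* recovers known structure under its
stated assumptions, not that the assumptions hold in vivo.

## Problem sizes

Default analysis and evaluation runs are scaled for a single CPU: the
numbered analysis scripts use 8 subjects at the full 720-pulse design
(46,080 traces); the acceptance script uses a 10-subject pipeline run,
a 4-subject noiseless cohort for metric recovery, 2000 null cohorts for
ANOVA calibration, and 50 random meshes for the geometry oracle. The
20-subject default of `make_cohort` is exercised for bookkeeping
(20 × 720 events; 115,200 lazily generated traces). The template patch
is 40 × 40 vertices at 1.5 mm spacing; the disc-overlap oracle uses an
81 × 81 patch at 0.5 mm, where the discretised Jaccard index matches
the analytic circle-intersection ratio within 3%.

## Known limitations

- Shortest-edge-path geodesics overestimate true geodesic distance on
  coarse meshes; at the default resolutions the effect on IDW weights is
  negligible, but very coarse meshes would bias map extents.
- The IDW halo (vertices within the radius of boundary stimulations)
  slightly inflates map support relative to the true suprathreshold
  field; centroid recovery absorbs most of this by symmetry, and the
  residual is measured (≈0.2–0.5 mm, under half an edge length on
  average) rather than corrected.
- Mauchly's chi-square approximation is poor at small n with many
  levels; the GG-always fallback is conservative.
- No electric-field modelling, onset-latency estimation, or volumetric
  (non-surface) warping.
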