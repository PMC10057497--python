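# Methods

This note documents the models, conventions, and numerical choices behind
the `golfswing` pipeline, and what its synthetic validation does and does
not establish about real motion-capture data.

## Coordinate frame and segment angles

The lab frame has X along the target line, Z vertical. Pelvis orientation
is the line from the right-side centroid (mean of RASIS and RPSIS) to the
left-side centroid, projected onto the horizontal plane; using the
four-marker side centroids rather than the ASIS pair alone halves the
marker-noise variance of the line without changing its noiseless
direction. Thorax orientation is the RACR→LACR line. Each segment angle is
the unwrapped four-quadrant angle of that line against +X, offset to zero
at the setup frame. Because the physical turn direction depends on
handedness and marker conventions, the sign is normalized so that
backswing rotation is positive: if the thorax's dominant excursion is
negative, both segment series are negated. Only transverse-plane rotation
is computed; shoulder/pelvis tilt and other 3-D angles are out of scope.

## Filtering

Marker positions are smoothed with a zero-phase Gaussian kernel before
differentiation (default −3 dB cutoff 20 Hz; `cutoff_hz=None` disables
it). A Gaussian was chosen over the recursive Butterworth filter that is
conventional in gait analysis for one decisive reason: a Butterworth's
impulse response rings, and next to the near-discontinuous impact
deceleration that ringing makes the filtered club speed overshoot the true
peak by of order 1 m/s, a bias an order of magnitude larger than the
club-velocity resolution this pipeline targets. A Gaussian kernel is
strictly positive, so filtered speed can never exceed the true local
maximum; the residual biases (peak attenuation ≈ V·ω̃²σ²/2 from the speed
profile's curvature, and an arc-radius shrinkage ≈ V·ω²σ²/2 from smoothing
a curved path) are second-order in the kernel width and total under
0.1 m/s at the default cutoff for club speeds to ~32 m/s. The 20 Hz
default also keeps the impact acceleration spike above the club's
centripetal acceleration (so impact detection cannot lock onto the speed
peak) while suppressing differentiation noise: with 2 mm marker noise the
per-trial SDs are ≈0.25° for the angular parameters and ≈0.07 m/s for
club velocity.

## Event detection

All three events come from the club-head marker:

* **Start** — the 0.2 m/s threshold crossing from which the club
  accelerates continuously into the swing, found by tracing back from the
  first frame at ≥1 m/s to the last sub-threshold frame; the club must
  move away from the target (negative X velocity for a target at +X,
  configurable for left-handed data) and stay above threshold for 0.05 s.
  Tracing back rather than scanning forward makes the detector immune to
  noise excursions during the setup hold.
* **Top of backswing** — minimum club speed between the start and the
  frame of global maximum speed; a minimum above 0.5 m/s triggers a
  "sloppy transition" warning.
* **Impact** — maximum acceleration magnitude within ±0.05 s of the global
  speed maximum (after the top), the deceleration spike of ball contact.

The sustained-start window, the 0.5 m/s warning level, and the ±0.05 s
impact search window are implementation constants, not measured
quantities; the 0.2 m/s threshold is the field's standard definition.

## Discrete parameters

With s, t, i the start/top/impact frames: Pmax = |θ_p(t) − θ_p(s)|,
Tmax = |θ_th(t) − θ_th(s)|, Xfac = θ_th(t) − θ_p(t) (signed, positive when
the thorax is rotated further), SXfac = max over [t, i] of
(θ_th − θ_p) − Xfac floored at zero, GCV = max club speed over (t, i].
Note an identity that constrains any generator built on these definitions:
when both segments start at zero and the thorax peaks at the top event,
Xfac ≡ Tmax − Pmax. Field data violate this identity by a few degrees
(start angles are not exactly zero and segment maxima need not coincide
with the club-defined top), which is why the synthetic presets pin Pmax,
Tmax, and GCV and let Xfac be emergent.

## Continuous relative phase

Both segment angles on the analysis interval [start, impact] are
mean-centred, mirror-padded by 50% of the interval length per side,
Hilbert-transformed, and their unwrapped analytic phases subtracted:
CRP = φ_pelvis − φ_thorax, so negative CRP means the pelvis lags the
thorax in phase space. Because the two phases are unwrapped independently,
their difference carries an arbitrary whole-turn offset; the single
constant 360°·round(median/360°) is removed, and no pointwise wrapping is
ever applied. A documented `negate` flag converts to the display
convention in which negative values mean the pelvis *led*. Mirror padding
confines the Gibbs edge artifact to roughly the outer tenth of the
interval (verified on sinusoids: phase-linearity error beyond 2° occurs
only in the outer 10% of samples); consumers should treat the first and
last few normalized nodes as unreliable.

Each trial's CRP is aligned around the frame of maximal pelvis rotation
and resampled to 200 nodes. The default `split` strategy maps
[start, max] linearly onto the first `round(0.5·200)` nodes and
[max, impact] onto the rest, so the maximum falls on node 99 in every
trial regardless of phase durations; an alternative `shift` strategy
resamples the whole interval and translates it (edge-padded) instead.
Both the align fraction and the strategy are recorded in the output.

## Statistical parametric mapping

The group comparison unit is the per-player mean CRP curve (trials within
a player are not independent observations, so averaging is required for
valid SPM inference). At each node the pooled-variance two-sample t
statistic is computed; residual smoothness is estimated as
FWHM = √(4 ln 2 / v) with v the mean squared gradient of the residual
curves after pointwise normalization by the pooled SD; and the critical
threshold solves the 1-D Euler-characteristic expectation
E[EC(u)] = α for the t field with (Q−1)/FWHM resels (Brent root-finding
on (0, 100); for very small samples, df ≤ 2, the equation can have no
root below 100 and the analysis reports an error rather than a threshold).
Inference is two-sided on |t| via α/2 per tail; suprathreshold clusters
are maximal runs of |t| > u, reported as node ranges without cluster-level
p-values. Unbalanced groups are supported natively; a `balance_seed`
option reproduces the balanced-design variant in which the larger group
is randomly subsampled to the smaller size.

Calibration (recomputed by the test suite and `scripts/acceptance.py`):
on smooth Gaussian nulls with FWHM ≈ 15 nodes, Q = 200, n = 6+8, the RFT
threshold agrees with the 2,000-permutation max-|t| threshold within 5%,
and the empirical familywise error over 1,000 null replicates at α = 0.05
falls within 0.05 ± 0.02.

## Group statistics

ANOVA, Pearson correlation, and the Shapiro–Wilk screen delegate to
`scipy.stats`; partial eta squared is computed from the sums of squares
and satisfies η²ₚ = F·df1/(F·df1 + df2) exactly for the one-way design.
The inference unit is the per-player mean: the published two-tailed
correlation significances are recovered exactly from the printed
coefficients only with n = 6 boys and n = 8 girls, which identifies
player means (not the 10× larger trial pool) as the observation unit, and
the package adopts it throughout. The normality screen is reported but
never switches methods automatically. No multiple-testing correction is
applied across the five parameters, matching the original reporting. The
source's ANOVA F statistics themselves (e.g. F = 31.98 for club velocity)
imply error degrees of freedom near 24, irreconcilable with 14 players;
F values are therefore always reported together with their dfs, and no
attempt is made to match those published magnitudes.

## Synthetic swing generator

The generator exists to give every pipeline stage a ground truth, not to
be biomechanically complete. Segment rotations are raised-cosine
(cycloidal) ramps — C¹-smooth, flat at both ends, with closed-form values
at every event — rising to the segment amplitude over the backswing
(default 0.8 s) and descending past zero to −0.5× the amplitude over the
downswing (default 0.35 s). Two timing parameters shape coordination: the
pelvis-onset lag (pelvis backswing starts after the thorax's; its
backswing is compressed so both peak together) and the transition lead
(the pelvis reverses before the thorax, producing X-factor stretch). The
club head travels a horizontal circular arc about a vertical axis whose
radius is solved from the requested peak speed, with a 45° arc amplitude
so the arc's angular rate — and hence the curvature bias of filtering, and
the centripetal acceleration that competes with the impact spike — stays
small; ball contact is a raised-cosine speed drop to rest over 15 ms,
placing the analytic acceleration maximum (the ground-truth impact) a
known half-window after the zero crossing. Setup geometry (pelvis markers
±0.14 m laterally with ASIS 0.12 m anterior of PSIS, acromia ±0.20 m, grip
marker at 0.2× the head radius) is fixed and arbitrary. Marker noise is
isotropic Gaussian, seeded; a seed is mandatory everywhere.

Sex presets carry the junior-elite group means and SDs (girls: Pmax
46.80 ± 6.44°, Tmax 110.57 ± 7.21°, GCV 23.01 ± 1.34 m/s; boys:
38.96 ± 8.44°, 111.34 ± 17.51°, 27.31 ± 1.99 m/s). The onset lag presets
(boys 40 ± 10 ms, girls 0 ± 10 ms) are simulator parameters expressing the
reported thorax-led male backswing, not measured values. The 10 ms
transition lead reproduces, by the closed-form stretch of the
raised-cosine profiles, the ~0.1° X-factor stretch both groups showed — a
value far below adult literature magnitudes, flagged as a unit/scale
oddity of the source data rather than matched by fitting. Cohorts draw
player profiles from the presets (amplitudes truncated at zero) with
backswing/downswing durations jittered between players (±0.05 s/±0.02 s)
and within-player trial-to-trial jitter at 20% of the between-player SD —
a choice that makes per-player means meaningfully more stable than single
trials, as in real repeated-measures designs.

What passing the synthetic tests shows: the event definitions, angle
conventions, phase computation, normalization, and statistics do what
their formulas say, at the noise levels and smooth kinematics the
generator produces. What it does not show: robustness to marker dropout
and relabeling, soft-tissue artifact, non-planar club paths, or swings
whose speed profile violates the single-peak structure the detectors
assume. Gaps up to 10% per marker are linearly interpolated on read (with
a warning); larger gaps are rejected.

## Statistical power and test design

Under the presets the true sex effect on club velocity is large
(d ≈ 2.5) but the pelvis-rotation effect is d ≈ 1.07, which at the
original 8 + 6 design yields only ~45% power at α = 0.05 — any single
simulated cohort at that size is a coin flip. The end-to-end qualitative
test therefore runs 40 + 30 players × 4 trials (a priori power > 99% for
the same effect sizes and thresholds), while the acceptance script
additionally runs the original 8 + 6 × 10 design and reports whatever that
draw produces. Problem sizes elsewhere (50-profile recovery sweeps,
100-replicate noise studies, 1,000-replicate error calibration, 2,000
permutations) were chosen once as the smallest sizes at which the checked
quantities are statistically stable.

## Known limitations

* Transverse-plane angles only; no 3-D segment orientation.
* The RFT threshold assumes stationary smoothness of the residual field;
  strongly non-stationary residuals (e.g. variance concentrated at the
  transition) would make it locally mis-calibrated — the permutation
  threshold is the model-free fallback.
* The club-defined "top" need not coincide with either segment's rotation
  maximum; parameter definitions are anchored to the club events by
  construction, so segment-anchored re-definitions would give slightly
  different values on the same data.
* The archived study deposit's file schema is not documented here; the
  reader maps it onto the trial-CSV layout before `analyze` can consume
  it.
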