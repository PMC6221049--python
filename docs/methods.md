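# Methods

This note documents the models, conventions and design choices behind
`tmsfmri`, and what the synthetic validation does and does not show.

## Coordinate and transform conventions

All spatial quantities are world millimetres in the RAS+ frame defined
by the NIfTI voxel-to-world affine; voxel indices are 0-based and the
third voxel axis is the slice axis. Rigid transforms are proper
(rotation determinant +1); Euler angles use the extrinsic x-y-z
convention (R = Rz·Ry·Rx) and are reported in degrees, rotations taken
about the volume centre. Realignment stores, per volume, both the
estimated head-motion transform (its parameters are the motion table)
and its inverse, the volume→reference map consumed by coil tracking.

## Synthetic acquisition model

The generator emulates the modelled protocol: 30 slices of 4×4×4 mm³
voxels, 500 dynamics at TR 2.0 s (a 17-minute run), single pulses at
random intervals of 5–8 dynamics (10–16 s, drawn uniformly in whole
dynamics) with intensities strictly alternating high (115% RMT) / low
(60% RMT) starting high. "Interleaved" is read as strict alternation;
a per-pulse random assignment is available (`alternate=False`) since
the protocol wording does not fix it.

Anatomy is three concentric ellipsoidal shells — CSF outside
(baseline 500), grey matter (1000), white matter core (900) — on a
16×16 in-plane matrix. Only slice count, voxel size and timing carry
protocol meaning for the recovery experiments; the in-plane matrix is
kept small so full-protocol simulations stay desk-scale. Voxel signal
is

    baseline · (1 + effect(t)) + drift(t) + AR(1) noise,

where `effect(t)` is the high-pulse impulse train convolved with the
peak-normalised canonical HRF, scaled to `effect_pct` (default 1%) in
the target region (a 3³ GM neighbourhood on the +x side); drift is a
1st+2nd-order Legendre polynomial with per-voxel random coefficients
(default amplitude 1% of GM baseline); noise is stationary AR(1)
Gaussian (default SD 15 ≈ temporal SNR 67, coefficient 0.3 — standard
single-subject 3T EPI values). A static multiplicative texture field
(smoothed Gaussian noise, 5% SD) models receive-coil/tissue intensity
inhomogeneity; it is also what makes rigid motion identifiable — a
texture-free shell phantom is nearly rotationally symmetric and no
registration algorithm could recover in-plane rotation from it.

Spikes are injected post-noise (and in the pipeline post-motion,
matching an acquisition-time origin): each event offsets every in-mask
voxel of one slice in one volume by a constant amplitude. Head motion
is a scaled Gaussian random walk (default 0.3 mm / 0.15° over the run,
a compliant subject), applied by trilinear resampling about the grid
centre with volume 0 as identity.

What the phantom does **not** model: k-space/reconstruction physics,
susceptibility distortion, slice-timing offsets, physiological noise
structure, realistic anatomy. Passing recovery tests therefore shows
the estimators are correct under their stated assumptions, not that
they are robust to every property of real data.

## Spike detection and repair

Detection operates on the realigned series (pipeline order: realign →
detect → repair → smooth → GLM). For each slice with ≥1 GM voxel the
mean GM signal is differenced in time and robust-z-scored per slice
(median/MAD, consistency factor 1.4826; SD fallback with a warning if
the MAD is zero). Volume t is flagged when the steps into and out of t
both exceed the threshold with opposite signs — by construction drifts
and sustained steps are invisible. Boundary volumes use the one-sided
criterion. The default threshold of 6 reflects that leak-current
deflections are gross outliers; it is exposed in the config. The
detection statistic is this package's own design: the original
analysis used an unspecified custom algorithm, so the robust-z detector
is a documented stand-in validated on synthetic truth.

Repair replaces a flagged slice voxel-wise by the average of the same
slice in the previous and next volume; runs of consecutive flagged
volumes interpolate linearly between the nearest clean neighbours;
series-boundary events copy the single clean neighbour; a slice flagged
everywhere raises. The phrase "previous and next slice" in the source
protocol is ambiguous between spatial and temporal neighbours; the
temporal reading is implemented (a one-sample temporal deflection has
clean temporal neighbours by definition, while spatial neighbours of an
affected slice need not be informative about it), and the spatial
reading is deliberately not offered.

## Realignment

Cost is the mean squared intensity difference over valid (in-grid)
voxels under trilinear resampling, zero-padded at the boundary.
Optimisation is Gauss-Newton on the six rigid parameters with an
analytic Jacobian (sampled image gradients × rotation derivatives), a
Levenberg damping fallback, convergence tolerance 1e-4 mm/deg, and a
3-level Gaussian pyramid. Registration is two-pass: to the first
volume, then to the mean of the aligned series; transforms are finally
re-expressed relative to volume 0 so the first volume is exactly
identity. The reference policy is configurable (`first`) since the
original description does not state one.

## Coil model and tracking

The fiducial template is a configurable JSON model; the shipped default
(six markers in two rows on the back plate, isocenter 20 mm inward
along the plate normal) is an assumption documented here, as the
physical plate geometry is not standardised. Pose fitting is
closed-form orthogonal Procrustes on labelled correspondences with the
SVD sign corrected to a proper rotation; <3 markers or a collinear
configuration raises. Tracking conjugates each volume→reference
realignment map by the EPI→anatomical affine (supplied, not estimated)
and applies it to the isocenter: the coil is fixed in scanner space
while the head moves, so the inverse realignment transforms give the
per-volume anatomical position of the stimulated spot. The COG is the
coordinate-wise mean over volumes; the maximum displacement is the
largest Euclidean distance to the COG; summaries print at 0.1 mm.
Nonlinear normalisation of coordinates to a template brain is out of
scope; all reports are native-space.

## GLM

The canonical HRF is the difference of two gamma densities (peak delay
6 s, undershoot delay 16 s, unit dispersions, peak:undershoot ratio 6,
32 s support, 16 microtime bins per TR), peak-normalised; the second
basis function is its first-order temporal derivative. Events enter as
unit impulses on the microtime grid, are convolved, and are sampled at
each dynamic's acquisition onset. The "80 Hz" high-pass figure quoted
for this protocol is physically impossible at TR 2 s (Nyquist 0.25 Hz)
and is interpreted as a cut-off *period* of 80 s, implemented as an
orthonormal DCT basis with K = ⌊2·N·TR/80⌋ regressors. WM/CSF nuisance
signals are in-mask means of the repaired, realigned, *unsmoothed*
series, mean-centred.

Estimation is voxel-wise OLS without prewhitening (the modelled
analysis names none); an optional single-pass AR(1) Cochrane-Orcutt
mode exists and is off by default. Consequently the null-calibration
experiments use white-noise phantoms — p-value uniformity and exact FWE
control are properties of the estimator under its own noise model, and
under AR(1) noise OLS p-values are mildly anticonservative, which is
the standard trade-off of unwhitened OLS. The default contrast tests
high-vs-low jointly over both basis functions (two rows: canonical
difference, derivative difference); the alternative reading (canonical
difference with the derivative as covariate) is available by passing a
single-row contrast. FWE control is Bonferroni over in-mask voxels by
default; random-field theory is deliberately not implemented, and a
max-statistic permutation test over pulse-intensity relabellings
(requiring ≥20 pulses per level) is provided as the exact alternative.

## Region summaries

A region is reported Left/Right/Bi/absent by the presence of
suprathreshold voxels per hemisphere, hemisphere assigned by the sign
of the world x coordinate (x<0 left) unless the label volume already
encodes hemisphere. This automated rule is a stand-in for the visual
anatomical assignment a human rater would perform.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: full protocol
scale (30 slices × 500 dynamics) for spike recovery and GLM power;
10³-voxel, 120-dynamic white-noise phantoms (200 replicates) for FWE
calibration; 16³ noiseless phantoms for motion recovery; a 12³ analytic
Gaussian-blob scene for the exhaustive grid-search registration oracle
(an analytic scene keeps the oracle's cost free of resampling bias);
100 seeds for the marker-noise Monte-Carlo. These sizes were chosen so
each experiment has unambiguous ground truth while remaining
desk-scale.

## Known limitations

* OLS without prewhitening is anticonservative under temporal
  autocorrelation (see above); use the permutation FWE mode when exact
  control matters.
* The detector only targets single-sample, single-slice deflections;
  multi-sample artifacts are out of scope by design.
* Realignment assumes small motion (warm starts from the previous
  volume) and intensity constancy; it is not robust to large abrupt
  motion or spin-history effects.
* The coil template geometry is an assumption; absolute isocenter
  coordinates inherit any error in it, though displacements (the
  motion-tracking quantity) do not depend on the offset's absolute
  position.
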