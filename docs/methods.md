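# Methods

`opmtheta` simulates and analyses a paired-system theta-band MEG experiment:
the same synthetic "subjects" are recorded with a wearable 58-site triaxial
optically-pumped-magnetometer (OPM) helmet (174 channels, 6.5 mm scalp
offset) and with a fixed 275-channel radial cryogenic (SQUID-like) array
(40 mm offset). This note documents the models, the defaults and why, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## Forward model

Heads are spheres (default scalp radius 0.09 m, source region 0.08 m). The
magnetic field of a current dipole in a spherically symmetric conductor has
the closed analytic form

    B(r) = µ0 / (4π F²) · [ F (Q × r0) − ((Q × r0)·r) ∇F ],

with `F = a (r a + r² − r0·r)`, `a = r − r0`, which is exact for any radial
conductivity profile; radial dipoles are externally silent. Lead fields are
channels × 3 matrices in T/(nA·m): the field at each channel position
projected on its unit sensitive axis, per unit dipole along each Cartesian
direction. Source grids are regular lattices (default 4 mm) restricted to
the source sphere, ordered x-fastest; voxels within 1 mm of the centre are
masked because the tangential/radial decomposition degenerates there.

Sensor sites are placed by a Fibonacci lattice over the spherical cap
covering the upper 65 % of the helmet sphere — a deterministic, quasi-uniform
stand-in for a real helmet layout. Triaxial sites carry a radial plus two
tangential orthonormal axes.

## Synthetic sessions

* **Steady-state visual source.** An occipital dipole at (0, −60, 20) mm,
  tangentially oriented, driven by a harmonic series (weights 1, 0.25) at the
  trial's flicker frequency (4, 6 or 8 Hz), gated 2 s on / 2 s off, 40 trials
  per frequency in pseudorandom order (120 trials, 480 s). Default amplitude
  8 nA·m, a typical evoked-response moment.
* **Frontal-midline theta source.** A frontal dipole at (0, 55, 35) mm whose
  moment is band-limited 4–8 Hz Gaussian noise with envelope
  1 + ΔA during 20 s task blocks (25 trials of 20 s on / 20 s off, 1000 s).
  The default amplitude, 3 nA·m, is calibrated so that the beamformer-
  projected rest-theta amplitude sits about 4× above the projected
  empty-room floor, matching the reported task-data-to-noise relation; the
  default task increase ΔA = 0.5 gives single-session envelope SNRs of
  roughly 2–3, in the range of the reported per-subject values.
* **Sensor noise.** Independent per channel, synthesised by FFT-shaping white
  Gaussian noise to the amplitude spectral density
  `floor · sqrt(1 + knee/f)` (the 1/f term is capped below 0.05 Hz). The OPM
  defaults floor = 12.2589 fT/√Hz, knee = 4.7039 Hz are the unique values for
  which the band means equal the published empty-room floors of 16.5 fT/√Hz
  (4–8 Hz) and 13.6 fT/√Hz (13–30 Hz). The cryogenic reference uses a flat
  8 fT/√Hz floor.
* **Uniform interference.** One 3-vector field time course projected on every
  channel axis: strong drifts below 3 Hz (1000 fT/√Hz per component — the
  band the dynamic coil stabilisation handles) plus a small broadband
  spatially-uniform floor (5 fT/√Hz) standing for remnant shielded-room
  interference; >99 % of the power is below 3 Hz. Being spatially uniform, it
  lies exactly in the null space of the homogeneous-field-correction
  projector. The cryogenic sessions are simulated interference-free: that
  system's synthetic gradiometry, which removes such interference in
  practice, is out of scope and modelled as already applied.
* **Movement artefact.** Rigid-body motion (smooth low-pass random rotations,
  default 2° RMS below 1 Hz, and 5 mm RMS translations) inside a static
  residual field B(p) = B0 + G·p produces channel signals
  (R ô)·B(R p + d) − ô·B(p). The OPM sessions move inside a 0.3 nT residual
  field; the cryogenic sessions are motionless.
* **Cohorts.** Each subject's dipole geometry — position jittered with
  σ = 5 mm and orientation drawn uniformly in the local tangent plane (a
  stand-in for between-subject differences in cortical folding) — is shared
  between that subject's two sessions; the theta task increase is log-normal
  (median 0.5, σ_log = 0.4); noise, interference and the theta carrier are
  independent per session. This gives fingerprinting a recoverable
  within-subject signature with honest between-session variability.

All randomness flows from named, CRC-derived sub-seeds of a master seed, so
sessions, cohorts and whole studies are bit-reproducible.

## Field nulling

The static background field is modelled to first spherical-harmonic order:
three uniform components and five independent linear gradients (G symmetric,
traceless, Gzz = −Gxx − Gyy) — exactly the patterns a bi-planar coil can
produce. The fit solves `m = ô·(B0 + G p)` by least squares over the 8
parameters from measurements taken by 5 tracked, moving triaxial sensors;
rank-deficient designs (insufficient motion) raise an error naming the
unconstrained parameters. The simulated procedure uses ±10° rotations and
±5 cm translations over 30 s at 1200 Hz (decimated ×10 for the fit),
15 fT/√Hz measurement noise and 0.1 mm / 0.1° RMS tracking noise — plausible
values for an optical tracker, exposed as configuration. Iterating feeds the
residual (truth − estimate) forward. Under these defaults the residual after
two iterations is far below the 300 pT target; the real procedure is limited
by systematics (coil imperfections, higher-order field structure) that are
deliberately outside this model.

The worst-case change of a measured field component when a sensitive axis
rotates by θ in a uniform field |B| is the chord length 2 |B| sin(θ/2):
52 pT for 1° in 3 nT, 0.62 nT for a full 180° rotation in a 0.31 nT
residual.

## Preprocessing

Zero-phase (two-pass) 4th-order Butterworth filters, broadband 1–40 Hz or
narrowband f0 ± 2 Hz, applied as second-order sections with odd-reflection
padding of 3·(order+1) samples. Trials are [0, window) s after each event;
truncated trials are dropped and logged. Bad-trial rejection pools variance
over channels and samples into one scalar per trial and removes trials above
mean + 3 sd in a single pass ("three standard deviations" is read as a
mean-offset rule, the standard outlier convention; the same rule applied
across channels gives bad-channel rejection). Homogeneous field correction
is the orthogonal projector I − N N⁺ built from the channels × 3 axis
matrix; it exactly annihilates any spatially uniform field, is idempotent,
and never increases the data norm. When data are HFC-projected, lead fields
are projected with the same operator before beamforming so the measurement
model stays consistent. Radial-only selection keeps, per site, the axis with
the largest |cosine| to the outward sphere normal.

## Beamforming and pseudo-T imaging

Covariance is the sample covariance of the whole experiment's concatenated
good-trial samples (globally demeaned per channel), regularised by adding
2 % of the largest eigenvalue to the diagonal (Tikhonov). For each voxel the
source orientation is the direction maximising unit-gain projected power.
In a spherical conductor the radial column of the lead field is identically
zero, so the orientation search is restricted to the 2-dimensional column
space of Lᵀ (top two right singular vectors); there the optimum is the
eigenvector of the smallest eigenvalue of the reduced Lᵀ C⁻¹ L. Orientation
signs are fixed towards +z for reproducible virtual electrodes. Weights are
`w = C⁻¹ L η / (ηᵀ Lᵀ C⁻¹ L η)` (unit gain, wᵀLη = 1; note this constraint
pins the scale of w, which is therefore invariant to a global rescaling of
the data). Task-vs-rest power contrast per voxel is the pseudo-T

    T = (wᵀ C_on w − wᵀ C_off w) / (2 wᵀ C_off w),

with theta contrast windows 5–20 s (task) and 24–39 s (rest) of each 40 s
trial, and visual windows 0–2 s / 2–4 s per narrowband (4/6/8 Hz) contrast,
the three visual images being averaged into one. Peaks are argmax within a
region mask; the "frontal" and "visual" masks are the anterior and posterior
thirds (by y) of the source sphere — synthetic stand-ins for anatomical
lobes. A two-stage search (8 mm whole-volume scan, then a 4 mm lattice
within ±8 mm of the coarse peak) gives 4 mm localisation at a fraction of
the full-grid cost. Virtual electrodes are wᵀ·data, normalised to unit
standard deviation; empty-room recordings are projected through the
task-derived weights unchanged.

## Spectral metrics

Trial Fourier spectra use rectangular windows on the exact on/off windows,
one-sided 2/N amplitude normalisation, averaged over trials. Welch amplitude
spectral densities use 20 s Hann segments with 10 s overlap (the overlap is
prescribed; the segment length is our choice, logged as open). Hilbert
envelopes are |analytic signal| per trial, trial-averaged, with the first
and last 0.5 s of each trial excluded from statistics; the baseline is the
mean envelope over the rest window and relative change is
(envelope − baseline)/baseline. Visual SNR is the on-window amplitude at the
fundamental divided by the mean off-window amplitude in a 4 Hz band around
it. Theta SNR is (mean task − mean rest)/sd rest of the trial-averaged
envelope. The instantaneous SNR time course is
(envelope(t) − mean rest)/sd rest — baseline-referenced so that its rest
mean is zero and its task-minus-rest mean equals the theta SNR exactly.

## Comparison statistics

Per-subject SNR pairs are compared by ordinary least squares of the test
system on the reference system with intercept (slope 1 = parity), with
Pearson r and its two-sided p. Group slopes pass through the task- and
rest-window means of the cohort-averaged instantaneous SNR curves.
Fingerprinting correlates (Pearson, over jointly valid voxels) each
subject's image from one system with every subject's image from the other:
n² pairs, n within-subject. Significance of within-minus-between uses a
Monte-Carlo null: each iteration redraws uniformly without replacement which
n of the n² correlations are labelled "within"; p = (1 + exceedances)/(1 +
iterations), one-sided, with a relative 1e−12 tolerance so exact
floating-point ties count as exceedances (the observed labelling itself can
be redrawn). An exhaustive enumerator over all C(n², n) labellings provides
the small-n oracle. Identification counts rows whose maximum is on the
diagonal; exact ties count as failures. Rank-sum comparisons use the
two-sided Wilcoxon rank-sum (Mann–Whitney) test, exact by enumeration for
combined n ≤ 20 without ties.

## Problem sizes

The generator defaults are the full study conditions (1200 Hz, 120 visual /
25 theta trials, 4 mm grids, cohort 14, 100 000 Monte-Carlo iterations).
The test suite and the bundled study configurations run reduced versions of
the same pipeline — 150–240 Hz sampling, 6–25 trials of 10 s on / 10 s off,
8 mm scans with 4 mm refinement, cohorts of 6–8, 20 000 iterations — chosen
so the whole suite runs in minutes on one CPU while exercising every stage
at honest signal-to-noise ratios.

## Limitations

Spherical heads and single-dipole "networks" understate real anatomical and
functional between-subject diversity, so absolute fingerprinting
correlations here are not comparable to human values (the within/between
gap, not its size, is the tested property). Sensor noise is Gaussian and
stationary; no cardiac or ocular sources, no sensor gain errors or
cross-talk, no dynamic (<3 Hz) closed-loop compensation (the starting field
magnitude knob stands in for it). The nulling simulation omits coil
systematics and higher-order field structure, so its residuals are
noise-limited and much smaller than practically achievable values.
Movement artefacts are band-limited below ~1 Hz and are therefore largely
removed by the theta band-pass; their main effect in practice — dynamic
range and cross-axis projection errors in the sensors — is not modelled.
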