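# Methods

## Optical model

A fluorophore is an oscillating electric dipole at height `z0` in the
sample medium (index `n0 = 1.33`) above the glass coverslip
(`n1 = 1.515`), imaged through the glass by an aplanatic objective of
aperture `NA_obj = 1.45`. The collected far field is computed by the
reciprocity method: the amplitude coupled into a collection direction
equals the dipole moment projected on the field that a unit plane wave,
sent back along that direction from the glass side, produces at the
emitter position. This form carries the glass-side Fresnel transmission
factors

    t_s = 2 n1 c1 / (n1 c1 + n0 c0),   t_p = 2 n1 c1 / (n0 c1 + n1 c0),

with `c1 = cos θ_glass` and `c0 = cos θ_sample` continued to imaginary
values above the critical aperture (`NA > n0`), which reproduces the
bright super-critical ring of interface-bound emitters. Standoff `z0`
enters as `exp(i k n0 c0 z0)` (a decay for the evanescent-coupled band),
defocus `z1` as the pupil phase `exp(i k n1 c1 z1)`, and the aplanatic
mapping as a `1/√c1` apodization of the pupil amplitude. Back-reflection
corrections are not applied; the detection diaphragms sit below the
critical aperture (`NA_high ≤ n0` is enforced), so the channels never see
the super-critical band anyway.

Coordinates are right-handed with z the optical axis toward the objective;
ξ is measured counter-clockwise from +x in [0°, 180°); η from +z, so
η = 0° is off-plane (vertical) and η = 90° in-plane. Pixels are 0-based
with centres at integer coordinates.

### Channels

A 50/50 splitter feeds two arms. The low-NA arm (circular diaphragm,
default `NA_low = 1.1`) is split by a Wollaston prism into 0° and 90°
analyzers; the high-NA arm (`NA_high = 1.3`) passes a half-wave plate that
rotates the polarization by 45° before an identical Wollaston, yielding
effective 45°/135° projections. The assignment of analyzer pairs to arms
is configurable. Analyzers and the splitter are ideal in theory mode; real
per-channel gains are absorbed by the measured calibration matrix.

### Basis PSFs and the integrated matrix

The polarized image of channel c is quadratic in the dipole field, hence
linear in the six second-order moments:
`I_c(r) = Σ_j B_cj(r) m_j`, j ∈ {xx, yy, zz, xy, xz, yz}. The basis
images `B_cj` are products of the image-plane amplitudes of the three unit
dipoles, evaluated by a chirp-z transform of the 256²-sample pupil onto a
camera patch oversampled 4× relative to the 130 nm pixel and then
area-binned. Aperture masks are anti-aliased over one pupil sample. Over
centred circular apertures the integrals of the xz/yz components vanish
(odd symmetry), which is exactly why only four moment components are
measurable from integrated intensities; the rendered xz/yz images still
shape the PSFs (they shift the lobes of tilted fixed dipoles).

The integrated matrix `⟨K⟩` is evaluated by direct pupil quadrature (free
of image-window truncation). The rendered basis images of the four
accessible components are flux-renormalised (factors ≈ 1.00–1.03) so that
their patch integrals reproduce `⟨K⟩` exactly: image rendering and
integrated-intensity bookkeeping then agree to machine precision, and a
finite rendering window does not leak photons. Quadrature error of `⟨K⟩`
is < 0.5 % per entry against a 2×-refined grid (tested).

### Photon normalisation

A molecule's photon budget N is defined **before** the channel split and
NA reduction: the rendered fields are scaled so that the power collected
at the full objective aperture equals N. The four channels then share
N × (collection factor), typically 0.31–0.57 depending on orientation
(vertical dipoles lose more to the undetected super-critical band).

### Collection fraction

`collection_fraction` integrates the pupil radiance radially
(adaptive quadrature). For an emitter with no net transverse polarization
(incoherent x+y dipole mixture — an "unpolarized" source in the optical
sense), the NA 1.3 diaphragm keeps 60.0 % of the signal collected at
NA 1.45; for a 3D-isotropic emitter (x+y+z) the figure is 50.3 %, because
the z-dipole's weight is concentrated at high angles. The published
throughput statement ("about 60 %") corresponds to the transverse-emitter
model, which is what the acceptance script reports; both models and both
normalisations (vs NA_obj-collected or vs total emitted power, the latter
including the interface-reflected upward radiation) are exposed.

## Orientation and wobble

Wobble is uniform in solid angle inside a cone of **full apex angle** δ
about the mean axis (a half-angle convention would halve all δ values);
the cone order parameter is γ(δ) = c(1+c)/2 with c = cos(δ/2), from the
cone-frame axial moment (1 + c + c²)/3. Retrieval inverts `⟨K⟩`,
renormalises the moments to unit trace (which removes the unknown
per-molecule intensity scale), clips into the physical set (non-negative
diagonal, |m_xy| ≤ √(m_xx m_yy)) with a flag, and applies the closed-form
inversion. Records whose analytic solution leaves the model manifold
(negative order parameter, sin²η argument > 1) are refit by bounded least
squares from the clipped analytic start and flagged `refined`; ξ-undefined
situations (vertical dipole, isotropic wobble) are flagged, never dropped
— dropping is the confidence filter's job. A Poisson-weighted
intensity-space minimisation (`orientation_from_intensities`) is available
as a refinement pass; on simulated data its precision matches the analytic
inversion (the system is exactly identified), so the fast closed form is
the default.

## Detection, estimation, pairing

Detection compares, under a Gaussian noise model in an 11×11 window, a
fixed-radius Gaussian peak + offset against offset-only; the statistic
`N ln(SSE0/SSE1)` is thresholded at the one-sided χ²₁ quantile of the
false-alarm probability (default 10⁻³; empirical null rate is below
2× nominal, tested), and candidates are local maxima at integer pixels.
The fixed detection radius defaults to the model-predicted Gaussian radius
of an in-plane wobbling molecule (η = 90°, δ = 100°), ≈ 0.88 px for the
default optics.

Intensities are estimated three ways: symmetric Gaussian and rotated
elliptical Gaussian fits (batched Levenberg–Marquardt, sub-pixel
positions, intensity = fitted volume, per-parameter precision from the
Fisher matrix of the Gaussian model), and box integration over the 11×11
window minus the median of a 2-pixel annulus. Gaussian fits that converge
to degenerate solutions — width filling the window or volume well beyond
the window's background-subtracted content, typical for a nearly dark
channel — are flagged and fall back to box integration. Pairing maps all
channels into the I0 frame (affine registration), then matches mutual
nearest neighbours within 3× the combined fitted localization precision,
first inside each Wollaston pair and then across arms; the fused position
is the intensity-weighted mean. Unpaired detections are counted and
discarded.

The estimator systematically captures only part of the PSF flux
(~0.80–0.86 for the Gaussian fits, ~0.90–0.95 for box, channel- and
shape-dependent). As on the real instrument, this response is absorbed by
the calibration: the default "synthetic bead calibration" renders the
polarizer-sweep states (in-plane dipole moments (cos²θ, sin²θ, 0,
sinθcosθ)) and the unpolarized state, estimates their intensities **with
the same estimator the pipeline uses**, and fits the sinusoid
a + b cos2θ + d sin2θ per channel; the zz column comes from the
unpolarized frame (without it the calibration correctly fails as
degenerate). The residual orientation dependence of the estimator response
(±2–4 %) is the main source of retrieval inaccuracy at extreme angles.

## CRLB

The Fisher information of (η, ξ, δ) is computed from the four integrated
intensities under Poisson noise, `FIM = Jᵀ diag(1/(I_c + B_c)) J`, with an
analytic Jacobian through the moment map and the collection normalisation
(validated against finite differences to 10⁻⁶). Background enters
aggregated over the estimation footprint; the default is the effective
Gaussian area 4π σ_psf² ≈ 21 px (≈ 210 photons/channel at 10 ph/px), which
reproduces the published bound levels — aggregating over the full 11×11
window (1210 photons) instead inflates the δ-bound floor from ≈ 8.0° to
≈ 16.7° and is available as an option. The bounds assume the photon scale
known; `unknown_scale=True` marginalises the per-molecule scale (Schur
complement), which is the honest reference for the actual retrieval (it
estimates the scale from the same four numbers) and is used in the
MC-vs-CRLB checks. Bounds are reported in degrees; ill-defined parameters
return infinite bounds with a flag.

## Synthetic data

Scenes use a counter-based generator (Philox), fully determined by the
seed. The default conditions are the published Monte-Carlo regime: ten
molecules per 64×64-pixel frame (≥ 8 px separation, 6 px margin), mean
directions area-uniform on the upper hemisphere, δ = 100°, 5000
photons/molecule, 10 background photons per pixel per channel. Structured
scenes: membrane-coated spheres (dipoles along the local normal, optional
label tilt, imaging planes from the contact point to ≤ 600 nm) and 3D
filament segments (label offset 20° from the axis by default, random
azimuth). Rendering quantises sub-pixel positions to the 4× oversampling
(32.5 nm); the ground-truth table records the positions as rendered, so
localization errors are measured against the true rendered position.
Aberrations are Noll-indexed Zernike pupil phases applied identically to
both arms; they deform PSF shapes but leave integrated ratios untouched
(pure phase), matching the method's aberration-robustness argument.
Excitation photoselection is assumed isotropic, so N is
orientation-independent. Blinking kinetics, EMCCD excess noise and
chromatic effects are not modelled.

What passing tests on these data do **not** show: real stacks add gain
maps, aberrated and z-extended PSFs, partially polarized bead calibrations
and labelling heterogeneity; the synthetic results are the noise-limited
best case of the idealised optical chain.

## Precision definition

Monte-Carlo "precision" is everywhere the robust SD — half the central
68.3 % percentile interval, equal to the standard deviation for Gaussian
errors. Angle retrievals near ill-defined regions and Gaussian fits on
donut-shaped off-plane PSFs produce rare heavy-tailed outliers that would
otherwise dominate a plain standard deviation at desk-scale repeat counts.
Bias is always the plain mean.

## Problem sizes

The validation script uses 10,000 molecules (1000 frames) for the
population statistics, 200 repeats per orientation grid point
(η ∈ {20°, 45°, 70°, 90°}, ξ ∈ {0°, 60°, 120°}, δ ∈ {30°, 100°, 150°} —
the method's stated operating range) for the localization study, and a
5°/5° (η, δ) grid for the CRLB floor; the test suite runs reduced versions
of the same computations. Both complete in a few minutes on one CPU.

## Known limitations and open points

- **Population misclassification.** Simulating uniformly random
  orientations at δ = 100°, 5000 photons and 10 bg/px and binning η at
  30°/60° gives per-ground-truth-class wrong-bin fractions of roughly
  19 % (off-plane), 39 % (intermediate) and 28 % (in-plane) through the
  full pipeline. These are close to what the measurement physics allows:
  the scale-marginalised CRLB of η at the 30° boundary is ≈ 5.5–6°, which
  already implies ≥ 15 % wrong-bin for the off-plane class for any
  unbiased estimator on the four integrated intensities, and the
  implemented estimator operates near that bound (verified directly and
  via an intensity-space MLE that matches it). Published wrong-bin figures
  much smaller than this (≈ 1 % off-plane) cannot be reached under these
  conditions within this model; per-retrieved-class and
  population-count-difference readings of the statistic were also computed
  and do not close the gap. The pipeline reports the honest measured
  rates.
- At exactly (η = 90°, ξ = 0°, δ = 100°) the two high-NA channels
  marginally outshine I0 (by ≈ 4 %) in the equal-gain model; I0 dominates
  strictly for δ ≲ 90°.
- The box estimator's localization precision at the extreme corner of the
  operating grid (η = 20°, δ = 30°) sits at 20–22 nm, marginally above
  the 20 nm envelope of the Gaussian estimators.
- The calibration assumes an ideal rotating polarizer and a fully
  depolarized bead; partial bead polarization would bias the zz column.
- Registration is a single global affine per channel; field-dependent
  distortion and chromatic calibration are out of scope.
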