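# Methods

This note documents the models implemented in `fiberwall`, the choices made
where the methodology was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Fiber orientation model

A fiber direction in the arterial wall is the unit vector
`N(Φ,Θ) = cosΘcosΦ e_θ + cosΘsinΦ e_z + sinΘ e_r` with in-plane angle Φ
(from the circumferential axis, in the circumferential–longitudinal plane)
and out-of-plane elevation Θ (toward the radial axis). The orientation
density factorizes, `ρ(N) = ρ_ip(Φ) ρ_op(Θ)`, with π-periodic in-plane and
even out-of-plane von Mises-type components governed by concentration
parameters `a, b ≥ 0`. The normalizations are `(1/2π)∫ρ_ip dΦ = 1` over a
full turn and `(1/2)∫ρ_op cosΘ dΘ = 1` over [−π/2, π/2] (spherical area
weight). Each density is condensed into one scalar: `κ_ip(a)` decreasing
from 1/2 (in-plane isotropy) to 0 (perfect alignment) and `κ_op(b)`
increasing from 1/3 (3-D isotropy) to 1/2 (no out-of-plane excursion).
`κ_op` equals the moment `(1/4)∫ρ_op cos³Θ dΘ`, which the closed form must
and does reproduce to 1e−10 (checked by quadrature in the tests).

Numerical care: the Bessel ratio `I₁/I₀` is evaluated with exponentially
scaled Bessels (`i1e/i0e`) so κ_ip is stable to a = 10⁶ and beyond; the
κ_op expression is 0/0 at b = 0 and is replaced below b = 1e−8 by its
series `1/3 + 4b/45`; ρ_op's b → 0 limit is the constant density 1.

Two symmetric collagen families at ±α share `a`; the single-family density
peaks at +α and an equal-weight mixture
`½[ρ_ip(Φ; a, +α) + ρ_ip(Φ; a, −α)]` represents the pair. Profile fitting
offers both; the stack pipeline defaults to trying both per image and
keeping the better profile fit, because single images may show one family
or both. Fitted peak locations are folded into [0°, 90°] from the
circumferential axis (a peak at 130° is the mirror family of 50°). Ties in
peak finding resolve toward the smaller angle via the argmax convention.

## Orientation extraction from images

Preprocessing (in order): clip intensities above the 99.9th percentile
(white-noise/calcification speckle), 3×3 median filter, min–max
normalization to [0, 1], second 3×3 median filter, 2–98 percentile contrast
stretch. Kernel sizes and percentiles are configurable; the defaults are
explicit choices, not inferred from any source, and a constant image passes
through unchanged with a warning.

Wedge filtering: the mean-subtracted image is windowed with a separable
Hann (raised-cosine) window to suppress the edge-discontinuity cross in the
spectrum, 2-D FFT power is computed, and power is summed over half-open 5°
angular wedges within a radial band of 1/20 to 1/4 of the Nyquist frequency
(excludes the DC/illumination pedestal and pixel-level noise). Spectral
energy of an oriented structure lies perpendicular to it, so spectral wedge
angles are rotated by 90° to spatial fiber angles; the convention is
counterclockwise from the horizontal (circumferential) axis in a y-up
frame, reported modulo 180°, and is pinned by rotation-equivariance tests.
Amplitudes are normalized to sum to one, making the distribution invariant
to intensity scaling.

Out-of-plane (circumferential–radial) images use the same machinery; wedge
centers c ∈ [0°, 180°) are wrapped to elevations Θ = ((c + 90) mod 180) − 90
so the fitted ρ_op peak is constrained to the circumferential axis.

### Isotropy screening and its calibration

An image is called isotropic when a first-order polynomial fitted to the
cumulative angular amplitude curve achieves R² ≥ 0.9998 (a uniform density
has an exactly linear cumulative curve; peaked densities bend it into a
sigmoid). The cumulative formulation is our resolution of an ambiguous
verbal prescription — a line fits a flat density trivially but with
undefined R² — and the threshold is configurable.

The default threshold presumes effectively noise-free profiles. A
single-image periodogram estimate carries χ² spectral sampling noise whose
cumulative-linearity floor we measured at ≈0.993 (256 px), ≈0.998 (512 px),
≈0.9996 (1024 px) and ≈0.99996 (2048 px, where white noise is classified
isotropic with margin); rasterized synthetic fiber images additionally
saturate near 0.992–0.9996 from orientation-dependent rasterization energy,
independent of fiber count. Consequently, isotropy classification of small
synthetic renders requires either spectrum averaging or a threshold matched
to the sampling floor; the tests exercise the screen at the default
threshold where the profiles support it (exact uniform profiles,
acquisition-scale noise images) and at a sampling-matched threshold for
small rendered images. Real stacks averaged through the thickness sit much
closer to the noise-free regime.

### Stack aggregation

Per specimen: the mean fiber angle α is the mean of the anisotropic
in-plane peak locations and its spread their standard deviation (the
"mean ± SD of peak locations" phrasing in the source field is ambiguous
about the estimator; we report both). κ_ip and κ_op are evaluated at the
mean concentration parameters, with isotropic images contributing a = 0 or
b = 0 to the means by default (configurable exclusion).

## Constitutive models

Deformation is an incompressible planar biaxial state,
`C = diag(λ_θ², λ_z², λ_r²)` with `λ_r = 1/(λ_θ λ_z)` by construction. The
measured structure enters through generalized structure tensors
`H_i = A I + B M_i⊗M_i + (1−3A−B) M_n⊗M_n`, `A = 2κ_op κ_ip`,
`B = 2κ_op(1 − 2κ_ip)`, mean directions `M = cosα e_θ ± sinα e_z`, normal
`M_n = e_r`. The fiber strain-like quantity
`E = H : (C − I) = A I₁ + B I_i + (1−3A−B) I_n − 1` is identical for both
collagen families. Structural constants are measured inputs and are never
fitted.

Two-fiber model: `Ψ = (c₂/2)(I₁−3) + Σ₂ k₁/(2k₂)[exp(k₂E²)−1]`, giving
planar biaxial stresses `σ_θθ = [c₂ + 4(A + Bcos²α)ψ′]λ_θ² − p` (and the
z-analog with sin²α), `p = [c₂ + 4(1−2A−B)ψ′]λ_r²`,
`ψ′ = k₁E exp(k₂E²)`. Four-fiber model: adds perfectly aligned longitudinal
elastin (E_el = λ_z² − 1) and circumferential smooth muscle
(E_smc = λ_θ² − 1), each with energy prefactor k₁/(4k₂); the collagen
stress coefficient is then `2(A + Bcos²α)ψ′_col`. The printed source
stress expressions for the four-fiber model contain a typographically
garbled brace placement; the implementation uses the form re-derived from
the energy via `σ = −pI + 2F(∂Ψ/∂C)Fᵀ`, under which every bracketed
stiffness term multiplies λ_θ² (resp. λ_z²). This derivation is enforced in
the test suite by central finite differences of the strain energy at
relative tolerance 1e−6, for random admissible parameter draws of both
models, and the model nesting (four-fiber with elastin/SMC off and
k1col = 2k₁ reduces exactly to two-fiber) is asserted to machine precision.

No tension–compression switch is applied to the fiber terms — the model as
formulated carries none — but a `tension_only` flag (default off) exposes
the convention for sensitivity studies. All parameters are nonnegative
(material stability; every published cohort value is ≥ 0), and stresses,
stiffness-like parameters, and energies are in kPa.

## Fitting, bootstrap, goodness of fit

The error function is the plain summed squared stress residual over all
points and both directions (kPa²). Minimization uses
`scipy.optimize.least_squares` with the trust-region-reflective method — a
damped (Levenberg–Marquardt-class) least-squares solver that, unlike plain
LM, honors the nonnegativity bounds — with tolerances ftol 1e−10 / xtol
1e−12 and at most 2000 evaluations per start. Because the exponential
stress terms create local minima, fitting multi-starts from one
deterministic unit start plus log-uniform draws: stiffness-like parameters
on [1e−2, 1e3] kPa, exponents on [1e−2, 1e2], 20 starts by default, all
driven by a caller seed.

The non-parametric bootstrap resamples individual stress–stretch records
with replacement (a per-protocol block bootstrap is available, since
"random sampling" admits both readings), refits each resample from a
randomly perturbed copy of the point estimate, and summarizes each
parameter marginal. The selected estimate defaults to the highest-density
KDE mode of each marginal — our reading of "analyze the distribution to
determine the global minimum" — with a best-SSE alternative. Coverage of
the central 95% bootstrap interval is verified by simulation at 2% noise.

R² is computed per loading direction as `1 − SS_res/SS_tot` with squared
residuals and squared deviations from the mean experimental stress. The
printed source formula omits the squares, which would make it a
dimensionally inconsistent ratio of signed sums; the standard coefficient
of determination is implemented instead.

## Synthetic data: what it emulates and what it does not

`make_protocols` reproduces the multi-ratio biaxial design: stretch ratios
θ:z of 1:0.1 … 1:0.9 and 0.9:1 … 0.1:1 in 0.1 steps plus three equibiaxial
repeats — 21 protocols, each a monotone linear stretch path from (1, 1)
discretized at 50 steps by default. With the default maximum stretch 1.3
this yields ~1000–2000 points per specimen, a deliberate desk-scale choice
against the ~21000–42000 points of a full experimental record; recovery
accuracy at this density is already solver-limited, not data-limited. The
noise model (2% multiplicative + 0.5 kPa additive Gaussian, seeded) is our
choice of a realistic load-cell/marker-tracking error scale. Quasi-static
behavior is assumed throughout; strain rate is not modeled.

`render_fiber_image` draws bright anti-aliased fiber chords whose
orientations are sampled (by rejection) from the ±α mixture or from ρ_op,
with optional sinusoidal undulation and Gaussian background noise. It
emulates orientation statistics, not microscopy: no point-spread function,
no depth attenuation, no fiber-diameter distribution, no speckle
statistics of real second-harmonic imaging. Passing recovery tests
therefore demonstrates that the wedge-filter + von Mises chain measures
orientation concentration correctly on textures with known ground truth —
not that it is robust to every real acquisition artifact. Recovery of the
rendered concentration has a small systematic broadening (finite fiber
width and rasterization), well inside the stated tolerances (α within 3°,
κ_ip within 0.05).

`synth_cohort` imposes a linear age trend on κ_op (defaults: 0.0011 per
year from 0.37, matching the packaged cohort's fitted trend), uniform ages
on [12, 70] years, a trend-free κ_ip around 0.16, and a mildly decreasing
mean fiber angle.

## Cohort statistics

Pearson r with the exact two-sided t-test (t = r√(n−2)/√(1−r²), n−2 d.f.),
OLS trend lines, sample (n−1) standard deviations, and pairwise deletion of
missing values. Recomputing the κ_op–age correlation from the packaged
table's rounded values gives r ≈ 0.67 (p ≈ 0.009), slightly below the 0.70
obtainable from unrounded data; the trend line's slope and intercept
(0.0011, 0.37) are insensitive to the rounding. Comparisons against
printed values use round-half-away-from-zero at the printed precision.

## Known limitations

- Shear deformation modes, residual stress, viscoelasticity, layer-specific
  mechanics, and active smooth-muscle contraction are out of scope.
- The image pipeline analyzes whole 2-D images; volumetric structure
  tensors and fiber tracing are not implemented.
- The isotropy threshold's calibration depends on the spectral sampling
  noise of the input (see above).
- Bootstrap refits are warm-started from the point estimate for speed; a
  pathologically multimodal posterior could in principle be explored
  incompletely, which is why the multi-start point fit and the mode/best-SSE
  alternatives are both exposed.
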