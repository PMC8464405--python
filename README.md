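# fiberwall

Structure-informed constitutive modeling of the arterial wall, from fibrous
texture images to fitted anisotropic hyperelastic material parameters.

The package is aimed at soft-tissue biomechanics researchers who combine
multiphoton imaging of collagen architecture (e.g. second-harmonic
generation) with planar biaxial mechanical testing of arteries. It covers
the full chain:

1. **Fiber orientation extraction** — grayscale texture images are
   despeckled and contrast-enhanced, then converted into angular
   distributions of relative fiber amplitude by 2-D Fourier power-spectrum
   analysis with 5° wedge filtering.
2. **Dispersion modeling** — orientation profiles are fitted with bivariate
   von Mises densities: in-plane
   `ρ_ip(Φ) = exp[a cos 2(Φ − α)] / I₀(a)` and out-of-plane
   `ρ_op(Θ) = 2√(2b/π) exp[b(cos 2Θ − 1)] / erf(√(2b))`, condensed into the
   dispersion parameters `κ_ip = 1/2 − I₁(a)/(2I₀(a))` ∈ [0, 1] and
   `κ_op = 1/2 − 1/(8b) + (1/4)√(2/(πb)) e^{−2b}/erf(√(2b))` ∈ [0, 1/2].
   Perfect alignment corresponds to κ_ip = 0, κ_op = 1/2.
3. **Constitutive modeling** — two- and four-fiber-family invariant-based
   incompressible hyperelastic models built on generalized structure tensors
   `H = A I + B M⊗M + (1 − 3A − B) Mₙ⊗Mₙ` with `A = 2κ_op κ_ip`,
   `B = 2κ_op(1 − 2κ_ip)`. The two-fiber model sums a neo-Hookean ground
   substance `(c₂/2)(I₁ − 3)` and two symmetric dispersed collagen families
   with exponential stiffening `k₁/(2k₂)[exp(k₂E²) − 1]`,
   `E = H : (C − I)`; the four-fiber model adds perfectly aligned
   longitudinal elastin and circumferential smooth muscle. Planar biaxial
   Cauchy stresses follow with the Lagrange pressure eliminated through the
   traction-free radial face.
4. **Fitting and identifiability** — bounded damped least squares with
   multi-start minimizes the summed squared stress residual over all
   protocols and both directions; a non-parametric bootstrap (resample
   records, refit, read off the highest-density mode of each marginal)
   probes parameter uniqueness. Goodness of fit is R² per direction.
5. **Cohort statistics** — Pearson age correlations with exact t-tests and
   OLS trends over the packaged 14-specimen superficial femoral artery
   tables.
6. **Synthetic data** — because the underlying raw study data are not
   publicly deposited, the package generates every input it needs: 21
   multi-ratio stretch protocols pushed through the forward models with a
   measurement-noise model, rendered fiber-texture images with orientations
   sampled from the von Mises densities, and cohorts with imposed age
   trends.

## Worked example

```python
import fiberwall as fw

# 1) Orientation/dispersion from a synthetic image stack with known truth:
#    fibers drawn from the ±45° mixture at concentration a = 4
stack = [fw.render_fiber_image(a=4.0, alpha_deg=45.0, seed=s) for s in range(5)]
structure = fw.stack_pipeline(stack)
print(structure.alpha_deg, structure.alpha_sd_deg)   # 45.8 ± 1.3 degrees
print(structure.kappa_ip)                            # 0.095 (truth 0.068)

# 2) Fit the two-fiber model to a simulated multi-protocol biaxial test
sc = fw.StructuralConstants.from_degrees(45.0, 0.16, 0.42)
truth = fw.TwoFiberParams(c2=15.0, k1=12.0, k2=3.5)   # kPa, kPa, –
data = fw.simulate_biaxial(truth, sc, fw.make_protocols(1.3, 1.3),
                           fw.NoiseModel(0.02, 0.5, seed=1))
res = fw.fit(data, "two_fiber", seed=0)
print(res.params.to_dict())        # {'c2': 15.21, 'k1': 11.55, 'k2': 3.64}
print(res.r2_theta, res.r2_z)      # 0.997 0.997

# 3) Age trend of the out-of-plane dispersion over the packaged cohort
trend = fw.age_trend_kop(fw.load_table2())
print(trend.slope, trend.intercept)  # 0.0011, 0.37  (κ_op per year, κ_op)
```

The recovered mean fiber angle (45.8°) and dispersion (κ_ip = 0.095) come
from re-measuring rendered images through the full preprocessing + wedge
filter + von Mises fit chain; the fitted stiffness parameters land within a
few percent of the generating truth despite 2% multiplicative + 0.5 kPa
additive stress noise; and the cohort trend line says the out-of-plane
dispersion increases by ≈0.0011 per year of age from a baseline of 0.37,
i.e. older specimens have tighter circumferential–radial fiber alignment.

A command-line interface mirrors the library:

```sh
fiberwall orient --stack stack.tif --plane in_plane --wedge 5 --out report.json
fiberwall fit --data specimen.csv --model four_fiber --structure report.json --seed 7
fiberwall cohort --out summary.json
fiberwall synth biaxial --seed 3 --out synthetic.csv
fiberwall run --config run.yaml
```

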