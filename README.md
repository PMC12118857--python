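# vegpattern

Spatial vegetation patterns — spots, labyrinths, gaps and stripes in
dryland ecosystems — are classically explained by deterministic
self-organization: scale-dependent feedbacks (plants concentrate water
under themselves and deplete it around them) amplify perturbations at a
characteristic wavelength.  Deterministic models in idealized
homogeneous environments, however, produce nearly crystalline, periodic
patterns, while natural ones are only moderately regular.  `vegpattern`
implements the complementary stochastic view: patterns form by
*filtering* of random exogenous heterogeneity (soil properties,
microtopography), which explains the intermediate regularity of real
patterns and lets them be synthesized by simple linear filters.

The toolkit is aimed at researchers in spatial ecology and ecohydrology
who want to

* **simulate** nonlinear reaction–advection–diffusion models with
  spatially varying coefficients — a one-equation grazing model for
  irregular patterns and the three-field water–vegetation model
  (biomass `b`, soil moisture `w`, surface water `h`) for regular ones:

      ∂b/∂t = c_b U − d_b b + e_b ∇²b
      ∂w/∂t = I − U − r_w w + e_w ∇²w
      ∂h/∂t = R − I + v_h ∂h/∂x + e_h ∇²h,

  with uptake `U = g_b w/(w+k_U) b` and vegetation-enhanced
  infiltration `I = a h (b + k_I w₀)/(b + k_I)`;
* **generate** correlated log-normal heterogeneity fields
  `e = exp(ε)`, `R_ε(r) = e^{−r/θ}`, with exact mean / coefficient of
  variation;
* **quantify** pattern structure spectrally: characteristic wavelength
  `λ_c = 2π/k_c`, regularity `S_rc/λ_c` (0 for irregular patterns,
  bounded by `L/λ_c` for periodic ones), low-pass cut-off `λ_l`,
  spectral coherence with the driving noise, transfer-function
  estimates, and a Monte-Carlo periodicity test;
* **synthesize** statistically equivalent patterns with parametric
  linear filters (low-pass, band-pass, noisy-oscillator) plus
  thresholding to a prescribed vegetation cover.

## Worked example

Simulate a spotted pattern in a homogeneous environment, measure it,
and fit the band-pass filter:

```python
from vegpattern import Grid, dynamics, spectra

grid = Grid(256, 256, dx=1.0)                       # 256 m x 256 m
params = dynamics.RietkerkParams(R_h=0.7, v_h=0.0, e_h=100.0)
config = dynamics.SimulationConfig(dt=0.25, t_end=6000.0, seed=1)
state = dynamics.simulate_rietkerk(params, config, grid=grid)

density = spectra.radial_density(spectra.periodogram(state.b))
m = spectra.pattern_metrics(density)
fit, r2 = spectra.hellinger_fit(density, "bandpass")
print(f"wavelength {m.wavelength:.1f} m, regularity {m.regularity:.2f}, "
      f"band-pass fit R2 {r2:.3f}")
```

This prints

```
wavelength 46.9 m, regularity 1.56, band-pass fit R2 0.945
```

— hexagonally ordered spots spaced about 47 m apart (the patch spacing
set by the water-redistribution feedback), a regularity well above the
≈1 typical of natural spotted patterns (heterogeneous runs bring it
down), and a band-pass spectral density that describes the pattern
almost completely.  A statistically equivalent pattern can now be
drawn without the model:

```python
from vegpattern import filters

bp = filters.bandpass_params_for(m.wavelength, m.regularity)
fake = filters.threshold(
    filters.synthesize(lambda k: filters.bandpass_density(k, bp),
                       grid=grid, seed=2),
    cover=0.4, mean_biomass=state.b.mean)
```

The same workflow is available from the shell:

```sh
vegpattern generate-noise --mean 0.2 --cv 0.3 --corr-length 50 \
    --nx 256 --ny 256 --seed 1 --out noise.nc
vegpattern simulate rietkerk --config run.yaml --noise noise.nc --out run.nc
vegpattern analyze --pattern run.nc --out metrics.json
vegpattern synthesize --family bandpass --wavelength 47 --regularity 1.5 \
    --cover 0.4 --out generic.nc
```

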