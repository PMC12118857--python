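# Methods

`vegpattern` treats the formation of spatial vegetation patterns as a
stochastic process: time-constant exogenous heterogeneity (soil
properties, microtopography) is filtered by scale-dependent biophysical
feedbacks, and the statistical structure of the resulting pattern — its
characteristic wavelength, regularity, and coherence with the driving
noise — is what the toolkit simulates, measures and synthesizes.  This
note records the models, the estimators, the numerical choices, and what
the synthetic test conditions do and do not establish about real
patterns.

## Models

**Grazing model (irregular patterns).** A single reaction-diffusion
equation for biomass `b` (g/m²),

    db/dt = a b (1 − b/K) − c b² / (b_n² + b²) + e ∇²b ,

with logistic regrowth (rate `a` = 1/d, carrying capacity `K` = 8 g/m²),
saturating grazing losses (scale `c` = 2 g/m²/d, half-saturation
`b_n` = 1 g/m²) and diffusion `e` = 0.1 m²/d.  The homogeneous
equilibria for the default set are the roots of `b³ − 8b² + 17b − 8`
(≈ 0.66, 2.47, 4.87 g/m²) plus the bare state; the outer two roots are
stable, so the system is bistable.  Runs start at the middle (unstable)
root, `b₀ = 2.4724`, and a spatially varying carrying capacity tips each
neighbourhood towards one of the branches — the resulting patch mosaic
is a low-pass image of the `K` map.

**Water-vegetation model (regular patterns).** Three coupled fields —
biomass `b` (g/m²), soil moisture `w` (mm), surface water `h` (mm):

    db/dt = c_b U − d_b b + e_b ∇²b
    dw/dt = I − U − r_w w + e_w ∇²w
    dh/dt = R − I + v_h ∂h/∂x + e_h ∇²h

with uptake `U = g_b w/(w + k_U) b` and vegetation-enhanced infiltration
`I = a h (b + k_I w_0)/(b + k_I)`: vegetated ground infiltrates up to
1/w₀ = 5× faster than bare ground, so surface water generated on bare
interspaces feeds the patches — short-range facilitation with long-range
competition for water.  Defaults are the standard parameter set
(`c_b` = 10 g/mm/m², `d_b` = 0.25 /d, `g_b` = 0.05 mm g⁻¹m⁻²d⁻¹,
`e_b` = 0.1 m²/d, `ā` = 0.2 /d, `k_I` = 5 mm, `r_w` = 0.2 /d,
`e_w` = 0.1 m²/d, `w₀` = 0.2, `k_U` = 5 g/m²).  Flat terrain
(`v_h` = 0, `e_h` = 100 m²/d) gives isotropic spotted / labyrinthine /
gapped patterns as precipitation `R` rises (defaults 0.7 / 1.0 /
1.2 mm/d); a hillslope (`v_h` = 10 m/d, `e_h` = (0, 20) m²/d,
`R` = 1 mm/d) gives stripes parallel to the contours that migrate uphill
(≈ 4 m/d in our runs).

**Coordinate convention.** Cell-centred periodic grids, origin at the
domain corner.  With `v_h > 0` surface water advects towards −x, so −x
is downhill; stripes migrate uphill (+x).

## Heterogeneity generator

The exogenous noise is a log-normal random field `e = exp(ε)` where `ε`
is Gaussian with exponential (first-order autoregressive) isotropic
autocorrelation `R(r) = exp(−r/θ)`.  Moments are matched so the field
has exactly the requested mean and coefficient of variation:
`σ_ε² = ln(1 + cv²)`, `μ_ε = ln μ − σ_ε²/2`.  The discrete kernel
averages the continuous autocorrelation over a grid cell (7-point
triangular-density quadrature per axis) and applies a raised-cosine
taper beyond 25 % of the domain half-width; the Gaussian stage is
synthesized spectrally (white noise × square root of the kernel
spectrum), which is exact on the periodic domain.  Two consequences
worth knowing:

* the zero-lag cell average enters the normalization, so the discrete
  autocorrelation at lag θ sits ≈ 0.52·dx/θ above `e⁻¹`;
* when θ approaches the domain size the tapered kernel's spectrum
  acquires small negative excursions; up to 0.1 % of spectral mass is
  clipped silently, up to 5 % with a warning, beyond that the kernel is
  rejected.

Default correlation lengths: `θ_K` = 1 m for the grazing model (noise
much finer than the patches) and `θ_a` = 50 m for the water-vegetation
model (noise much coarser than the patches); the separation of θ from
both the patch scale and the domain is limited on desk-scale domains,
which matters for the heterogeneous-run diagnostics below.

## Spectral estimators

* **Periodogram**: `|F(b − mean)|²/N²`; its sum equals the field
  variance (Parseval).  **Density estimates** are tile-averaged
  (Welch, non-overlapping tiles, default 4×4) and normalized to unit
  volume; cross-spectra and coherence apply a per-tile Hann taper, which
  keeps the coherence of exactly linear filter pairs near 1 (residual
  loss is leakage of impulse responses across tile boundaries).
* **Radial/directional densities**: angular ring average (one Fourier
  ring per bin, Δk = 2π/L, cut at the Nyquist circle) or axis average
  folded onto the half-axis, normalized to unit integral.
* **Wavelength and regularity**: the lobe maximum of the density after a
  3-bin moving average (raw ring profiles bias the maximum up by ~10 %),
  quadratic interpolation over 3 bins, ties broken towards lower
  wavenumber; the mean and the first ring are excluded.  A peak counts
  as a lobe only if it exceeds 1.3× the low-wavenumber floor of a 5-bin
  smoothed copy — otherwise the density is low-pass shaped, the pattern
  is irregular (regularity 0, wavelength undefined) and the half-power
  cut-off wavelength is reported instead, with `S(0)` proxied by the
  mean of rings 1–3.  The regularity ratio `S_rc/λ_c` expresses the lobe
  maximum per cycle per metre, so a perfectly periodic pattern on a
  domain of side `L` attains exactly `L/λ_c`; the ratio is invariant
  under rescaling `dx`.
* **Transfer function**: `T = S_eb/S_e` from tile-averaged cross and
  auto densities (mean excluded, empty bins masked), or the zero-phase
  approximation `T = s √(S_b/S_e)` for isotropic systems.
* **Coherence**: `c = |S_eb|²/(S_e S_b)` on the tile-averaged densities
  (raw-periodogram coherence is identically 1), weighted mean
  `c̄ = Σ S_b c / Σ S_b`.  With 16 tiles the independent-field floor is
  ≈ 1/16.
* **Periodicity test**: parametric bootstrap.  The statistic is the
  maximum periodogram ordinate relative to the isotropically smoothed
  density estimated from the field itself; surrogates are Gaussian
  fields synthesized from that density and pushed through the identical
  estimation pipeline; `p = (1 + #{surrogate ≥ observed})/(n + 1)`.
  The test attains its nominal type-I error on its own null (verified at
  the 5 % level over 200 calibration runs).
* **Local phase**: analytic signal (Hilbert transform) of a transect;
  local wavelength is 2π over the phase gradient; cells below 10 % of
  the median amplitude are flagged unreliable.
* **Hellinger fits**: parametric densities are fitted by minimizing
  `∫(√S_fit − √S_emp)² dk` (Nelder-Mead in log-parameter space); the
  goodness of fit is `R² = 1 − SSE/SST` on the square-root densities —
  an interpretation choice, since "R²" for densities is not otherwise
  pinned down.

## Linear filter families

* **Low-pass** `S ∝ 1/(1 + (k/k₀)^{2p})`, `p ≥ 1`; `k₀` is exactly the
  half-power corner.
* **Band-pass** `S ∝ (k/k_c)^{2α}/(1 + (k/k_c)²)^{2α}`: vanishes at the
  origin, peaks exactly at `k_c`, and the regularity has the closed form
  `2·4^{−α}/B(α+½, α−½)` — monotone in α, independent of `k_c` — so the
  two parameters map one-to-one onto (wavelength, regularity).  The
  calibration is restricted to α > 1 (2-D integrability), bounding the
  attainable regularity below at 1/π.
* **Noisy oscillator** (striped patterns): a Lorentzian line pair at
  ±k_c with half-width γ_x perpendicular to the stripes — the transform
  of the phase-diffusing correlation `cos(k_c x) e^{−γ_x|x|}` — and a
  Lorentzian at the origin with half-width γ_y parallel to them; the 2-D
  density is the outer product.  Closed-form regularities
  `r_x ≈ k_c/(π γ_x)`, `r_y = 2k_c/(π γ_y)` give the three-parameter
  calibration.  Patterns are generated as a clipped cosine of
  `k_c x + φ(x, y)` where φ is an anisotropic Brownian phase surface
  (spectral synthesis with density ∝ (k_x² + k_y²/c)^{−3/2}, amplitude
  and anisotropy calibrated against the exact discrete structure
  function so increments grow as 2γ_x and 2γ_y per metre).  Clipping
  redistributes some variance into harmonics, so measured lobe widths
  sit near, not exactly on, the Lorentzian prediction.

Generic patterns are synthesized as `F⁻¹(√S · F(e))` (zero phase) and
thresholded: the top `round(pN)` cells receive a uniform biomass chosen
so the mean is exactly the requested value; excluding a top fraction as
well yields ringed patterns.  Cover estimation on arbitrary patterns
uses Otsu's bimodal-histogram threshold.

## Numerical integration

First-order operator splitting: reactions advance explicitly
(`dt` = 0.25 d for the water-vegetation model, 0.05 d for the grazing
model), then diffusion and advection are applied exactly in Fourier
space through the integrating factor `exp(dt(−e_x k_x² − e_y k_y² +
i v k_x))`.  This removes the stiff diffusion constraint at metre
resolution; the advection is a spectrally exact phase shift.  Negative
values (Gibbs ringing of sharp fronts) are clipped with the removed mass
tracked; a step that clips more than 0.1 % of a field's mass aborts the
run, except during a 50-step grace period when the near-delta initial
condition rings benignly.  Stationarity is declared when the relative L1
change of the biomass radial density over a 50-day window falls below
10⁻³ (with a hard time cap).  Halving dt leaves the converged radial
density unchanged to ≲0.03 % L1; rarely, a bistable domain wall pins
into a different — equally valid — steady configuration at a different
dt, which shows up as a few-percent jump rather than a convergence
failure.

**Initial condition.** The "random" initialization is sparse
nucleation: 5 % of cells seeded at 20 g/m², water fields at the
bare-state equilibrium.  In the patterned regime the bare state is
linearly stable and no vegetated homogeneous state exists, so
establishment is subcritical: spatially uniform random cover drains the
shared surface water and collapses to desert, whereas sparse nuclei
capture runoff from their surroundings and grow into the pattern.  The
phase experiments instead start from a periodic stripe train at the
model's intrinsic spacing — the long-time homogeneous state that serves
as the unperturbed reference.

## Problem sizes, and what desk-scale runs show

Simulations in the test suite and the acceptance script use 256 m
isotropic domains (6 000 d), 1 024 m one-dimensional hillslopes
(15 000 d), and ensembles of 3–20 seeds; the `full=True` switches of the
experiments module select kilometre-scale domains and 10× horizons.
Consequences of the reduced scale, measured and accepted rather than
hidden:

* the emergent spotted wavelength is 45–47 m against the full-scale
  44 m (patterns keep coarsening extremely slowly);
* the stripe spacing of an individual hillslope run freezes inside a
  multistable wavelength band (64–113 m over seeds, unchanged from
  6 000 to 40 000 d), so the spacing is reported as an ensemble mean
  (≈ 80–83 m; the full-scale two-dimensional value is 73 m, where
  transverse defect dynamics reselect the spacing);
* at cv(a) = 0.3 the 256-m heterogeneous run has no resolvable ring —
  its lobe would sit in the third Fourier ring — so the heterogeneous
  diagnostics at desk scale assert the collapse of regularity and the
  loss of periodicity (p ≈ 0.4–0.6 versus ≈ 0.01 homogeneous), not the
  full-scale regularity value;
* the exogenous share of the infiltration variance (c_a ≈ 0.28 at desk
  scale) exceeds its kilometre-scale sweep value (≤ 0.18) because θ_a
  is not far from the domain size.

The synthetic heterogeneity reproduces the marginal distribution and
the correlation length of mapped soil variability, but real landscapes
are anisotropic, non-stationary and cross-correlated with topography;
passing tests show the estimators and the filtering theory are
internally consistent, not that any particular landscape obeys them.

## Phase-noise experiments

A localized infiltration deficit in a striped run lowers amplitude and
wavelength locally; both recover beyond the dip while the phase offset —
carried along by the migrating stripes — persists (measured against the
paired homogeneous reference from the same initial train).  With a
half-heterogeneous domain the ensemble variance of the phase deviation
grows monotonically with distance into the heterogeneous half (Spearman
ρ ≥ 0.84 across configurations), and the deviation is strongly coupled
to the along-slope integral of the infiltration anomaly run by run
(mean |corr| ≈ 0.4–0.5).  The *sign* of that coupling varies between
noise realizations in our configuration — a continuously migrating train
on a periodic domain integrates the same noise repeatedly — so the
magnitude, not the sign, is the asserted quantity.  The default
250-day horizon keeps the train within its first pass through the
heterogeneous half.

## Known limitations

Periodic boundaries only; no topographic forcing beyond the uniform
slope implicit in the advection term; time-constant noise only; the
periodicity test is a surrogate-calibrated stand-in for exact tests from
the time-series literature; Welch tiles trade leakage against variance
with no overlap; and the linear filters reproduce spatial structure, not
dynamics — uphill migration and asymmetric stripe cross-sections are
outside their reach by construction.
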