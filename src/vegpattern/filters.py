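"""Parametric linear filters and pattern synthesis.

Three filter families span the observed pattern classes:

* **low-pass** (irregular patterns): ``S(k) = C / (1 + (k/k0)^(2p))`` —
  corner wavenumber ``k0`` and order ``p`` set the cut-off wavelength and
  the decay rate; ``p >= 1`` keeps the 2D density integrable.
* **band-pass** (isotropic regular patterns):
  ``S(kr) = C (kr/kc)^(2a) / (1 + (kr/kc)^2)^(2a)`` — vanishes at the
  origin, peaks exactly at ``kc``, and the shape parameter ``a > 1`` maps
  one-to-one onto the regularity, so the two degrees of freedom are
  exactly (wavelength, regularity).
* **noisy oscillator** (anisotropic/striped patterns): a pair of
  Lorentzian lines at ``+-kc`` with width ``gamma_x`` perpendicular to
  the stripes (the transform of ``cos(kc x) exp(-gamma_x |x|)``, i.e. a
  phase-diffusing oscillation) and a Lorentzian at the origin with width
  ``gamma_y`` parallel to them; the 2D density is the outer product.

A generic pattern is synthesized by multiplying the transform of a noise
field with the (zero-phase) transfer ``T = s sqrt(S)`` and transforming
back; thresholding at a cover fraction then yields spotted, labyrinthine
or gapped vegetation maps with an exactly prescribed mean biomass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import betaln

from .grid import Grid, ScalarField

__all__ = [
    "LowPassParams",
    "BandPassParams",
    "OscillatorParams",
    "lowpass_density",
    "bandpass_density",
    "bandpass_regularity",
    "bandpass_params_for",
    "oscillator_density",
    "oscillator_regularity",
    "oscillator_params_for",
    "synthesize",
    "threshold",
    "oscillator_generate",
    "cover_fraction",
    "density_family",
    "make_params",
    "default_init",
]


@dataclass(frozen=True)
class LowPassParams:
    """Corner wavenumber k0 (rad/m) and order p (p >= 1 for 2D integrability)."""

    k0: float
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.p < 1:
            raise ValueError("order p < 1 is not integrable in 2D")


@dataclass(frozen=True)
class BandPassParams:
    """Characteristic wavenumber kc (rad/m) and shape parameter alpha."""

    kc: float
    alpha: float

    def __post_init__(self) -> None:
        if self.kc <= 0:
            raise ValueError("kc must be positive")
        if self.alpha <= 0.5:
            raise ValueError("alpha <= 1/2 gives a non-integrable radial density")


@dataclass(frozen=True)
class OscillatorParams:
    """kc and the phase-diffusion widths perpendicular/parallel to stripes."""

    kc: float | None = None
    gamma_x: float | None = None
    gamma_y: float | None = None

    def __post_init__(self) -> None:
        for name in ("kc", "gamma_x", "gamma_y"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def lowpass_density(k, params: LowPassParams) -> np.ndarray:
    """Low-pass density, unnormalized; S(k0) = S(0)/2 (half-power corner)."""
    k = np.asarray(k, dtype=float)
    return 1.0 / (1.0 + (k / params.k0) ** (2.0 * params.p))


def bandpass_density(kr, params: BandPassParams) -> np.ndarray:
    """Band-pass radial density, unnormalized; S(0)=0, argmax at kc."""
    u = np.asarray(kr, dtype=float) / params.kc
    with np.errstate(divide="ignore", invalid="ignore"):
        s = u ** (2.0 * params.alpha) / (1.0 + u**2) ** (2.0 * params.alpha)
    return np.where(np.asarray(kr) == 0, 0.0, s)


def bandpass_regularity(alpha: float) -> float:
    """Closed-form regularity S_rc/lambda_c of the band-pass family.

    With the radial density normalized to unit integral over the half
    axis, regularity = 4^(-alpha) * 2 / B(alpha+1/2, alpha-1/2); it is
    independent of kc (scale invariance) and increases with alpha.
    """
    if alpha <= 0.5:
        raise ValueError("alpha must exceed 1/2")
    return float(2.0 * np.exp(-alpha * np.log(4.0)
                              - betaln(alpha + 0.5, alpha - 0.5)))


_BP_ALPHA_MAX = 500.0


def bandpass_params_for(wavelength: float, regularity: float) -> BandPassParams:
    """Invert the (wavelength, regularity) calibration of the band-pass family.

    Restricted to ``alpha > 1`` so the two-dimensional density (with its
    ring Jacobian) stays integrable; this bounds the attainable
    regularity from below at 1/pi.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    r_min = bandpass_regularity(1.0 + 1e-9)
    r_max = bandpass_regularity(_BP_ALPHA_MAX)
    if not (r_min < regularity < r_max):
        raise ValueError(
            f"requested regularity {regularity:.3g} outside the attainable "
            f"range ({r_min:.3g}, {r_max:.3g}) of the band-pass family")
    alpha = brentq(lambda a: bandpass_regularity(a) - regularity,
                   1.0 + 1e-9, _BP_ALPHA_MAX, xtol=1e-12)
    return BandPassParams(kc=2.0 * np.pi / wavelength, alpha=float(alpha))


def oscillator_density(k, params: OscillatorParams, axis: str = "x") -> np.ndarray:
    """Oscillator density along one axis, unnormalized.

    Perpendicular to the stripes (axis 'x'): a symmetric pair of
    Lorentzian lines at +-kc with half-width gamma_x — the Fourier
    transform of the phase-diffusing correlation
    ``cos(kc x) exp(-gamma_x |x|)``.  Parallel ('y'): a Lorentzian at
    the origin with half-width gamma_y.
    """
    k = np.asarray(k, dtype=float)
    if axis == "x":
        kc, g = params.kc, params.gamma_x
        if kc is None or g is None:
            raise ValueError("axis 'x' needs kc and gamma_x")
        return g / (g**2 + (k - kc) ** 2) + g / (g**2 + (k + kc) ** 2)
    if axis == "y":
        g = params.gamma_y
        if g is None:
            raise ValueError("axis 'y' needs gamma_y")
        return g / (g**2 + k**2)
    raise ValueError("axis must be 'x' or 'y'")


def oscillator_regularity(params: OscillatorParams) -> tuple[float, float]:
    """Implied (S_x+c/lambda_c, S_y+c/lambda_c) of the oscillator densities.

    Closed forms on the continuous half-axis: the x-density integrates
    to pi regardless of (kc, gamma_x), giving
    ``r_x = kc/(pi gamma_x) (1 + gamma_x^2/(gamma_x^2+4 kc^2))`` and
    ``r_y = 2 kc / (pi gamma_y)``.
    """
    kc, gx, gy = params.kc, params.gamma_x, params.gamma_y
    r_x = kc / (np.pi * gx) * (1.0 + gx**2 / (gx**2 + 4.0 * kc**2))
    r_y = 2.0 * kc / (np.pi * gy)
    return float(r_x), float(r_y)


def oscillator_params_for(wavelength: float, reg_x: float,
                          reg_y: float) -> OscillatorParams:
    """Oscillator parameters for a target (wavelength, perpendicular
    regularity, parallel regularity)."""
    if min(wavelength, reg_x, reg_y) <= 0:
        raise ValueError("wavelength and regularities must be positive")
    kc = 2.0 * np.pi / wavelength

    def f(g):
        return kc / (np.pi * g) * (1.0 + g**2 / (g**2 + 4 * kc**2)) - reg_x

    hi = 2.0 * kc / (np.pi * reg_x)  # r_x >= kc/(pi g), so g <= kc/(pi r_x) * 2
    gx = brentq(f, 1e-12 * kc, 10.0 * hi + kc, xtol=1e-14)
    gy = 2.0 * kc / (np.pi * reg_y)
    return OscillatorParams(kc=kc, gamma_x=float(gx), gamma_y=float(gy))


# ---------------------------------------------------------------------------
# synthesis
# ---------------------------------------------------------------------------

def _transfer_on_grid(density, grid: Grid) -> np.ndarray:
    """Zero-phase transfer sqrt(S) evaluated on the grid wavenumbers."""
    from .spectra import Spectrum2D, TransferFunction2D

    if isinstance(density, TransferFunction2D):
        if density.grid.shape != grid.shape:
            raise ValueError("transfer grid does not match the noise grid")
        return density.values.astype(complex)
    if isinstance(density, Spectrum2D):
        if density.grid.shape != grid.shape:
            raise ValueError("density grid does not match the noise grid")
        s = density.values.real
    elif callable(density):
        s = density(grid.k_radial())
    else:
        raise TypeError("density must be callable, Spectrum2D or "
                        "TransferFunction2D")
    s = np.clip(np.asarray(s, dtype=float), 0.0, None)
    t = np.sqrt(s).astype(complex)
    t[0, 0] = 0.0  # the mean is not part of the spatial structure
    return t


def synthesize(density, noise=None, grid: Grid | None = None,
               seed: int = 0, offset: float = 0.0) -> ScalarField:
    """Generic pattern: filter a noise field with the given density/transfer.

    ``b = offset + F^-1(T . F(e - mean(e)))`` with ``T = sqrt(S)`` (zero
    phase) or the supplied transfer function.  The tile-averaged density
    of the output converges to S as the domain grows.  If ``noise`` is
    omitted, white Gaussian noise is drawn on ``grid`` with ``seed``.
    """
    if noise is None:
        if grid is None:
            raise ValueError("either a noise field or a grid is required")
        rng = np.random.default_rng(seed)
        noise = ScalarField(grid, rng.standard_normal(grid.shape))
    elif not isinstance(noise, ScalarField):
        noise = np.atleast_2d(np.asarray(noise, dtype=float))
        noise = ScalarField(Grid(nx=noise.shape[1], ny=noise.shape[0],
                                 dx=1.0 if grid is None else grid.dx), noise)
    grid = noise.grid
    t = _transfer_on_grid(density, grid)
    e = noise.values - noise.values.mean()
    out = np.fft.ifft2(t * np.fft.fft2(e)).real + offset
    return ScalarField(grid, out)


def threshold(pattern, cover: float, mean_biomass: float = 1.0,
              exclude_top: float = 0.0) -> ScalarField:
    """Threshold a generic pattern to a vegetation cover fraction.

    The ``round(cover * N)`` highest-valued cells (after excluding the
    ``exclude_top`` fraction at the very top, which yields ringed
    patterns) are set to a uniform biomass such that the field mean is
    exactly ``mean_biomass``; all other cells are 0.
    """
    if not 0.0 < cover <= 1.0:
        raise ValueError("cover fraction must be in (0, 1]")
    if isinstance(pattern, ScalarField):
        grid, values = pattern.grid, pattern.values
    else:
        values = np.atleast_2d(np.asarray(pattern, dtype=float))
        grid = Grid(nx=values.shape[1], ny=values.shape[0])
    n = values.size
    k = max(int(round(cover * n)), 1)
    k_top = int(round(exclude_top * n))
    if k + k_top > n:
        raise ValueError("cover + exclude_top exceeds the domain")
    order = np.argsort(values, axis=None)
    veg = order[n - k_top - k: n - k_top]
    out = np.zeros(n)
    out[veg] = mean_biomass * n / k
    return ScalarField(grid, out.reshape(values.shape), units="g/m^2")


# ---------------------------------------------------------------------------
# oscillator pattern generator (Brownian-surface phase)
# ---------------------------------------------------------------------------

def _brownian_phase_spectrum(grid: Grid, gamma_x: float,
                             gamma_y: float) -> np.ndarray:
    """Discrete spectrum of the anisotropic Brownian phase surface.

    S(k) ~ (kx^2 + ky^2/c)^(-3/2) gives a variogram growing linearly
    with distance (Brownian surface); the anisotropy c and the overall
    amplitude are calibrated against the exact discrete structure
    function so that E[(phi(x+d)-phi(x))^2] = 2 gamma_x d along x and
    2 gamma_y d along y.
    """
    kx = grid.kx()[None, :]
    ky = grid.ky()[:, None]
    n = grid.n_cells

    def spectrum(c):
        with np.errstate(divide="ignore"):
            s = (kx**2 + ky**2 / c) ** (-1.5)
        s[0, 0] = 0.0
        return s

    def slopes(c):
        s = spectrum(c)
        lags = np.arange(1, 5)
        dx_slopes = []
        dy_slopes = []
        for lag in lags:
            d = lag * grid.dx
            dxs = (2.0 / n) * (s * (1.0 - np.cos(kx * d))).sum()
            dys = (2.0 / n) * (s * (1.0 - np.cos(ky * d))).sum()
            dx_slopes.append(dxs / d)
            dy_slopes.append(dys / d)
        return float(np.mean(dx_slopes)), float(np.mean(dy_slopes))

    if grid.is_1d:
        sx, _ = slopes(1.0)
        return spectrum(1.0) * (2.0 * gamma_x / sx)

    ratio_target = gamma_y / gamma_x

    def f(log_c):
        sx, sy = slopes(np.exp(log_c))
        return np.log(sy / sx) - np.log(ratio_target)

    log_c = brentq(f, np.log(1e-6), np.log(1e6), xtol=1e-10)
    c = float(np.exp(log_c))
    sx, _ = slopes(c)
    return spectrum(c) * (2.0 * gamma_x / sx)


def oscillator_generate(params: OscillatorParams, grid: Grid, seed: int = 0,
                        cover: float = 0.5,
                        mean_biomass: float = 1.0) -> ScalarField:
    """Striped pattern from a noisy oscillation b = g(kc x + phi(x, y)).

    ``phi`` is an anisotropic Brownian phase surface whose increment
    rates are calibrated to (gamma_x, gamma_y); ``g`` is a clipped
    cosine at the target cover, so the output is bimodal and needs no
    further thresholding.  gamma -> 0 recovers perfectly periodic
    stripes.
    """
    if params.kc is None or params.gamma_x is None or params.gamma_y is None:
        raise ValueError("oscillator generation needs kc, gamma_x and gamma_y")
    if not 0.0 < cover <= 1.0:
        raise ValueError("cover fraction must be in (0, 1]")
    x = grid.x()[None, :]
    tiny = 1e-12 * params.kc
    if params.gamma_x <= tiny and params.gamma_y <= tiny:
        phi = np.zeros(grid.shape)
    else:
        spec = _brownian_phase_spectrum(grid, max(params.gamma_x, tiny),
                                        max(params.gamma_y, tiny))
        rng = np.random.default_rng(seed)
        white = rng.standard_normal(grid.shape)
        phi = np.fft.ifft2(np.sqrt(spec) * np.fft.fft2(white)).real
    wave = np.cos(params.kc * x + phi)
    level = np.cos(np.pi * cover)  # P(cos(U) > cos(pi p)) = p for uniform phase
    veg = wave > level
    frac = max(veg.mean(), 1.0 / grid.n_cells)
    out = np.where(veg, mean_biomass / frac, 0.0)
    return ScalarField(grid, out, units="g/m^2")


def cover_fraction(pattern) -> float:
    """Vegetated fraction of a (bimodal) pattern via Otsu's histogram threshold."""
    from skimage.filters import threshold_otsu

    values = pattern.values if isinstance(pattern, ScalarField) \
        else np.asarray(pattern, dtype=float)
    if np.ptp(values) == 0:
        raise ValueError("cover fraction undefined for a constant pattern")
    t = threshold_otsu(values)
    return float((values > t).mean())


# ---------------------------------------------------------------------------
# family registry used by the Hellinger fitter
# ---------------------------------------------------------------------------

def density_family(family: str) -> Callable:
    """Unnormalized density S(k, *params) for a named filter family."""
    if family == "lowpass":
        return lambda k, k0, p: lowpass_density(k, LowPassParams(k0, max(p, 1.0)))
    if family == "bandpass":
        return lambda k, kc, alpha: bandpass_density(
            k, BandPassParams(kc, max(alpha, 0.5 + 1e-9)))
    if family == "oscillator-x":
        return lambda k, kc, gx: oscillator_density(
            k, OscillatorParams(kc=kc, gamma_x=gx), axis="x")
    if family == "oscillator-y":
        return lambda k, gy: oscillator_density(
            k, OscillatorParams(gamma_y=gy), axis="y")
    raise ValueError(f"unknown filter family {family!r}")


def make_params(family: str, values):
    values = [float(v) for v in values]
    if family == "lowpass":
        return LowPassParams(values[0], max(values[1], 1.0))
    if family == "bandpass":
        return BandPassParams(values[0], max(values[1], 0.5 + 1e-9))
    if family == "oscillator-x":
        return OscillatorParams(kc=values[0], gamma_x=values[1])
    if family == "oscillator-y":
        return OscillatorParams(gamma_y=values[0])
    raise ValueError(f"unknown filter family {family!r}")


def default_init(family: str, k: np.ndarray, s: np.ndarray):
    """Heuristic initial parameters from an empirical density."""
    kmax = float(k[np.argmax(s)])
    if family == "lowpass":
        below = np.nonzero(s <= 0.5 * s[0])[0]
        k0 = float(k[below[0]]) if len(below) else float(k[len(k) // 2])
        return [max(k0, k[0]), 2.0]
    if family == "bandpass":
        return [max(kmax, k[0]), 2.0]
    if family == "oscillator-x":
        kc = max(kmax, k[0])
        return [kc, 0.2 * kc]
    if family == "oscillator-y":
        below = np.nonzero(s <= 0.5 * s.max())[0]
        g = float(k[below[0]]) if len(below) else float(k[len(k) // 2])
        return [max(g, 0.5 * float(k[0]))]
    raise ValueError(f"unknown filter family {family!r}")
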