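"""Spatially correlated log-normal heterogeneity fields.

Exogenous environmental heterogeneity (spatially varying soil properties,
microtopography, ...) is modelled as a time-constant log-normal random
field ``e = exp(eps)`` where ``eps`` is Gaussian with an isotropic
first-order (exponentially decaying) autocorrelation

    R(r) = exp(-r / theta),

``theta`` being the correlation length.  The marginal parameters of the
Gaussian stage are moment-matched so the log-normal field has the
requested mean ``mu_e`` and coefficient of variation ``cv = sigma_e/mu_e``.

The discrete process corrects the continuous autocorrelation for the
finite cell size (cell-pair averaging) and the finite domain (raised
cosine taper), and is sampled exactly on the periodic grid by spectral
synthesis: white noise is transformed, scaled by the square root of the
kernel spectrum, and transformed back.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import Grid, ScalarField

__all__ = [
    "HeterogeneityParams",
    "lognormal_params",
    "correlation_kernel",
    "kernel_spectrum",
    "generate_field",
    "coefficient_of_variation",
]


@dataclass(frozen=True)
class HeterogeneityParams:
    """Log-normal heterogeneity: mean, coefficient of variation, correlation length.

    ``mean`` carries the units of the target coefficient (e.g. the
    infiltration coefficient, 1/d); ``cv`` is dimensionless; ``theta``
    is the correlation length in metres; ``seed`` drives one dedicated
    generator stream per field.
    """

    mean: float
    cv: float
    theta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.theta <= 0:
            raise ValueError("correlation length must be positive")


def lognormal_params(mu_e: float, cv: float) -> tuple[float, float]:
    """Gaussian-stage parameters (mu_eps, sigma_eps^2) for a log-normal field.

    Moment matching: ``exp(N(mu_eps, sigma_eps^2))`` has mean ``mu_e``
    and coefficient of variation ``cv``.
    """
    if mu_e <= 0:
        raise ValueError("mu_e must be positive")
    if cv < 0:
        raise ValueError("cv must be non-negative")
    sigma2 = np.log1p(cv**2)
    mu_eps = np.log(mu_e) - 0.5 * sigma2
    return float(mu_eps), float(sigma2)


def _cell_average_quadrature(n: int = 7) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature for the separation of two points uniform in a cell.

    The difference of two independent uniforms on ``[0, dx]`` has a
    triangular density on ``[-dx, dx]``; in 2D the cell-pair separation
    density is the product of two triangles.  Returns offsets (in units
    of dx) and weights of a tensor-product midpoint rule on that density.
    """
    s = (np.arange(n) + 0.5) / n * 2.0 - 1.0  # offsets in (-1, 1)
    w = 1.0 - np.abs(s)  # triangular density
    w = w / w.sum()
    return s, w


def correlation_kernel(theta: float, grid: Grid) -> ScalarField:
    """Discrete autocorrelation field of the heterogeneity process.

    ``R(r) ~ exp(-r/theta)``, averaged over the area of a grid cell
    (finite resolution) and tapered with a raised-cosine window at lags
    beyond 25% of the domain half-width (finite extent).  The value at
    zero lag is 1 by construction.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if theta < grid.dx / 10.0:
        warnings.warn(
            f"correlation length {theta} m is far below the cell size "
            f"{grid.dx} m; the kernel is unresolved",
            stacklevel=2,
        )

    # lag offsets (periodic) along each axis, in metres
    rx = grid.dx * np.minimum(np.arange(grid.nx), grid.nx - np.arange(grid.nx))
    ry = grid.dx * np.minimum(np.arange(grid.ny), grid.ny - np.arange(grid.ny))

    s, w = _cell_average_quadrature()
    off = s * grid.dx
    if grid.is_1d:
        # 1D cell-average: R_d(l) = E[exp(-|l + u - v|/theta)]
        lag = np.abs(rx[:, None] + off[None, :])
        r_cell = (np.exp(-lag / theta) * w[None, :]).sum(axis=1)[None, :]
    else:
        lx = rx[None, :, None] + off[None, None, :]
        ly = ry[:, None, None] + off[None, None, :]
        # separable quadrature over the two offset axes
        acc = np.zeros(grid.shape)
        for j, wy in enumerate(w):
            dyj = ly[..., j]
            dist = np.sqrt(lx**2 + dyj[..., None] ** 2)
            acc += wy * (np.exp(-dist / theta) * w[None, None, :]).sum(axis=-1)
        r_cell = acc
    r_cell = r_cell / r_cell.flat[0]

    # raised-cosine taper beyond 25% of the domain half-width
    r = grid.lag_radial()
    half = 0.5 * min(grid.lx, grid.ly if not grid.is_1d else grid.lx)
    r0 = 0.25 * half
    taper = np.ones_like(r)
    ramp = (r > r0) & (r < half)
    taper[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - r0) / (half - r0)))
    taper[r >= half] = 0.0

    return ScalarField(grid, r_cell * taper, units="")


def kernel_spectrum(theta: float, grid: Grid) -> np.ndarray:
    """Non-negative spectral transform of the discrete correlation kernel.

    The FFT of the corrected kernel is real.  When the correlation
    length approaches the domain size the taper leaves small negative
    excursions; they are clipped as long as the negative mass is a small
    fraction of the total (the realized covariance then deviates
    slightly from the requested one), otherwise the kernel is rejected.
    """
    kern = correlation_kernel(theta, grid)
    spec = np.fft.fft2(kern.values).real
    neg = -spec[spec < 0].sum()
    total = np.abs(spec).sum()
    if total > 0 and neg / total > 0.05:
        raise ValueError(
            "correlation kernel has a significantly negative spectrum "
            f"({neg / total:.1%} of total mass); the correlation length "
            "is not representable on this grid"
        )
    if total > 0 and neg / total > 1e-3:
        warnings.warn(
            f"correlation length {theta} m is large relative to the "
            f"domain; clipping {neg / total:.2%} negative spectral mass",
            stacklevel=2,
        )
    spec = np.clip(spec, 0.0, None)
    # renormalize so the synthesized Gaussian stage keeps unit variance
    spec *= grid.n_cells / spec.sum()
    return spec


def generate_field(params: HeterogeneityParams, grid: Grid) -> ScalarField:
    """Sample a correlated log-normal heterogeneity field on the grid.

    Spectral synthesis of the Gaussian stage (exact on the periodic
    domain), then exponentiation.  Identical ``(params, grid)`` gives a
    bitwise-identical field.
    """
    mu_eps, sigma2 = lognormal_params(params.mean, params.cv)
    if sigma2 == 0.0:
        return ScalarField(grid, np.full(grid.shape, params.mean))

    spec = kernel_spectrum(params.theta, grid)
    rng = np.random.default_rng(params.seed)
    white = rng.standard_normal(grid.shape)
    # E[|FFT(white)_k|^2] = N and sum_k spec_k = N * R(0) = N, so the
    # synthesized Gaussian field has unit variance.
    gauss = np.fft.ifft2(np.sqrt(spec) * np.fft.fft2(white)).real
    eps = mu_eps + np.sqrt(sigma2) * gauss
    return ScalarField(grid, np.exp(eps))


def coefficient_of_variation(field: ScalarField | np.ndarray) -> float:
    """sigma / mu of the field values."""
    values = field.values if isinstance(field, ScalarField) else np.asarray(field)
    mu = values.mean()
    if mu == 0:
        raise ValueError("coefficient of variation undefined for zero-mean field")
    return float(values.std() / abs(mu))
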