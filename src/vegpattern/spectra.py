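"""Spectral diagnostics for spatial patterns.

Periodograms and Welch-style tile-averaged density estimates, radial and
directional density reductions, pattern metrics (characteristic
wavelength, regularity, cut-off wavelength), autocorrelation, transfer
function and coherence estimation, a Monte-Carlo periodicity test,
analytic-signal phase extraction, and Hellinger-distance fitting of
parametric filter densities.

Conventions
-----------
Wavenumber axes are angular (rad/m) in FFT order.  A periodogram is
``|F(b - mean(b))|^2 / N^2`` so its sum equals the field variance
(Parseval).  Estimated densities are normalized to unit volume.  The
regularity ratio expresses the lobe maximum of the normalized
one-dimensional density per *cycle* per metre, so that a perfectly
periodic pattern on a domain of side ``L`` attains the theoretical
maximum ``L / lambda_c``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .grid import Grid, ScalarField

__all__ = [
    "Spectrum2D",
    "RadialDensity",
    "DirectionalDensity",
    "RegularitySummary",
    "TransferFunction2D",
    "CoherenceResult",
    "PhaseProfile",
    "periodogram",
    "estimate_density",
    "cross_density",
    "radial_density",
    "directional_density",
    "pattern_metrics",
    "autocorrelation",
    "transfer_estimate",
    "coherence",
    "periodicity_test",
    "local_phase",
    "hellinger_fit",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Spectrum2D:
    """Two-dimensional (cross-)spectral estimate in FFT order.

    ``values >= 0`` for auto-spectra; ``grid`` is the grid the transform
    was taken on (the tile grid for tile-averaged estimates).
    """

    grid: Grid
    values: np.ndarray
    normalized: bool = False

    @property
    def kx(self) -> np.ndarray:
        return self.grid.kx()

    @property
    def ky(self) -> np.ndarray:
        return self.grid.ky()

    @property
    def dk(self) -> tuple[float, float]:
        return 2.0 * np.pi / self.grid.lx, 2.0 * np.pi / self.grid.ly

    def normalize(self) -> "Spectrum2D":
        """Scale to unit volume: sum(values) * dkx * dky = 1."""
        dkx, dky = self.dk
        vol = self.values.sum() * dkx * dky
        if vol <= 0:
            raise ValueError("cannot normalize an empty spectrum")
        return Spectrum2D(self.grid, self.values / vol, normalized=True)


@dataclass
class RadialDensity:
    """Angle-averaged density over radial wavenumber bins (one ring per bin)."""

    kr: np.ndarray        # bin centres, rad/m
    values: np.ndarray    # angular means, normalized to unit integral
    dk: float             # bin width, rad/m
    volume: float = 1.0   # ring-integrated volume before normalization


@dataclass
class DirectionalDensity:
    """Axis density folded onto the non-negative half-axis, unit integral."""

    k: np.ndarray
    values: np.ndarray
    dk: float
    axis: str = "x"


@dataclass
class RegularitySummary:
    """Wavelength / regularity / cut-off metrics of one pattern.

    ``regularity`` is ``S_rc/lambda_c`` for isotropic patterns or the
    ``(S_x+c/lambda_c, S_y+c/lambda_c)`` pair for anisotropic ones, on
    the per-cycle scale bounded by ``L/lambda_c`` for periodic patterns.
    An irregular pattern (density lobe at the origin) has regularity 0
    and undefined ``wavelength``; its cut-off wavelength ``cutoff`` is
    the half-power point of the low-pass-shaped density.
    """

    wavelength: float
    regularity: float | tuple[float, float]
    cutoff: float = float("nan")
    p_value: float = float("nan")

    @property
    def is_regular(self) -> bool:
        r = self.regularity
        r0 = r[0] if isinstance(r, tuple) else r
        return r0 > 0


@dataclass
class TransferFunction2D:
    """Complex transfer-function estimate over the tile wavenumber grid."""

    grid: Grid
    values: np.ndarray
    scale: float = 1.0

    def impulse_response(self) -> np.ndarray:
        """Real-space impulse response (inverse transform of the transfer)."""
        return np.fft.ifft2(self.values).real


@dataclass
class CoherenceResult:
    """Wavenumber-resolved spectral coherence in [0, 1] and its weighted mean."""

    grid: Grid
    values: np.ndarray
    weighted_mean: float


@dataclass
class PhaseProfile:
    """Local amplitude / phase / wavelength along a 1D transect."""

    x: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray          # unwrapped
    wavelength: np.ndarray
    dphi: np.ndarray           # deviation from the deterministic drift
    kc: float
    reliable: np.ndarray       # amplitude above the noise floor


# ---------------------------------------------------------------------------
# periodogram / density estimation
# ---------------------------------------------------------------------------

def _as_values(field) -> tuple[np.ndarray, Grid]:
    if isinstance(field, ScalarField):
        return field.values, field.grid
    values = np.atleast_2d(np.asarray(field, dtype=float))
    return values, Grid(nx=values.shape[1], ny=values.shape[0], dx=1.0)


def periodogram(field, taper: bool = False) -> Spectrum2D:
    """Squared Fourier magnitude of the mean-removed field.

    ``sum(values) == var(field)`` (Parseval, population variance).  An
    optional Hann taper reduces leakage for non-periodic inputs.
    """
    values, grid = _as_values(field)
    f = values - values.mean()
    if taper:
        wy = np.hanning(grid.ny) if grid.ny > 1 else np.ones(1)
        wx = np.hanning(grid.nx)
        w = wy[:, None] * wx[None, :]
        f = f * w / np.sqrt((w**2).mean())
    p = np.abs(np.fft.fft2(f)) ** 2 / grid.n_cells**2
    return Spectrum2D(grid, p, normalized=False)


def _tile_views(values: np.ndarray, tiles: tuple[int, int]) -> list[np.ndarray]:
    ty, tx = tiles
    ny, nx = values.shape
    if ny % ty or nx % tx:
        raise ValueError("tile counts must divide the grid dimensions")
    hy, hx = ny // ty, nx // tx
    return [values[i * hy:(i + 1) * hy, j * hx:(j + 1) * hx]
            for i in range(ty) for j in range(tx)]


def _tile_shape(grid: Grid, tile_count) -> tuple[int, int]:
    if isinstance(tile_count, int):
        ty = 1 if grid.is_1d else tile_count
        tiles = (ty, tile_count)
    else:
        tiles = tuple(tile_count)
    if grid.ny // tiles[0] < 1 or grid.nx // tiles[1] < 8:
        raise ValueError("tiles too small for a meaningful spectral estimate")
    return tiles


def estimate_density(field, tile_count=4) -> Spectrum2D:
    """Welch-style tile-averaged spectral density, unit volume.

    The field is split into non-overlapping tiles, each tile's
    mean-removed periodogram is averaged, and the result is normalized.
    ``tile_count=1`` reduces to the (normalized) periodogram.
    """
    values, grid = _as_values(field)
    tiles = _tile_shape(grid, tile_count)
    hy, hx = grid.ny // tiles[0], grid.nx // tiles[1]
    tgrid = Grid(nx=hx, ny=hy, dx=grid.dx)
    acc = np.zeros((hy, hx))
    for tile in _tile_views(values, tiles):
        f = tile - tile.mean()
        acc += np.abs(np.fft.fft2(f)) ** 2
    acc /= len(_tile_views(values, tiles))
    return Spectrum2D(tgrid, acc, normalized=False).normalize()


def cross_density(e, b, tile_count=4,
                  taper: bool = True) -> tuple[Spectrum2D, Spectrum2D, Spectrum2D]:
    """Tile-averaged (S_eb, S_e, S_b) on a common tile grid.

    A per-tile Hann taper (applied to both fields) limits the spectral
    leakage that non-periodic tile boundaries would otherwise inject
    into the cross terms.
    """
    ev, egrid = _as_values(e)
    bv, bgrid = _as_values(b)
    if ev.shape != bv.shape:
        raise ValueError("fields must share one grid")
    tiles = _tile_shape(egrid, tile_count)
    hy, hx = egrid.ny // tiles[0], egrid.nx // tiles[1]
    tgrid = Grid(nx=hx, ny=hy, dx=egrid.dx)
    n = hy * hx
    if taper:
        wy = np.hanning(hy) if hy > 1 else np.ones(1)
        wx = np.hanning(hx)
        win = wy[:, None] * wx[None, :]
        win = win / np.sqrt((win**2).mean())
    else:
        win = np.ones((hy, hx))
    s_eb = np.zeros((hy, hx), dtype=complex)
    s_e = np.zeros((hy, hx))
    s_b = np.zeros((hy, hx))
    for te, tb in zip(_tile_views(ev, tiles), _tile_views(bv, tiles)):
        fe = np.fft.fft2((te - te.mean()) * win)
        fb = np.fft.fft2((tb - tb.mean()) * win)
        s_eb += np.conj(fe) * fb / n**2
        s_e += np.abs(fe) ** 2 / n**2
        s_b += np.abs(fb) ** 2 / n**2
    m = len(_tile_views(ev, tiles))
    return (Spectrum2D(tgrid, s_eb / m), Spectrum2D(tgrid, s_e / m),
            Spectrum2D(tgrid, s_b / m))


# ---------------------------------------------------------------------------
# radial / directional reductions
# ---------------------------------------------------------------------------

def radial_density(spectrum: Spectrum2D) -> RadialDensity:
    """Angular average of the density over rings of width 2*pi/L.

    Empty rings (possible beyond the Nyquist circle) are merged with
    their lower neighbour; the reduction is cut at the Nyquist radius.
    """
    grid = spectrum.grid
    kr = grid.k_radial()
    dk = 2.0 * np.pi / max(grid.lx, grid.ly if not grid.is_1d else grid.lx)
    idx = np.round(kr / dk).astype(int)
    nyq = np.pi / grid.dx
    nbin = int(np.floor(nyq / dk)) + 1
    sums = np.bincount(idx.ravel(), weights=spectrum.values.ravel().real,
                       minlength=nbin)[:nbin]
    counts = np.bincount(idx.ravel(), minlength=nbin)[:nbin]
    # merge empty rings downward
    for j in range(1, nbin):
        if counts[j] == 0:
            sums[j] = sums[j - 1]
            counts[j] = counts[j - 1]
    means = sums / np.maximum(counts, 1)
    k = np.arange(nbin) * dk
    # ring-integrated volume before normalization (conservation check)
    dkx, dky = spectrum.dk
    volume = float((means * counts).sum() * dkx * dky)
    integral = means.sum() * dk
    if integral > 0:
        means = means / integral
    return RadialDensity(kr=k, values=means, dk=dk, volume=volume)


def directional_density(spectrum: Spectrum2D, axis: str = "x") -> DirectionalDensity:
    """Density averaged along the other axis, folded onto the half-axis."""
    if axis == "x":
        line = spectrum.values.real.mean(axis=0)
        n, dk = spectrum.grid.nx, spectrum.dk[0]
    elif axis == "y":
        line = spectrum.values.real.mean(axis=1)
        n, dk = spectrum.grid.ny, spectrum.dk[1]
    else:
        raise ValueError("axis must be 'x' or 'y'")
    half = n // 2 + 1
    folded = line[:half].copy()
    for j in range(1, (n + 1) // 2):
        folded[j] += line[n - j]
    k = np.arange(half) * dk
    integral = folded.sum() * dk
    if integral > 0:
        folded = folded / integral
    return DirectionalDensity(k=k, values=folded, dk=dk, axis=axis)


# ---------------------------------------------------------------------------
# pattern metrics
# ---------------------------------------------------------------------------

def _smooth_density(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over radial bins.

    The mean bin (index 0) is excluded from the average — it is zero by
    construction and would drag down its neighbours — and kept as is.
    Edge bins average over the neighbours actually available.
    """
    if window <= 1 or len(values) < window + 2:
        return values
    ker = np.ones(window)
    body = values[1:]
    num = np.convolve(body, ker, mode="same")
    den = np.convolve(np.ones_like(body), ker, mode="same")
    out = values.copy()
    out[1:] = num / den
    return out


def _lobe_peak(k: np.ndarray, s: np.ndarray, skip: int = 2,
               s_floor: np.ndarray | None = None):
    """Lobe maximum with 3-point quadratic interpolation.

    The mean and the first ring are excluded from the search (spurious
    low-frequency components).  Returns ``(k_peak, s_peak)`` or ``None``
    when the maximum sits at the origin side (irregular pattern).
    ``s_floor`` is a more strongly smoothed copy of the density used for
    the lobe-at-origin decision (the innermost rings hold few Fourier
    cells, so the raw floor is noisy).
    """
    if len(s) <= skip + 1:
        return None
    if s_floor is None:
        s_floor = s
    i = skip + int(np.argmax(s[skip:]))
    if i == skip and s[skip] <= s[skip - 1]:
        return None  # density decays from the origin: lobe at k=0
    # a genuine lobe rises out of the low-wavenumber floor; a flat or
    # decaying (low-pass shaped) density does not
    floor = float(np.min(s_floor[1:i + 1]))
    if s[i] < 1.3 * floor:
        return None
    ties = [j for j in range(skip, len(s)) if s[j] == s[i]]
    i = min(ties)  # tie-break to the lower wavenumber
    if _is_multimodal(s, skip, i):
        warnings.warn("multimodal density; reporting the global maximum",
                      stacklevel=3)
    if 0 < i < len(s) - 1:
        y0, y1, y2 = s[i - 1], s[i], s[i + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        delta = float(np.clip(delta, -0.5, 0.5))
        k_peak = k[i] + delta * (k[1] - k[0])
        s_peak = y1 - 0.25 * (y0 - y2) * delta
    else:
        k_peak, s_peak = k[i], s[i]
    return float(k_peak), float(s_peak)


def _is_multimodal(s: np.ndarray, skip: int, imax: int) -> bool:
    """Two well-separated lobes: a second maximum above 60% of the peak
    with a valley below 40% of the peak in between."""
    smax = s[imax]
    interior = s[skip:]
    if len(interior) < 5 or smax <= 0:
        return False
    peaks = []
    for j in range(1, len(interior) - 1):
        if interior[j] > interior[j - 1] and interior[j] >= interior[j + 1] \
                and interior[j] > 0.6 * smax:
            peaks.append(j + skip)
    for a, b in zip(peaks[:-1], peaks[1:]):
        if s[a:b + 1].min() < 0.4 * smax:
            return True
    return False


def _half_power_cutoff(k: np.ndarray, s: np.ndarray) -> float:
    """Wavelength where a low-pass-shaped density drops to half its maximum."""
    if len(s) < 5:
        return float("nan")
    # the innermost rings contain few Fourier cells; average a handful
    # of them to stand in for S(0) (the mean itself was removed)
    s0 = float(np.mean(s[1:4]))
    below = np.nonzero(s[3:] <= 0.5 * s0)[0]
    if len(below) == 0:
        return float("nan")
    j = below[0] + 3
    if j == 3 and s[2] <= 0.5 * s0:
        return float(2.0 * np.pi / k[2])
    # linear interpolation between bins j-1 and j
    f = (s[j - 1] - 0.5 * s0) / max(s[j - 1] - s[j], 1e-300)
    kl = k[j - 1] + f * (k[j] - k[j - 1])
    return float(2.0 * np.pi / kl)


def pattern_metrics(density, smooth: int = 3) -> RegularitySummary:
    """Characteristic wavelength, regularity and cut-off of a density.

    Accepts a ``Spectrum2D`` (reduced radially), a ``RadialDensity``, or
    an ``(S_x+, S_y+)`` pair of ``DirectionalDensity`` for anisotropic
    patterns.  A centered ``smooth``-bin moving average is applied before
    the lobe search (periodogram-based profiles are noisy at the peak;
    3 bins keeps the bias of the lobe maximum below a few percent).
    Regularity is 0 with undefined wavelength when the lobe maximum is
    at the origin.
    """
    if isinstance(density, Spectrum2D):
        density = radial_density(density)

    if isinstance(density, RadialDensity):
        s = _smooth_density(density.values, smooth)
        s = s / (s.sum() * density.dk)
        s5 = _smooth_density(density.values, max(smooth, 5))
        s5 = s5 / (s5.sum() * density.dk)
        peak = _lobe_peak(density.kr, s, skip=2, s_floor=s5)
        if peak is None:
            lam_l = _half_power_cutoff(density.kr, s)
            return RegularitySummary(float("nan"), 0.0, cutoff=lam_l)
        kc, src = peak
        lam_c = 2.0 * np.pi / kc
        return RegularitySummary(lam_c, 2.0 * np.pi * src / lam_c)

    if isinstance(density, tuple) and len(density) == 2:
        sx, sy = density
        sxv = _smooth_density(sx.values, smooth)
        sxv = sxv / (sxv.sum() * sx.dk)
        sx5 = _smooth_density(sx.values, max(smooth, 5))
        sx5 = sx5 / (sx5.sum() * sx.dk)
        syv = _smooth_density(sy.values, smooth)
        syv = syv / (syv.sum() * sy.dk)
        peak = _lobe_peak(sx.k, sxv, skip=2, s_floor=sx5)
        if peak is None:
            lam_l = _half_power_cutoff(sx.k, sxv)
            return RegularitySummary(float("nan"), (0.0, 0.0), cutoff=lam_l)
        kc, sxc = peak
        lam_c = 2.0 * np.pi / kc
        syc = float(syv.max())
        return RegularitySummary(
            lam_c,
            (2.0 * np.pi * sxc / lam_c, 2.0 * np.pi * syc / lam_c),
        )

    raise TypeError("density must be Spectrum2D, RadialDensity or a "
                    "(DirectionalDensity, DirectionalDensity) pair")


# ---------------------------------------------------------------------------
# autocorrelation, transfer, coherence
# ---------------------------------------------------------------------------

def autocorrelation(field_or_spectrum) -> np.ndarray:
    """Wiener-Khinchin autocorrelation, 1 at zero lag."""
    if isinstance(field_or_spectrum, Spectrum2D):
        p = field_or_spectrum.values.real
    else:
        p = periodogram(field_or_spectrum).values
    r = np.fft.ifft2(p).real
    r0 = r.flat[0]
    if r0 <= 0:
        raise ValueError("zero-variance input has no autocorrelation")
    return r / r0


def transfer_estimate(e, b, tile_count=4, method: str = "cross",
                      scale: float = 1.0) -> TransferFunction2D:
    """Linear transfer function mapping heterogeneity e to pattern b.

    ``method='cross'`` uses the cross-spectral density T = S_eb / S_e;
    ``method='sqrt'`` uses the zero-phase approximation
    T = s * sqrt(S_b / S_e), valid for isotropic systems.  The mean
    (k=0) is excluded; wavenumbers where S_e vanishes are masked to 0.
    """
    s_eb, s_e, s_b = cross_density(e, b, tile_count)
    denom = s_e.values.copy()
    mask = denom <= 0
    denom[mask] = 1.0
    if method == "cross":
        t = s_eb.values / denom
    elif method == "sqrt":
        t = scale * np.sqrt(s_b.values / denom).astype(complex)
    else:
        raise ValueError("method must be 'cross' or 'sqrt'")
    t[mask] = 0.0
    t[0, 0] = 0.0
    return TransferFunction2D(s_e.grid, t, scale=scale)


def coherence(e, b, tile_count=4) -> CoherenceResult:
    """Tile-averaged spectral coherence and its density-weighted mean.

    Coherence of raw (untiled) periodograms is identically 1; at least
    four tiles are required.
    """
    tiles = _tile_shape(_as_values(e)[1], tile_count)
    if tiles[0] * tiles[1] < 4:
        raise ValueError("coherence estimation needs at least 4 tiles")
    s_eb, s_e, s_b = cross_density(e, b, tile_count)
    denom = s_e.values * s_b.values
    c = np.zeros_like(denom)
    ok = denom > 0
    c[ok] = np.abs(s_eb.values[ok]) ** 2 / denom[ok]
    c = np.clip(c, 0.0, 1.0)
    w = s_b.values.copy()
    w[0, 0] = 0.0  # the mean is not part of the spatial structure
    cbar = float((w * c).sum() / w.sum()) if w.sum() > 0 else 0.0
    c[0, 0] = 0.0
    return CoherenceResult(s_e.grid, c, cbar)


# ---------------------------------------------------------------------------
# periodicity test
# ---------------------------------------------------------------------------

def _isotropic_null_density(p: np.ndarray, grid: Grid) -> np.ndarray:
    """Smooth null density: ring means of the periodogram mapped back to 2D."""
    kr = grid.k_radial()
    dk = 2.0 * np.pi / max(grid.lx, grid.ly if not grid.is_1d else grid.lx)
    idx = np.round(kr / dk).astype(int)
    nbin = idx.max() + 1
    sums = np.bincount(idx.ravel(), weights=p.ravel(), minlength=nbin)
    counts = np.bincount(idx.ravel(), minlength=nbin)
    means = sums / np.maximum(counts, 1)
    # light 3-bin smoothing stabilizes the inner rings
    sm = means.copy()
    if nbin > 2:
        sm[1:-1] = (means[:-2] + means[1:-1] + means[2:]) / 3.0
    null = sm[idx]
    null[0, 0] = 0.0
    return null


def _max_ordinate_stat(values: np.ndarray, grid: Grid) -> float:
    p = periodogram(ScalarField(grid, values)).values
    null = _isotropic_null_density(p, grid)
    ok = null > 0
    return float((p[ok] / null[ok]).max())


def periodicity_test(field, n_surrogates: int = 99, seed: int = 0) -> float:
    """Monte-Carlo p-value against the null of a smooth spectral density.

    The statistic is the maximum periodogram ordinate relative to the
    isotropically smoothed density estimated from the field itself;
    surrogates are Gaussian random fields synthesized from that density
    and pushed through the identical estimation pipeline (parametric
    bootstrap).  Small p indicates a periodic pattern.
    """
    if n_surrogates < 99:
        raise ValueError("at least 99 surrogates are required")
    values, grid = _as_values(field)
    stat_obs = _max_ordinate_stat(values, grid)

    p = periodogram(ScalarField(grid, values)).values
    null = _isotropic_null_density(p, grid)
    amp = np.sqrt(null)
    rng = np.random.default_rng(seed)
    n_exceed = 0
    for _ in range(n_surrogates):
        white = rng.standard_normal(grid.shape)
        surr = np.fft.ifft2(amp * np.fft.fft2(white)).real
        if _max_ordinate_stat(surr, grid) >= stat_obs:
            n_exceed += 1
    return (1.0 + n_exceed) / (n_surrogates + 1.0)


# ---------------------------------------------------------------------------
# local phase along a transect
# ---------------------------------------------------------------------------

def local_phase(transect, dx: float = 1.0, kc: float | None = None,
                ref_index: int = 0, amp_floor: float = 0.1) -> PhaseProfile:
    """Analytic-signal amplitude, phase and local wavelength of a transect.

    ``dphi = phi - phi_ref - kc (x - x_ref)`` is the deviation of the
    unwrapped phase from the deterministic drift; ``kc`` defaults to the
    mean phase gradient.  Cells whose amplitude falls below ``amp_floor``
    times the median amplitude are flagged unreliable.
    """
    if isinstance(transect, ScalarField):
        dx = transect.grid.dx
        transect = transect.values
    u = np.asarray(transect, dtype=float).ravel()
    z = hilbert(u - u.mean())
    amplitude = np.abs(z)
    phase = np.unwrap(np.angle(z))
    grad = np.gradient(phase, dx)
    if kc is None:
        kc = float(np.median(grad))
    with np.errstate(divide="ignore"):
        wavelength = np.where(grad > 0, 2.0 * np.pi / np.maximum(grad, 1e-12),
                              np.inf)
    x = (np.arange(u.size) + 0.5) * dx
    dphi = phase - phase[ref_index] - kc * (x - x[ref_index])
    reliable = amplitude > amp_floor * np.median(amplitude)
    return PhaseProfile(x, amplitude, phase, wavelength, dphi, kc, reliable)


# ---------------------------------------------------------------------------
# Hellinger-distance fitting of parametric densities
# ---------------------------------------------------------------------------

def hellinger_fit(density, family: str, init=None):
    """Fit a parametric filter density by minimizing the Hellinger distance.

    ``family`` is one of ``lowpass``, ``bandpass``, ``oscillator-x``,
    ``oscillator-y``.  Minimizes ``int (sqrt(S_fit) - sqrt(S_emp))^2 dk``
    over the resolved wavenumbers (the mean bin is excluded) and reports
    the fitted parameter object and the goodness of fit
    ``R^2 = 1 - SSE/SST`` computed on the square-root densities.
    """
    from scipy.optimize import minimize

    from . import filters

    if isinstance(density, RadialDensity):
        k, s = density.kr, density.values
    elif isinstance(density, DirectionalDensity):
        k, s = density.k, density.values
    else:
        raise TypeError("density must be RadialDensity or DirectionalDensity")
    k, s = k[1:], s[1:]  # the mean is not part of the spatial structure
    dk = k[1] - k[0] if len(k) > 1 else 1.0

    model = filters.density_family(family)
    if init is None:
        init = filters.default_init(family, k, s)

    sqrt_emp = np.sqrt(np.maximum(s, 0.0))

    def objective(logp):
        params = np.exp(logp)
        sf = model(k, *params)
        tot = sf.sum() * dk
        if not np.isfinite(tot) or tot <= 0:
            return 1e6
        return float(((np.sqrt(sf / tot) - sqrt_emp) ** 2).sum() * dk)

    res = minimize(objective, np.log(np.asarray(init, dtype=float)),
                   method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 2000})
    if not res.success and res.fun > objective(np.log(np.asarray(init))):
        warnings.warn(f"Hellinger fit did not converge: {res.message}",
                      stacklevel=2)
    params = np.exp(res.x)
    sf = model(k, *params)
    sf = sf / (sf.sum() * dk)
    sse = ((np.sqrt(sf) - sqrt_emp) ** 2).sum()
    sst = ((sqrt_emp - sqrt_emp.mean()) ** 2).sum()
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return filters.make_params(family, params), float(r2)
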