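"""Periodic grids and gridded scalar fields.

All fields in the toolkit live on a regular, periodic grid with square
cells of physical size ``dx`` (metres).  The periodic convention matches
the FFT-based noise generation, integrators and spectral diagnostics:
wavenumbers span ``[-pi/dx, pi/dx)`` on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Regular periodic grid.

    Parameters
    ----------
    nx, ny : int
        Number of cells along x and y (``ny = 1`` for 1D problems).
    dx : float
        Cell size in metres (cells are square, ``dy = dx``).
    """

    nx: int
    ny: int = 1
    dx: float = 1.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid needs at least one cell per axis")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)`` of fields on this grid."""
        return (self.ny, self.nx)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def lx(self) -> float:
        return self.nx * self.dx

    @property
    def ly(self) -> float:
        return self.ny * self.dx

    @property
    def is_1d(self) -> bool:
        return self.ny == 1

    def x(self) -> np.ndarray:
        """Cell-centre x coordinates (origin at the domain corner)."""
        return (np.arange(self.nx) + 0.5) * self.dx

    def y(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.dx

    def kx(self) -> np.ndarray:
        """Angular wavenumbers along x (rad/m, FFT order)."""
        return 2.0 * np.pi * np.fft.fftfreq(self.nx, d=self.dx)

    def ky(self) -> np.ndarray:
        return 2.0 * np.pi * np.fft.fftfreq(self.ny, d=self.dx)

    def k_radial(self) -> np.ndarray:
        """Field of radial wavenumber magnitudes |k| over (ny, nx)."""
        kx = self.kx()[None, :]
        ky = self.ky()[:, None]
        return np.sqrt(kx**2 + ky**2)

    def lag_radial(self) -> np.ndarray:
        """Field of periodic lag distances |r| over (ny, nx)."""
        rx = self.dx * np.minimum(np.arange(self.nx), self.nx - np.arange(self.nx))
        ry = self.dx * np.minimum(np.arange(self.ny), self.ny - np.arange(self.ny))
        return np.hypot(rx[None, :], ry[:, None])


@dataclass
class ScalarField:
    """A scalar quantity (biomass, water depth, coefficient map) on a grid."""

    grid: Grid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def copy(self) -> "ScalarField":
        return ScalarField(self.grid, self.values.copy(), self.units)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())
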