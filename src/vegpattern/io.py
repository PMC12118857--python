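"""File formats, metrics records and fixture generation.

Gridded fields travel as NetCDF (CF-style ``y``/``x`` dimensions, cell
size and units in attributes), greyscale PNG, or GeoTIFF with the pixel
size in the TIFF resolution tags.  Metrics go to flat CSV/JSON records.
Every file carries a provenance block (package version, parameters,
seed) in its attributes or sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from PIL import Image

from . import __version__
from .grid import Grid, ScalarField

__all__ = [
    "read_pattern",
    "write_field",
    "write_state",
    "write_spectrum",
    "write_metrics",
    "metrics_record",
    "fixture_generator",
]

#: stable column order of metrics records
METRIC_COLUMNS = [
    "run_id", "wavelength", "regularity", "regularity_parallel",
    "cutoff", "p_value", "coherence", "c_a", "c_ie", "c_h",
    "cover", "r2_fit",
]


def _provenance(extra: dict | None = None) -> dict:
    prov = {"generator": f"vegpattern {__version__}"}
    if extra:
        prov.update({k: v for k, v in extra.items() if v is not None})
    return prov


# ---------------------------------------------------------------------------
# gridded fields
# ---------------------------------------------------------------------------

def write_field(field: ScalarField, path, **provenance) -> Path:
    """Write a scalar field; the format follows the file extension
    (``.nc``, ``.png``, ``.tif``/``.tiff``)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".nc":
        da = xr.DataArray(
            field.values, dims=("y", "x"),
            coords={"y": field.grid.y(), "x": field.grid.x()},
            name="field",
            attrs={"units": field.units, "dx": field.grid.dx,
                   **_provenance(provenance)},
        )
        da.to_netcdf(path, engine="scipy")
    elif suffix == ".png":
        v = field.values
        span = np.ptp(v)
        scaled = (255 * (v - v.min()) / span).astype(np.uint8) if span > 0 \
            else np.zeros_like(v, dtype=np.uint8)
        Image.fromarray(scaled, mode="L").save(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        # pixel size via the resolution tags: pixels per centimetre with
        # dx interpreted in metres scaled to a 1 cm = 1 m convention
        tifffile.imwrite(path, field.values.astype(np.float32),
                         resolution=(1.0 / field.grid.dx, 1.0 / field.grid.dx),
                         resolutionunit="CENTIMETER",
                         description=json.dumps(
                             {"dx": field.grid.dx, "units": field.units,
                              **_provenance(provenance)}))
    else:
        raise ValueError(f"unsupported field format {suffix!r}")
    return path


def read_pattern(path, dx: float | None = None,
                 binarize: bool = False) -> ScalarField:
    """Read a pattern raster from NetCDF, PNG or GeoTIFF.

    PNG values are scaled to [0, 1].  The cell size comes from the file
    metadata where available, otherwise ``dx`` is required.  With
    ``binarize`` the field is thresholded at its bimodal-histogram
    threshold on load.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".nc":
        with xr.open_dataarray(path, engine="scipy") as da:
            values = np.atleast_2d(da.values.astype(float))
            file_dx = float(da.attrs.get("dx", 0)) or None
            units = str(da.attrs.get("units", ""))
        dx = dx or file_dx
    elif suffix == ".png":
        img = Image.open(path).convert("L")
        values = np.asarray(img, dtype=float) / 255.0
        units = ""
    elif suffix in (".tif", ".tiff"):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = np.atleast_2d(page.asarray().astype(float))
            units = ""
            desc = page.tags.get("ImageDescription")
            if desc is not None:
                try:
                    meta = json.loads(desc.value)
                    dx = dx or float(meta.get("dx"))
                    units = meta.get("units", "")
                except (ValueError, TypeError):
                    pass
            if dx is None:
                xres = page.tags.get("XResolution")
                if xres is not None:
                    num, den = xres.value
                    if num:
                        dx = den / num
    else:
        raise ValueError(f"unsupported pattern format {suffix!r}")
    if dx is None:
        raise ValueError(
            f"{path.name} carries no pixel-size metadata; pass dx explicitly")
    grid = Grid(nx=values.shape[1], ny=values.shape[0], dx=dx)
    field = ScalarField(grid, values, units=units)
    if binarize:
        from .filters import cover_fraction, threshold

        field = threshold(field, cover_fraction(field))
    return field


def write_state(state, path, **provenance) -> Path:
    """Write a coupled (b, w, h) model state as one NetCDF dataset."""
    path = Path(path)
    grid = state.b.grid
    ds = xr.Dataset(
        {name: (("y", "x"), getattr(state, name).values)
         for name in ("b", "w", "h")},
        coords={"y": grid.y(), "x": grid.x()},
        attrs={"dx": grid.dx, "t": state.t, **_provenance(provenance)},
    )
    for name in ("b", "w", "h"):
        ds[name].attrs["units"] = getattr(state, name).units
    ds.to_netcdf(path, engine="scipy")
    return path


def write_spectrum(spectrum, path, **provenance) -> Path:
    """Write a 2D spectral density with its wavenumber coordinates (rad/m)."""
    path = Path(path)
    da = xr.DataArray(
        np.fft.fftshift(spectrum.values.real),
        dims=("ky", "kx"),
        coords={"ky": np.fft.fftshift(spectrum.ky),
                "kx": np.fft.fftshift(spectrum.kx)},
        name="density",
        attrs={"units": "density", "normalized": int(spectrum.normalized),
               **_provenance(provenance)},
    )
    da.to_netcdf(path, engine="scipy")
    return path


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def metrics_record(run_id: str, **metrics) -> dict:
    """One flat metrics record with the stable column order."""
    rec = {c: metrics.get(c, np.nan) for c in METRIC_COLUMNS}
    rec["run_id"] = run_id
    extra = set(metrics) - set(METRIC_COLUMNS)
    if extra:
        raise ValueError(f"unknown metric fields: {sorted(extra)}")
    return rec


def write_metrics(records, path, **provenance) -> Path:
    """Write metrics records as CSV (list/DataFrame) or JSON (any)."""
    path = Path(path)
    if isinstance(records, dict):
        records = [records]
    if path.suffix.lower() == ".json":
        payload = {"provenance": _provenance(provenance),
                   "records": list(records) if not isinstance(records, pd.DataFrame)
                   else records.to_dict(orient="records")}
        path.write_text(json.dumps(payload, indent=2, default=float))
    elif path.suffix.lower() == ".csv":
        df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
        cols = [c for c in METRIC_COLUMNS if c in df.columns]
        cols += [c for c in df.columns if c not in cols]
        df[cols].to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported metrics format {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def fixture_generator(suite: str) -> dict[str, ScalarField]:
    """Small seeded test assets, generated on the fly.

    ``spectral``: cosine and white-noise fields; ``filters``: band-pass
    syntheses at three regularities plus a hexagonal spot lattice;
    ``dynamics``: a 64² spotted micro-run of the water-vegetation model.
    """
    from . import filters as flt

    rng = np.random.default_rng(20240917)
    if suite == "spectral":
        grid = Grid(128, 128, 1.0)
        x = grid.x()[None, :]
        y = grid.y()[:, None]
        out = {
            "cosine": ScalarField(grid, np.broadcast_to(
                np.cos(2 * np.pi * x / 16.0), grid.shape).copy()),
            "diagonal": ScalarField(grid, np.cos(2 * np.pi * (x + y) / 16.0)),
            "white": ScalarField(grid, rng.standard_normal(grid.shape)),
        }
        return out
    if suite == "filters":
        grid = Grid(256, 256, 1.0)
        out = {}
        for reg in (0.5, 1.0, 2.0):
            params = flt.bandpass_params_for(24.0, reg)
            out[f"bandpass_reg{reg}"] = flt.synthesize(
                lambda k, p=params: flt.bandpass_density(k, p),
                grid=grid, seed=int(10 * reg))
        out["hexagonal"] = _hex_lattice(grid, spacing=24.0)
        return out
    if suite == "dynamics":
        from .dynamics import RietkerkParams, SimulationConfig, simulate_rietkerk

        grid = Grid(64, 64, 1.0)
        state = simulate_rietkerk(
            RietkerkParams(R_h=0.7, v_h=0.0, e_h=100.0),
            SimulationConfig(dt=0.25, t_end=1000.0, seed=3,
                             stat_window=200.0, min_time=400.0),
            grid=grid)
        return {"rietkerk_b": state.b, "rietkerk_w": state.w,
                "rietkerk_h": state.h}
    raise ValueError(f"unknown fixture suite {suite!r}")


def _hex_lattice(grid: Grid, spacing: float) -> ScalarField:
    """Binary hexagonal spot lattice (commensurate with the domain)."""
    nx_sp = max(int(round(grid.lx / spacing)), 1)
    sx = grid.lx / nx_sp
    sy_row = sx * np.sqrt(3.0) / 2.0
    n_rows = max(int(round(grid.ly / sy_row)), 1)
    sy = grid.ly / n_rows
    values = np.zeros(grid.shape)
    for row in range(n_rows):
        y = row * sy
        offset = (row % 2) * sx / 2.0
        for col in range(nx_sp):
            x = offset + col * sx
            ix, iy = int(x / grid.dx) % grid.nx, int(y / grid.dx) % grid.ny
            for ddy in range(-2, 3):
                for ddx in range(-2, 3):
                    if ddx**2 + ddy**2 <= 4:
                        values[(iy + ddy) % grid.ny, (ix + ddx) % grid.nx] = 1.0
    return ScalarField(grid, values)
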