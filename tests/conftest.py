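"""Shared fixtures.

The expensive model runs (grazing and water-vegetation simulations at
256 m) are session-scoped so the pipeline tests and the acceptance
tests share one integration each.
"""

from __future__ import annotations

import numpy as np
import pytest

from vegpattern import Grid, HeterogeneityParams, generate_field
from vegpattern import dynamics, spectra


@pytest.fixture(scope="session")
def grid256():
    return Grid(256, 256, 1.0)


@pytest.fixture(scope="session")
def grazing_cv01(grid256):
    """Grazing run with cv(K)=0.1 (theta_K = 1 m), plus its K map."""
    K = generate_field(HeterogeneityParams(8.0, 0.1, 1.0, seed=1), grid256)
    cfg = dynamics.SimulationConfig(dt=0.05, t_end=1500.0, init="homogeneous",
                                    b0=2.4724, seed=1, stat_window=1e12,
                                    min_time=1e12)
    b = dynamics.simulate_grazing(dynamics.GrazingParams(), cfg, K_field=K)
    return K, b


@pytest.fixture(scope="session")
def grazing_cv1(grid256):
    """Grazing run with strong heterogeneity cv(K)=1."""
    K = generate_field(HeterogeneityParams(8.0, 1.0, 1.0, seed=1), grid256)
    cfg = dynamics.SimulationConfig(dt=0.05, t_end=1000.0, init="homogeneous",
                                    b0=2.4724, seed=1, stat_window=1e12,
                                    min_time=1e12)
    b = dynamics.simulate_grazing(dynamics.GrazingParams(), cfg, K_field=K)
    return K, b


@pytest.fixture(scope="session")
def rietkerk_hom(grid256):
    """Spotted pattern in a homogeneous environment (R = 0.7 mm/d)."""
    params = dynamics.RietkerkParams(R_h=0.7, v_h=0.0, e_h=100.0)
    cfg = dynamics.SimulationConfig(dt=0.25, t_end=6000.0, seed=1,
                                    stat_window=200.0, min_time=1500.0)
    return dynamics.simulate_rietkerk(params, cfg, grid=grid256)


@pytest.fixture(scope="session")
def rietkerk_het03(grid256):
    """Spotted-regime run with heterogeneous infiltration, cv(a)=0.3."""
    a = generate_field(HeterogeneityParams(0.2, 0.3, 50.0, seed=2), grid256)
    params = dynamics.RietkerkParams(R_h=0.7, v_h=0.0, e_h=100.0)
    cfg = dynamics.SimulationConfig(dt=0.25, t_end=6000.0, seed=2,
                                    stat_window=200.0, min_time=1500.0)
    state = dynamics.simulate_rietkerk(params, cfg, a_field=a, grid=grid256)
    return a, state


@pytest.fixture(scope="session")
def striped_runs():
    """Three 1D hillslope stripe trains (R=1 mm/d, v=10 m/d), long horizon."""
    grid = Grid(1024, 1, 1.0)
    params = dynamics.RietkerkParams(R_h=1.0, v_h=10.0, e_h=(0.0, 0.0))
    out = []
    for seed in range(3):
        cfg = dynamics.SimulationConfig(dt=0.2, t_end=15000.0, seed=seed,
                                        stat_window=1e12, min_time=1e12)
        out.append(dynamics.simulate_rietkerk(params, cfg, grid=grid).b)
    return out
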