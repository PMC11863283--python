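"""Shared fixtures: small synthetic samples and configurations.

Scaled-down anatomy models (few rings, moderate densities) keep the suite
fast; the bundled presets are exercised where full-scale behaviour matters.
"""

import numpy as np
import pandas as pd
import pytest

from qwamap import (
    AnatomyModel,
    RunConfig,
    SampleTable,
    generate_sample,
    make_ring_table,
)


@pytest.fixture(scope="session")
def config():
    return RunConfig(rng_seed=1)


@pytest.fixture(scope="session")
def small_diffuse_model():
    return AnatomyModel(
        porosity="diffuse",
        n_rings=5,
        ring_width_mean=1200.0,
        ring_width_sd=200.0,
        vessel_density_target=80.0,
        fibre_fill_fraction=0.15,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_ring_porous_model():
    return AnatomyModel(
        porosity="ring_porous",
        n_rings=4,
        ring_width_mean=2000.0,
        ring_width_sd=250.0,
        vessel_density_target=18.0,
        ew_weight=0.12,
        fibre_fill_fraction=0.1,
        radial_size_trend=1.0,
        rng_seed=12,
    )


@pytest.fixture(scope="session")
def diffuse_truth(small_diffuse_model, config):
    return generate_sample(small_diffuse_model, config)


@pytest.fixture(scope="session")
def ring_porous_truth(small_ring_porous_model):
    cfg = RunConfig(cutoff=5000.0, sector_width=450.0, rng_seed=1)
    return generate_sample(small_ring_porous_model, cfg)


def build_table(areas, years=None, ring_width=2400.0, aoi=None, x=None, method="thin_section"):
    """Minimal hand-built SampleTable for arithmetic tests."""
    areas = np.asarray(areas, dtype=float)
    n = len(areas)
    if years is None:
        years = np.full(n, 2000, dtype=int)
    years = np.asarray(years, dtype=int)
    uniq = np.unique(years) if n else np.array([2000])
    rings = make_ring_table(uniq, np.full(len(uniq), ring_width), aoi_areas=aoi)
    starts = {y: i * ring_width for i, y in enumerate(uniq)}
    if x is None:
        rng = np.random.default_rng(0)
        x = np.array([starts[y] + rng.uniform(0, ring_width) for y in years])
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "year": years,
            "x_cal_um": x,
            "y_cal_um": np.linspace(10, 4990, n) if n else [],
            "lumen_area_um2": areas,
            "major_axis_um": np.nan,
            "minor_axis_um": np.nan,
            "rad_dist_um": np.nan,
            "rad_dist_pct": np.nan,
            "cell_class": "unclassified",
        }
    )
    from qwamap import compute_rad_dist

    cells = compute_rad_dist(cells, rings)
    return SampleTable(
        sample_id="hand",
        species="test",
        method=method,
        resolution_ppum=2.27,
        cells=cells,
        rings=rings,
    ).validate()


@pytest.fixture
def hand_table():
    return build_table
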