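import numpy as np
import pytest

from vinecanopy import SiteConfig, SyntheticSiteSpec, build_grid, generate_site
from vinecanopy.synthetic import site_rows


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def tiny_spec():
    """Two short rows, flat ground, fast to render at 2 cm resolution."""
    return SyntheticSiteSpec(
        n_rows=2,
        row_length=8.1,
        inter_row=2.5,
        intra_row=0.9,
        row_azimuth=90.0,
        terrain_slope=0.0,
        terrain_noise_sd=0.005,
        missing_fraction=0.0,
        per_vine_size_cv=0.05,
        point_density=150.0,
        dem_dp=0.02,
        seed=42,
    )


@pytest.fixture
def tiny_cfg(tiny_spec):
    return SiteConfig(
        inter_row=tiny_spec.inter_row,
        intra_row=tiny_spec.intra_row,
        row_azimuth=tiny_spec.row_azimuth,
    )


@pytest.fixture
def tiny_site(tiny_spec, tiny_cfg):
    truth = generate_site(tiny_spec)
    cells = build_grid(site_rows(tiny_spec), tiny_cfg)
    return tiny_spec, tiny_cfg, truth, cells
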