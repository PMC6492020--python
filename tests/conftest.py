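import numpy as np
import pytest

from xylemct.synthetic import (DiameterDistribution, OrganSimConfig, XylemRegion,
                               generate_cross_section, generate_final_scan,
                               organ_preset)


@pytest.fixture
def small_config():
    """Small, fast, noiseless section: ~50 well-separated conduits."""
    return OrganSimConfig(
        organ_label="test_organ",
        vessel_density_per_mm2=180.0,
        diameter_dist=DiameterDistribution.from_targets(16.0, 22.0, 10.0, 40.0),
        weibull_scale_mpa=2.5,
        weibull_shape=3.0,
        xylem_region=XylemRegion(outer_radius_um=300.0),
        image_size_px=(350, 350),
        pixel_size_um=2.0,
        seed=11,
    )


@pytest.fixture
def section_pair(small_config):
    """(initial image, truth, final image) at psi = -2.2 MPa."""
    image, truth = generate_cross_section(small_config, -2.2)
    final = generate_final_scan(truth, small_config)
    return image, truth, final


@pytest.fixture
def beech_stem_config():
    return organ_preset("beech_stem", image_size_px=(400, 400), seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
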