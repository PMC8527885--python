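import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from biofilmquant import simdata

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bfneg_section():
    """Default-noise BF− section with ground truth (session-cached)."""
    cfg = simdata.SectionSimConfig(bf_status="BF-", seed=11)
    return simdata.gen_section(cfg) + (cfg,)


@pytest.fixture(scope="session")
def bfpos_section():
    """Default-noise BF+ section, 4 fields, with ground truth."""
    cfg = simdata.SectionSimConfig(bf_status="BF+", n_fields=4, seed=11)
    return simdata.gen_section(cfg) + (cfg,)


@pytest.fixture(scope="session")
def small_noiseless_cfg():
    """Tiny fast section: 50 um field at 0.25 um/px (200 px), no noise."""
    return simdata.SectionSimConfig(
        field_size_um=50.0, pixel_size_um=0.25, n_fields=1, noise="none",
        bf_status="BF-", mean_count_bfneg=6.0, mucus_gap_um=10.0,
        adherent_band_um=8.0, epithelium_margin_um=12.0,
        epithelium_amplitude_um=2.0, seed=7)
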