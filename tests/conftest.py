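import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from coastalch4 import SyntheticSiteSpec, profile_from_arrays


@pytest.fixture
def rng():
    return np.random.default_rng(20240605)


@pytest.fixture
def porewater_profile():
    """Small hand-built porewater profile: CH4 rising, SO4 falling."""
    return profile_from_arrays(
        [0.0, 0.025, 0.05, 0.075, 0.1], "porewater",
        ch4=[0.0, 500.0, 1000.0, 1400.0, 1700.0],
        so4=[3600.0, 2400.0, 1000.0, 400.0, 150.0],
        porosity=[0.9] * 5,
    )


@pytest.fixture
def stratified_spec():
    """Noise-free euxinic stratified site with every truth planted."""
    return SyntheticSiteSpec(
        seed=11, site_id="STRAT", redox_true="euxinic",
        oxycline_depth_true=10.0, smtz_depth_true=0.03, F_sed_true=4.0,
        escape_true=0.3, f_bubble_true=0.1, alpha_true=1.0107,
        noise_cv=0.0, delta_noise=0.0,
    )


@pytest.fixture
def mixed_oxic_spec():
    """Noise-free fully mixed oxic site (no oxycline)."""
    return SyntheticSiteSpec(
        seed=12, site_id="MIXED", redox_true="oxic", oxycline_depth_true=None,
        smtz_depth_true=0.05, F_sed_true=2.4, escape_true=0.08,
        f_bubble_true=0.67, noise_cv=0.0, delta_noise=0.0,
    )
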