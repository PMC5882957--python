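import dataclasses

import pytest

from estronet import SyntheticDesign, simulate_dataset


def scaled_design(**overrides) -> SyntheticDesign:
    """A scaled-down study design for fast unit tests: same structure as
    the default (3 tissues x 7 days x 3 replicates, planted modules,
    bridging straddle pairs, connectors, background), ~135 genes."""
    base = dict(
        module_sizes={
            "endometrium_up": 20,
            "endometrium_down": 15,
            "ovary_up": 20,
            "ovary_down": 15,
            "oviduct_down": 20,
        },
        n_bridging=12,
        connectors_per_side=2,
        n_background=21,
        seed=7,
    )
    base.update(overrides)
    return dataclasses.replace(SyntheticDesign(), **base)


@pytest.fixture(scope="session")
def small_design():
    return scaled_design()


@pytest.fixture(scope="session")
def small_dataset(small_design):
    return simulate_dataset(small_design)


@pytest.fixture(scope="session")
def noisefree_design():
    return scaled_design(noise_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_dataset(noisefree_design):
    return simulate_dataset(noisefree_design)
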