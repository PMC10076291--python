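import numpy as np
import pytest

from spacerlink.synthetic_data import SyntheticConfig, generate_community


@pytest.fixture(scope="session")
def small_community():
    """A compact community exercising links at 0/1/2 mismatches plus viral
    arrays, conflicts, proviruses and Chi planting -- shared across tests."""
    cfg = SyntheticConfig(
        n_hosts=6,
        n_viruses=24,
        seed=11,
        planted_links=(
            (0, 1, 3, 0),
            (1, 2, 2, 1),
            (2, 3, 2, 2),
            (3, 4, 2, 0),
        ),
        viral_array_spec=(
            (10, 4, ((11, "protospacer"), (12, "shared_spacer"))),
            (12, 3, ()),
        ),
        provirus_spec=(
            (10, 0, 1.0, 4000, "integrated"),
            (13, 1, 0.95, 5000, "cobinned"),
        ),
        chi_spec={20: 4, 21: 0},
    )
    return generate_community(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
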