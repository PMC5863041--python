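import numpy as np
import pandas as pd
import pytest

import slimfoot as sf


@pytest.fixture(scope="session")
def small_params():
    return sf.SimulationParams(n_sites_per_class=5, fragments_per_site=200, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_params):
    return sf.build_site_panel(small_params)


@pytest.fixture(scope="session")
def small_chip(small_panel, small_params):
    return sf.simulate_chip_fragments(small_panel, small_params, seed=12)


@pytest.fixture()
def toy_fragments():
    """Hand-built fragment set on a 1 kb chromosome."""
    frags = pd.DataFrame({
        "chrom": ["chrI"] * 4,
        "start": [10, 10, 100, 300],
        "end": [20, 20, 180, 447],
        "name": ["a", "b", "c", "d"],
        "strand": ["."] * 4,
    })
    return sf.FragmentSet(frags, {"chrI": 1000})


def anchors_frame(positions, strands, chrom="chrI", names=None):
    names = names or [f"a{i}" for i in range(len(positions))]
    return pd.DataFrame({"chrom": chrom, "pos": positions,
                         "strand": strands, "name": names})
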