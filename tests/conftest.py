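import numpy as np
import pytest
from hypothesis import settings

import imctc
from imctc.binmap import BinMap

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bin_map_5k() -> BinMap:
    """A 5000-bin, 24-chromosome genome, the scale used for real profiles."""
    return imctc.make_bin_map(5000, 24, seed=11)


@pytest.fixture(scope="session")
def flat_bin_map() -> BinMap:
    """2000 equal-length bins over 4 chromosomes (no length confound)."""
    n, L = 2000, 500_000
    chrom = np.repeat([f"chr{i}" for i in range(1, 5)], n // 4).astype(object)
    start = np.tile(np.arange(n // 4) * L, 4)
    rng = np.random.default_rng(3)
    gc = 0.2 + 0.6 * rng.beta(2.5, 3.5, size=n)
    return BinMap(chrom, start, start + L, gc)


@pytest.fixture(scope="session")
def index_truth(bin_map_5k):
    return imctc.make_truth_profile(
        bin_map_5k, imctc.index_clone_events(bin_map_5k), clone="index"
    )


@pytest.fixture(scope="session")
def annotated_populations():
    """The two CK+ phenotypes of a human-annotated training subset, with
    well-separated CD45 intensity distributions."""
    return [
        imctc.FeaturePopulation("im.CTC", 0.7, 320, 25, 180, 25, "CD45+/CK+"),
        imctc.FeaturePopulation("epi.CTC", 0.3, 320, 25, 20, 8, "CD45-/CK+"),
    ]
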