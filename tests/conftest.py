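import numpy as np
import pytest

import bulkmap as bm
from bulkmap.pipeline import records_from_simulation


@pytest.fixture(scope="session")
def design():
    return bm.BulkDesign()  # 22 low / 24 high


@pytest.fixture(scope="session")
def exact_null(design):
    return bm.null_threshold_exact(design)


@pytest.fixture(scope="session")
def small_map():
    """Two short chromosomes with markers every 20 kb — fast to simulate."""
    chroms = [("chr1", 2_000_000, 50.0), ("chr2", 1_500_000, 50.0)]
    snps = {name: list(range(20_000, plen + 1, 20_000)) for name, plen, _ in chroms}
    return bm.GenomeMap(chromosomes=chroms, snp_positions=snps)


@pytest.fixture(scope="session")
def default_simulation():
    """One full experiment at the study conditions (116 RILs, 22/24 bulks)."""
    return bm.simulate_experiment(seed=1)


@pytest.fixture(scope="session")
def default_records(default_simulation):
    return records_from_simulation(default_simulation)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)
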