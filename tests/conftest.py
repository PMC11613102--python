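import pytest

from hmcprog.fixtures import table12_cohort, toy_catalog
from hmcprog.simulate import HmcSimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """500-feature simulated count matrix with planted effects (session-wide)."""
    cfg = HmcSimConfig(n_features=500, frac_differential=0.1, delta_log2fc=1.0, seed=42)
    counts, meta, truth = simulate_counts(cfg)
    return counts, meta, truth


@pytest.fixture(scope="session")
def cohort_fixture():
    return table12_cohort()


@pytest.fixture()
def catalog():
    return toy_catalog()


@pytest.fixture()
def catalog_file(tmp_path, catalog):
    path = tmp_path / "catalog.bed"
    catalog.to_csv(path, sep="\t", header=False, index=False)
    return path
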