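from pathlib import Path

import pytest

from convergeomics.simulate import SimConfig, write_bundle

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact study: 400 genes, 120 miRNAs, 80 CpG clusters, strong
    shared signal."""
    return SimConfig(
        seed=7,
        n_genes=400,
        n_mirna=120,
        n_cpg_sites=400,
        rho_shared=0.8,
        frac_de=0.15,
    )


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_config, outdir)
    return outdir, paths


@pytest.fixture
def toy_mirna_paths():
    return DATA_DIR / "toy_mirna_counts.csv", DATA_DIR / "toy_mirna_samples.csv"


@pytest.fixture
def toy_coverage_path():
    return DATA_DIR / "toy_sites.cov"
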