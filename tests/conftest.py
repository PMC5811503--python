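import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from gwaboost.simulate import SimulationConfig, generate, generate_bundle


@pytest.fixture(scope="session")
def small_cfg():
    """A fast, small synthetic configuration for unit-level pipeline tests."""
    return SimulationConfig(
        n_genes=300,
        n_snps=3000,
        genome_length=1_500_000,
        module_size=20,
        module_extra_edges=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_instance(small_cfg):
    """In-memory (network, genes, snps, reference, truth) bundle."""
    return generate(small_cfg)


@pytest.fixture(scope="session")
def small_bundle(small_cfg, tmp_path_factory):
    """The same small bundle written to disk as the four input files."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_bundle(small_cfg, outdir)
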