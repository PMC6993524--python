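import numpy as np
import pytest

from sipreads.gradient import GradientParams


@pytest.fixture(scope="session")
def params() -> GradientParams:
    """Default gradient: TLA-110-like fixed-angle rotor at 55 krpm, 20 C."""
    return GradientParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fixture_experiment(tmp_path_factory):
    """A small ready-to-run synthetic experiment (5 genomes, 1 sample)."""
    from sipreads.fixtures import make_fixture_set

    outdir = tmp_path_factory.mktemp("fixture_exp")
    cfg_path = make_fixture_set(
        outdir,
        seed=7,
        genome_length=60_000,
        total_pairs=4000,
        coverage=1.5,
    )
    return cfg_path
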