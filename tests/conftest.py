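import numpy as np
import pytest

from pempni.synthetic_fixtures import (
    SyntheticSpec,
    add_noise_groups,
    build_energy_dataset,
    generate,
    make_dataset,
)


@pytest.fixture(scope="session")
def toy_spec():
    return SyntheticSpec(seed=7, n_complexes=3, mutations_per_complex=2)


@pytest.fixture(scope="session")
def toy_complexes(toy_spec):
    return generate(toy_spec)


@pytest.fixture(scope="session")
def toy(toy_complexes):
    return toy_complexes[0]


@pytest.fixture(scope="session")
def bundle_dir(toy_spec, tmp_path_factory):
    root = tmp_path_factory.mktemp("bundle")
    make_dataset(toy_spec, root)
    return root


@pytest.fixture(scope="session")
def bench_spec():
    """The synthetic regression benchmark: 40 complexes x 6 mutations,
    ddG linear in the planted whole-complex energy change, sigma 0.3."""
    return SyntheticSpec(seed=11, n_complexes=40, mutations_per_complex=6,
                         noise_sigma=0.3)


@pytest.fixture(scope="session")
def bench_dataset(bench_spec):
    ds, truth = build_energy_dataset(bench_spec, groups=("EWC",))
    ds = add_noise_groups(ds, ["noiseA", "noiseB", "noiseC"], dim=10, seed=99)
    return ds, truth
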