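import pytest

from poolsweep.simulate import SimulationConfig, SweepSpec, write_fixture_bundle


@pytest.fixture(scope="session")
def bundle_config():
    return SimulationConfig(
        n_populations=4,
        contig_lengths={"contig1": 500_000, "contig2": 400_000},
        snv_density=0.004,
        mean_depth=30.0,
        sweep_specs=(
            SweepSpec("contig1", 200_000, 250_000, (0,), 1.0),
            SweepSpec("contig2", 100_000, 150_000, (1,), 1.0),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def bundle(bundle_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture_bundle")
    return write_fixture_bundle(bundle_config, out)
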