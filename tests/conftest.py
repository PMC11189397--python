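import pathlib

import pytest

from epco2.io import RunConfig
from epco2.params import McConfig, ProxyParams
from epco2.synth import TruthScenario, generate_dataset


@pytest.fixture(scope="session")
def noiseless_scenario():
    return TruthScenario(
        seed=7, noise_d13c=0.0, noise_gdgt_sst=0.0, noise_foram=0.0, noise_dsst=0.0
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_scenario):
    return generate_dataset(noiseless_scenario)


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(TruthScenario(seed=11))


@pytest.fixture
def written_noiseless(noiseless_dataset, tmp_path) -> dict[str, pathlib.Path]:
    return noiseless_dataset.write(tmp_path / "data")


@pytest.fixture
def noiseless_config(written_noiseless, tmp_path) -> RunConfig:
    cfg = RunConfig(
        samples=written_noiseless["samples"],
        foram=written_noiseless["foram"],
        dsst=written_noiseless["dsst"],
        aux_sst=written_noiseless["aux_sst"],
        outdir=tmp_path / "out",
    )
    cfg.proxy_params = ProxyParams().exact()
    cfg.mc = McConfig(n_draws=200, seed=0)
    return cfg
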