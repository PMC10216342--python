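import pytest

from tsrseg.experiments import (run_scaled_bpn, run_scaled_unet,
                                scaled_dataset)

SEED = 0


@pytest.fixture(scope="session")
def dataset():
    return scaled_dataset(seed=SEED)


@pytest.fixture(scope="session")
def bpn_run(dataset):
    return run_scaled_bpn(dataset, seed=SEED)


@pytest.fixture(scope="session")
def unet_run(dataset):
    return run_scaled_unet(dataset, seed=SEED)
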