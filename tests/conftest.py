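import logging

import pytest

from lglwgs.simulate import SimulationConfig, simulate_dataset

logging.getLogger("lglwgs").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """One default synthetic run (seed 0) with artifacts on disk, shared
    across tests that only read it."""
    outdir = tmp_path_factory.mktemp("default_run")
    return simulate_dataset(SimulationConfig(), outdir=outdir), outdir


@pytest.fixture(scope="session")
def fitted_cnv(default_dataset):
    from lglwgs.coverage import CopyNumberModel

    ds, _ = default_dataset
    model = CopyNumberModel(ds.coverage, sample="tumor")
    return ds, model.fit()
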