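import numpy as np
import pytest

from sdrpred.binding_db import BindingCoreStore, CoreRecord, build_store
from sdrpred.hla import SDRConfiguration
from sdrpred.simulate import (
    generate_panel,
    paired_sharing,
    records_from_peptides,
    sample_cores,
)


@pytest.fixture(scope="session")
def config():
    return SDRConfiguration.default()


@pytest.fixture(scope="session")
def paired_panel(config):
    """Five synthetic allotypes where consecutive pairs share all pockets
    (groups 0,0,1,1,2) — the last allotype has no SDR-similar partner."""
    return generate_panel(5, paired_sharing(5, config), seed=1, sdr_config=config)


@pytest.fixture(scope="session")
def paired_store(paired_panel, config):
    """Store built from 60 sampled 9-mer cores per paired-panel allotype."""
    allotypes, truths, _ = paired_panel
    records = []
    for i, truth in enumerate(truths):
        cores = sample_cores(truth, 60, seed=100 + i, sdr_config=config)
        records += records_from_peptides(truth.allotype, cores, seed=200 + i)
    return build_store(records, allotypes, config, seed=7)


def store_from_cores(profiles: dict, cores_by_allele: dict) -> BindingCoreStore:
    """Hand-assemble a store from explicit core strings (test helper)."""
    return BindingCoreStore(
        cores={
            a: [CoreRecord(a, c, c, 0) for c in cs]
            for a, cs in cores_by_allele.items()
        },
        profiles=profiles,
        meta={},
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
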