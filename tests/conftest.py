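import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make _oracles importable

from sorfconstraint.io_formats import variant_sites_from_frame
from sorfconstraint.pipeline import PipelineResult, run_pipeline
from sorfconstraint.synthetic import SimulationConfig, SyntheticDataset, simulate

#: the study seed; every stochastic end-to-end check runs under it
STUDY_SEED = 42


@pytest.fixture(scope="session")
def neutral_dataset() -> SyntheticDataset:
    """Default synthetic dataset: selection factors all 1 (neutral callset)."""
    return simulate(SimulationConfig(seed=STUDY_SEED))


@pytest.fixture(scope="session")
def neutral_result(neutral_dataset) -> PipelineResult:
    ds = neutral_dataset
    return run_pipeline(
        ds.genome, ds.sorfs, variant_sites_from_frame(ds.variants), ds.rates, ds.methylation
    )


@pytest.fixture(scope="session")
def selection_dataset() -> SyntheticDataset:
    """Same conditions with missense variants depleted twofold."""
    return simulate(SimulationConfig(seed=STUDY_SEED, selection={"missense": 0.5}))


@pytest.fixture(scope="session")
def selection_result(selection_dataset) -> PipelineResult:
    ds = selection_dataset
    return run_pipeline(
        ds.genome, ds.sorfs, variant_sites_from_frame(ds.variants), ds.rates, ds.methylation
    )
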