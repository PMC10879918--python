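import numpy as np
import pytest

from isobmr import (
    ExperimentDesign,
    PipelineConfig,
    SyntheticTruth,
    generate_design,
    run_pipeline,
    simulate_counts,
)

CHEM = "aflatoxin B1"


@pytest.fixture(scope="session")
def small_design() -> ExperimentDesign:
    return ExperimentDesign(chemicals=[CHEM])


@pytest.fixture(scope="session")
def small_truth() -> SyntheticTruth:
    return SyntheticTruth(n_genes=300, seed=11).realise()


@pytest.fixture(scope="session")
def small_dataset(small_design, small_truth):
    ann = generate_design(small_design, seed=11)
    counts = simulate_counts(small_truth, ann)
    return counts, ann


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    counts, ann = small_dataset
    cfg = PipelineConfig(n_perm=199, seed=11, mode="per-replicate")
    return run_pipeline(counts, ann, CHEM, cfg)
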