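import numpy as np
import pytest

from hybridexpress.core_io import CountMatrix, SampleSheet
from hybridexpress.synthetic_data import SimConfig, default_sample_sheet


@pytest.fixture
def sheet() -> SampleSheet:
    return default_sample_sheet()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130523)


@pytest.fixture
def small_counts(rng, sheet) -> CountMatrix:
    counts = rng.poisson(100, size=(50, len(sheet.sample_ids)))
    return CountMatrix(
        contig_ids=[f"c{i:03d}" for i in range(50)],
        sample_ids=list(sheet.sample_ids),
        counts=counts,
    )


@pytest.fixture
def null_config(sheet) -> SimConfig:
    return SimConfig(
        n_contigs=300,
        samples=sheet,
        fraction_parent_diff=0.0,
        fraction_cis=0.0,
        fraction_transgressive=0.0,
        fraction_high_variance=0.0,
        snps_per_contig_mean=0.0,
        seed=11,
    )
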