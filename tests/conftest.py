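import warnings

import pytest

from rrmbind import (FixtureSpec, PipelineConfig, generate_cluster,
                     run_pipeline)

PLANTED = [
    ("β1–1", "K", "G", 4.0),
    ("β3–5", "R", "A", 4.0),
    ("loop5–2", "N", "U", 4.0),
]


@pytest.fixture(scope="session")
def planted_fixture():
    """A seeded synthetic cluster with three isolated planted preferences."""
    master, entries, truth = generate_cluster(FixtureSpec(
        seed=7, n_uniprot_groups=30, planted_preferences=list(PLANTED)))
    return master, entries, truth


@pytest.fixture(scope="session")
def pipeline_result(planted_fixture):
    """Full pipeline run on the planted cluster."""
    master, entries, _ = planted_fixture
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(entries, PipelineConfig(seed=11), master=master)


@pytest.fixture(scope="session")
def coded_result():
    """Pipeline run on a cluster with a full planted recognition code.

    Every interface residue prefers its own nucleotide, which is what
    gives the leave-one-out scores their binder/non-binder separation.
    """
    master, entries, truth = generate_cluster(FixtureSpec(
        seed=7, n_uniprot_groups=30, code_enrichment=4.0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(entries, PipelineConfig(seed=11),
                              master=master)
    return result, truth


@pytest.fixture(scope="session")
def fitted(pipeline_result):
    return pipeline_result.results
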