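import pytest

from cernet.synthetic_data import (
    SimulationParams,
    generate_annotation,
    generate_expression,
    generate_sequences,
)

SMALL = SimulationParams(
    n_mirna=4,
    n_mrna=12,
    n_lncrna=6,
    n_planted_triplets=4,
    samples_per_condition=6,
    mrna_len=400,
    lncrna_len=300,
    seed=7,
)


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    return SMALL


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """Small planted dataset: (transcripts, annotation, expression, trait, truth)."""
    transcripts, truth = generate_sequences(small_params)
    transcripts, annotation = generate_annotation(small_params, transcripts, truth)
    expr, trait, truth = generate_expression(small_params, transcripts, truth)
    return transcripts, annotation, expr, trait, truth


@pytest.fixture(scope="session")
def small_bundle(small_params, tmp_path_factory):
    from cernet.synthetic_data import write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_params, outdir)
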