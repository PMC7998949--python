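import pytest

from fivep.synthetic_degradome import (
    DecayModelParams,
    build_toy_reference,
    sample_fiveprime_ends,
)


@pytest.fixture(scope="session")
def small_params():
    return DecayModelParams(n_transcripts=8, total_reads=20_000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_params):
    """A small but fully structured simulation shared across tests."""
    genomes, models = build_toy_reference(small_params)
    truth = sample_fiveprime_ends(small_params, models)
    return genomes, models, truth


@pytest.fixture(scope="session")
def small_ends(small_sim, small_params):
    from fivep.fiveprime_counts import extract_five_prime_ends
    from fivep.synthetic_degradome import iter_alignment_records

    genomes, models, truth = small_sim
    return extract_five_prime_ends(iter_alignment_records(truth, models))
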