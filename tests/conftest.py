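import pytest

import splicequery as sq


@pytest.fixture(scope="session")
def models():
    return sq.load_reference_transcripts()


@pytest.fixture(scope="session")
def model_by_id(models):
    return {t.transcript_id: t for t in models}


@pytest.fixture(scope="session")
def catalog(models):
    return sq.JunctionCatalog(models)


@pytest.fixture(scope="session")
def genome(models):
    return sq.simulate_genome(seed=7, models=models)


@pytest.fixture(scope="session")
def queries(catalog, genome):
    return catalog.queries(genome)
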