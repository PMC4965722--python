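import pytest

from bioir import PipelineConfig, build_index


@pytest.fixture(scope="session")
def plain_config():
    """Pipeline with no stopwords and no stemming: tokens index verbatim."""
    return PipelineConfig(stopwords=frozenset(), stemmer="none")


@pytest.fixture(scope="session")
def toy_docs():
    # hand-countable three-document corpus
    return [
        ("d1", "gene expression cancer gene"),
        ("d2", "protein cancer pathway"),
        ("d3", "gene therapy trial"),
    ]


@pytest.fixture(scope="session")
def toy_index(toy_docs, plain_config):
    return build_index(toy_docs, plain_config)
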