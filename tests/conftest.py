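import pytest

from litanno import fixtures, store, vocab

CORPUS_SEED = 11


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("demo_corpus")
    ledger = fixtures.generate_corpus(CORPUS_SEED, 5, out)
    return out, ledger


@pytest.fixture(scope="session")
def ledger(demo_dir):
    return demo_dir[1]


@pytest.fixture(scope="session")
def corpus(demo_dir):
    return store.load_corpus(demo_dir[0])


@pytest.fixture(scope="session")
def vocab_tree(ledger):
    return vocab.load_vocabulary(ledger.param_csv, ledger.terms_csv)
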