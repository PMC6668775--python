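import pytest

from ndra.fixtures import FixtureConfig, generate_lexicon
from ndra.lexicon import LexiconEntry
from ndra.networks import train_model
from ndra.visual import default_complexity_table


@pytest.fixture(scope="session")
def bear_lexicon():
    """Tiny lexicon around 'bear' with orthographic neighbors."""
    return [
        LexiconEntry("bear", "b8R", 20_000),
        LexiconEntry("fear", "f8R", 8_000),
        LexiconEntry("year", "j7R", 12_000),
        LexiconEntry("band", "b{nd", 15_000),
        LexiconEntry("land", "l{nd", 9_000),
        LexiconEntry("hand", "h{nd", 18_000),
        LexiconEntry("dish", "dIS", 5_000),
    ]


@pytest.fixture(scope="session")
def bear_model(bear_lexicon):
    return train_model(bear_lexicon, sublexical=True)


@pytest.fixture(scope="session")
def consistent_lexicon():
    """Fully consistent synthetic lexicon (every body -> one rime)."""
    return generate_lexicon(
        FixtureConfig(seed=3, n_words=300, n_bodies=60, consistency_mix=0.0)
    )


@pytest.fixture(scope="session")
def consistent_model(consistent_lexicon):
    return train_model(consistent_lexicon)


@pytest.fixture(scope="session")
def complexity_table():
    return default_complexity_table()
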