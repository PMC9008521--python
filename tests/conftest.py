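import datetime as dt

import numpy as np
import pytest

from discourselens.sentiment import SentimentLexicon, load_lexicon


@pytest.fixture(scope="session")
def lexicon() -> SentimentLexicon:
    """The bundled synthetic demonstration lexicon."""
    return load_lexicon()


@pytest.fixture
def tiny_lexicon() -> SentimentLexicon:
    return SentimentLexicon({"good": 7.0, "bad": 3.0, "ok": 5.0})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20221130)


@pytest.fixture
def small_vocab() -> list[str]:
    return [f"w{i}" for i in range(40)] + ["mental", "health", "care"]


def make_day(year=2021, month=3, day=5) -> dt.date:
    return dt.date(year, month, day)
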