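import numpy as np
import pytest

from turntaking import (GeneratorConfig, Turn, WordToken, default_scheme,
                        generate_corpus)


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_corpus():
    """A 6-conversation synthetic corpus shared across fast tests."""
    return generate_corpus(GeneratorConfig(n_conversations=6, seed=42))


def make_token(speaker="A", start=0.0, end=100.0, orth="word", conv="c0",
               **kw):
    return WordToken(conversation_id=conv, speaker_id=speaker, orth=orth,
                     start_ms=start, end_ms=end, **kw)


def make_turn(speaker, spans, acts=None, conv="c0", laughter=None, sex=None,
              orths=None, pos=None):
    """Turn from (start, end) spans with optional per-token fields."""
    toks = []
    for i, (s, e) in enumerate(spans):
        toks.append(WordToken(
            conversation_id=conv, speaker_id=speaker,
            orth=(orths[i] if orths else f"w{i}"),
            start_ms=s, end_ms=e,
            pos=(pos[min(i, len(pos) - 1)] if pos else None),
            dialog_act=(acts[min(i, len(acts) - 1)] if acts else None),
            laughter=bool(laughter[min(i, len(laughter) - 1)])
            if laughter else False))
    return Turn(toks, speaker_sex=sex)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
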