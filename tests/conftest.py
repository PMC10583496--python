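import numpy as np
import pytest

from speechlex import LexiconResources, Token, Transcript


@pytest.fixture
def tiny_lexicons() -> LexiconResources:
    return LexiconResources(
        fillers=frozenset({"um", "uh", "hmm"}),
        empty_words=frozenset({"thing", "stuff", "place"}),
        stop_words=frozenset({"the", "a", "an", "is", "on", "and"}),
        frequency_per_million={
            "the": 100.0, "cat": 10.0, "sat": 5.0, "on": 50.0, "mat": 2.0,
            "a": 80.0, "um": 20.0, "is": 60.0, "and": 70.0,
        },
        oov_frequency=1.0,
    )


def make_transcript(
    text: str,
    task: str = "PDT1",
    duration: float = 10.0,
    pid: str = "P1",
    gold_tags=None,
) -> Transcript:
    """Build a transcript from dialect-marked text (trailing '-' = partial,
    leading '&' = nonword)."""
    tokens = []
    for raw in text.split():
        if raw.startswith("&"):
            tokens.append(Token(raw[1:], "nonword"))
        elif raw.endswith("-"):
            tokens.append(Token(raw[:-1], "partial_word"))
        else:
            tokens.append(Token(raw, "word"))
    return Transcript(pid, task, tuple(tokens), duration,
                      gold_tags=tuple(gold_tags) if gold_tags else None)


def random_tagged_transcript(rng: np.random.Generator, n_tokens: int = 60):
    """A random transcript with gold tags, for oracle-equivalence checks."""
    vocab = [f"w{i}" for i in range(25)] + ["um", "uh", "the", "a", "an",
                                            "thing", "stuff", "cat", "sat", "on"]
    tags = ["NN", "NNS", "VB", "VBD", "VBG", "DT", "PDT", "WDT", "PRP",
            "PRP$", "WP", "WP$", "JJ", "RB", "IN", "CC", "UH"]
    tokens, gold = [], []
    for _ in range(n_tokens):
        u = rng.random()
        word = vocab[rng.integers(len(vocab))]
        if u < 0.05:
            tokens.append(Token(word, "partial_word"))
        elif u < 0.08:
            tokens.append(Token(word, "nonword"))
        else:
            tokens.append(Token(word, "word"))
            gold.append(tags[rng.integers(len(tags))])
    if not gold:  # guarantee at least one word token
        tokens.append(Token("cat", "word"))
        gold.append("NN")
    duration = float(rng.uniform(5, 120))
    return Transcript("R1", "ET1", tuple(tokens), duration, gold_tags=tuple(gold))
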