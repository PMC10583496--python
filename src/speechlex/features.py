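"""The 16 lexical-semantic features computed from one transcript.

Word counting conventions, applied uniformly:

* N — the lexical word count — covers tokens of kind ``word`` only.  Fillers
  are spoken words and count toward N; partial words and nonwords do not.
* Speech rate alone counts *every* token (words, nonwords, partial words),
  divided by the elapsed duration in seconds.
* The nine category features (fillers, empty words, articles, pronouns,
  nouns, verbs, determiners, content words) are proportions of N scaled per
  100 words.

Part-of-speech tagging is an injected dependency: any callable mapping a
word list to an equal-length list of Penn Treebank tags satisfies the
contract.  Transcripts carrying gold tags (e.g. from the synthetic
generator) use those; otherwise :func:`default_tagger`, a small rule-based
Penn tagger, is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

from .corpus import FEATURE_NAMES, Transcript
from .errors import PreconditionError, ValidationError
from .lexicons import LexiconResources

Tagger = Callable[[Sequence[str]], Sequence[str]]

#: Penn tags counted per category.
PRONOUN_TAGS = frozenset({"PRP", "PRP$", "WP", "WP$"})
DETERMINER_TAGS = frozenset({"DT", "PDT", "WDT"})

#: Per-100-words scale for the proportion features; a config constant so the
#: raw-proportion rendering is one edit away.
PROPORTION_SCALE = 100.0

BRUNET_EXPONENT = 0.165


@dataclass(frozen=True)
class LexicalProfile:
    """Token/type counts of a transcript's lexical words.

    N = word tokens, V = distinct types, V1 = hapax legomena (types that
    occur exactly once).
    """

    N: int
    V: int
    V1: int

    def __post_init__(self) -> None:
        if not (1 <= self.V <= self.N and 0 <= self.V1 <= self.V):
            raise ValidationError(
                f"inconsistent profile N={self.N}, V={self.V}, V1={self.V1}"
            )


@dataclass(frozen=True)
class FeatureVector:
    word_count: float
    fillers: float
    empty_words: float
    definite_articles: float
    indefinite_articles: float
    pronouns: float
    nouns: float
    verbs: float
    determiners: float
    content_words: float
    frequency: float
    type_token_ratio: float
    honore: float
    brunet: float
    speech_rate: float
    filler_rate: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def lexical_profile(transcript: Transcript) -> LexicalProfile:
    """Count word tokens (N), types (V) and hapaxes (V1)."""
    words = transcript.word_tokens
    if not words:
        raise PreconditionError(
            f"empty transcript {transcript.participant_id}_{transcript.task_id}: "
            "no word tokens"
        )
    counts: dict[str, int] = {}
    for tok in words:
        counts[tok.surface] = counts.get(tok.surface, 0) + 1
    return LexicalProfile(
        N=len(words),
        V=len(counts),
        V1=sum(1 for c in counts.values() if c == 1),
    )


def pos_tags(transcript: Transcript, tagger: Tagger | None = None) -> tuple[str, ...]:
    """Penn tags for the word tokens: gold tags if present, else the tagger."""
    words = [t.surface for t in transcript.word_tokens]
    if transcript.gold_tags is not None:
        return transcript.gold_tags
    tagger = tagger if tagger is not None else default_tagger
    tags = tuple(tagger(words))
    if len(tags) != len(words):
        raise ValidationError(
            f"tagger returned {len(tags)} tags for {len(words)} tokens"
        )
    return tags


def proportion_features(
    transcript: Transcript,
    lexicons: LexiconResources,
    tags: Sequence[str],
) -> dict[str, float]:
    """The nine category features, each 100 x (category count / N).

    Categories: filler and empty words by lexicon membership; definite
    article = *the*; indefinite = *a*/*an*; pronouns = PRP, PRP$, WP, WP$;
    nouns = NN*; verbs = VB*; determiners = DT, PDT, WDT; content words =
    words not in the stop-word list.
    """
    words = transcript.word_tokens
    n = len(words)
    if len(tags) != n:
        raise ValidationError(f"need {n} tags, got {len(tags)}")
    counts = dict.fromkeys(
        ("fillers", "empty_words", "definite_articles", "indefinite_articles",
         "pronouns", "nouns", "verbs", "determiners", "content_words"), 0)
    for tok, tag in zip(words, tags):
        if not tag:
            raise ValidationError(f"untagged word token {tok.surface!r}")
        s = tok.surface
        if s in lexicons.fillers:
            counts["fillers"] += 1
        if s in lexicons.empty_words:
            counts["empty_words"] += 1
        if s == "the":
            counts["definite_articles"] += 1
        if s in ("a", "an"):
            counts["indefinite_articles"] += 1
        if tag in PRONOUN_TAGS:
            counts["pronouns"] += 1
        if tag.startswith("NN"):
            counts["nouns"] += 1
        if tag.startswith("VB"):
            counts["verbs"] += 1
        if tag in DETERMINER_TAGS:
            counts["determiners"] += 1
        if s not in lexicons.stop_words:
            counts["content_words"] += 1
    return {k: PROPORTION_SCALE * v / n for k, v in counts.items()}


def mean_log_frequency(transcript: Transcript, lexicons: LexiconResources) -> float:
    """Token-weighted mean of log10 per-million word frequency."""
    words = transcript.word_tokens
    if not words:
        raise PreconditionError("empty transcript")
    return sum(lexicons.log_frequency(t.surface) for t in words) / len(words)


def type_token_ratio(profile: LexicalProfile) -> float:
    """Lexical diversity: distinct types over total tokens, V/N."""
    return profile.V / profile.N


def honore_statistic(profile: LexicalProfile) -> float:
    """Honoré's lexical-richness statistic, R = 100 ln(N) / (1 - V1/V).

    Grows with the hapax proportion; undefined when every type is a hapax
    (V1 == V), in which case NaN is returned with a warning.
    """
    if profile.V1 == profile.V:
        warnings.warn(
            f"Honoré statistic undefined: all {profile.V} types are hapaxes",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.nan
    return 100.0 * math.log(profile.N) / (1.0 - profile.V1 / profile.V)


def brunet_index(profile: LexicalProfile) -> float:
    """Brunet's index, W = N^(V^-0.165); lower values = richer vocabulary."""
    return profile.N ** (profile.V ** -BRUNET_EXPONENT)


def rate_features(transcript: Transcript, lexicons: LexiconResources) -> tuple[float, float]:
    """(speech_rate, filler_rate) in tokens per second.

    Speech rate counts all tokens of every kind; filler rate counts filler
    word tokens only.  Both divide by the elapsed duration.
    """
    if not transcript.duration_seconds > 0:
        raise ValidationError("duration must be positive")
    n_all = len(transcript.tokens)
    n_fillers = sum(
        1 for t in transcript.word_tokens if t.surface in lexicons.fillers
    )
    return (
        n_all / transcript.duration_seconds,
        n_fillers / transcript.duration_seconds,
    )


def extract_features(
    transcript: Transcript,
    lexicons: LexiconResources,
    tagger: Tagger | None = None,
) -> FeatureVector:
    """Compute all 16 features for one transcript.

    Deterministic given the transcript, the lexicons and the tagger output.
    """
    profile = lexical_profile(transcript)
    tags = pos_tags(transcript, tagger)
    props = proportion_features(transcript, lexicons, tags)
    speech_rate, filler_rate = rate_features(transcript, lexicons)
    return FeatureVector(
        word_count=float(profile.N),
        frequency=mean_log_frequency(transcript, lexicons),
        type_token_ratio=type_token_ratio(profile),
        honore=honore_statistic(profile),
        brunet=brunet_index(profile),
        speech_rate=speech_rate,
        filler_rate=filler_rate,
        **props,
    )


# --- default rule-based Penn tagger -------------------------------------

_TAG_LEXICON: dict[str, str] = {}
_TAG_LEXICON.update({w: "DT" for w in (
    "the", "a", "an", "this", "that", "these", "those", "each", "every",
    "some", "any", "no", "another", "all", "both")})
_TAG_LEXICON.update({w: "PRP" for w in (
    "i", "you", "he", "she", "it", "we", "they", "me", "him", "us", "them",
    "myself", "yourself", "himself", "herself", "itself", "ourselves",
    "themselves")})
_TAG_LEXICON.update({w: "PRP$" for w in ("my", "your", "his", "her", "its", "our", "their")})
_TAG_LEXICON.update({"who": "WP", "whom": "WP", "whose": "WP$", "which": "WDT"})
_TAG_LEXICON.update({w: "VBP" for w in ("am", "are", "have", "do")})
_TAG_LEXICON.update({w: "VBZ" for w in ("is", "has", "does")})
_TAG_LEXICON.update({w: "VBD" for w in ("was", "were", "had", "did", "went", "got", "said", "saw")})
_TAG_LEXICON.update({w: "VB" for w in ("be", "go", "get", "see", "know", "think", "look", "like", "want")})
_TAG_LEXICON.update({"been": "VBN", "being": "VBG", "done": "VBN"})
_TAG_LEXICON.update({w: "MD" for w in (
    "will", "would", "can", "could", "shall", "should", "may", "might", "must")})
_TAG_LEXICON.update({w: "IN" for w in (
    "of", "in", "on", "at", "by", "for", "with", "from", "to", "into",
    "about", "over", "under", "through", "because", "as", "if", "while")})
_TAG_LEXICON.update({w: "CC" for w in ("and", "or", "but", "nor")})
_TAG_LEXICON.update({w: "UH" for w in ("um", "uh", "hmm", "er", "eh", "mm", "oh", "well", "yeah")})
_TAG_LEXICON.update({w: "RB" for w in (
    "not", "very", "really", "there", "here", "then", "now", "just", "so",
    "too", "also", "always", "never")})


def default_tagger(words: Sequence[str]) -> list[str]:
    """Small rule-based Penn Treebank tagger: closed-class lexicon plus
    suffix heuristics, noun by default.  Adequate for the synthetic corpora
    and smoke use; inject a trained tagger for real transcripts."""
    tags = []
    for w in words:
        if w in _TAG_LEXICON:
            tags.append(_TAG_LEXICON[w])
        elif w.endswith("ing") and len(w) > 4:
            tags.append("VBG")
        elif w.endswith("ed") and len(w) > 3:
            tags.append("VBD")
        elif w.endswith("ly") and len(w) > 3:
            tags.append("RB")
        elif w.endswith("s") and len(w) > 3 and not w.endswith("ss"):
            tags.append("NNS")
        else:
            tags.append("NN")
    return tags
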