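"""Synthetic cohorts with the statistical structure the analyses assume.

Two generators at different levels:

``generate_feature_matrix``
    Draws a feature matrix directly from a trait-plus-noise model.  For
    participant *i*, feature *f*, a person trait
    ``theta ~ Normal(mu_group, sqrt(rho_f))`` is shared across tasks, and
    each task observation adds ``Normal(0, sqrt(1 - rho_f))`` noise, so the
    population correlation between any two tasks is exactly ``rho_f``.
    Expository tasks receive an additive level offset to mimic the higher
    word counts of open-ended prompts.  Statistical tests built on this
    level do not depend on any NLP plumbing.

``generate_transcripts``
    Emits a full corpus of token-level transcripts.  Each participant gets
    a :class:`SpeakerProfile` (verbosity, filler propensity, vocabulary
    skew, base speech rate, empty-word propensity) drawn once from a
    group-level distribution; the profile is the person-stable signal that
    makes extracted features reliable across tasks.  Tokens come from a
    Zipf-distributed synthetic vocabulary with known part-of-speech tags,
    so extraction tests need no external tagger.

Both generators are pure functions of their spec and seed.

The default cohort emulates the study conditions the analyses target: 39
participants (10 MCI / 29 cognitively intact), 5 tasks (2 expository + 3
picture description), 16 features, within-type reliability around 0.6, and
expository word counts roughly 2.5x picture word counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import (
    EXPOSITORY_TASKS,
    FEATURE_NAMES,
    TASKS,
    CohortRecord,
    FeatureMatrix,
    Token,
    Transcript,
)
from .errors import ValidationError
from .lexicons import LexiconResources

#: Task-level word-count multipliers relative to a speaker's base verbosity;
#: expository prompts elicit roughly 2-2.5x the words of picture prompts.
DEFAULT_TASK_MULTIPLIERS: Mapping[str, float] = {
    "ET1": 2.6,
    "ET2": 2.2,
    "PDT1": 1.2,
    "PDT2": 0.97,
    "PDT3": 0.92,
}

#: The neuropsychological battery and its cognitive domains, used when the
#: generator emits T-scores.
DEFAULT_DOMAIN_MAP: Mapping[str, str] = {
    "digit_span_forward": "attention",
    "digit_span_backward": "attention",
    "trails_a": "attention",
    "trails_b": "executive",
    "frontal_assessment": "executive",
    "cowa": "language",
    "animal_naming": "language",
    "boston_naming": "language",
    "figure_copy": "visuospatial",
    "hvlt_total": "memory",
    "hvlt_delayed": "memory",
    "figure_delayed": "memory",
}

_FILLERS = ("um", "uh", "hmm", "er", "eh", "mm")
_EMPTY_WORDS = ("thing", "things", "stuff", "place", "something", "someone", "anything")
_NONWORDS = ("mhm", "hm", "ah")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Generative parameters for a feature-level cohort.

    ``rho`` is the target inter-task correlation per feature (scalar or one
    value per feature), ``group_shift`` the MCI-minus-intact mean difference
    in z units, ``expository_offset`` the additive level shift of the two
    expository tasks.
    """

    n_mci: int = 10
    n_intact: int = 29
    n_features: int = 16
    rho: float | Sequence[float] = 0.6
    group_shift: float | Sequence[float] = 0.0
    expository_offset: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mci < 2 or self.n_intact < 2:
            raise ValidationError("group sizes must be >= 2")
        rho = np.broadcast_to(np.asarray(self.rho, dtype=float), (self.n_features,))
        if np.any(rho < 0) or np.any(rho >= 1):
            raise ValidationError("rho must lie in [0, 1)")

    @property
    def feature_names(self) -> tuple[str, ...]:
        if self.n_features == len(FEATURE_NAMES):
            return FEATURE_NAMES
        return tuple(f"f{k:02d}" for k in range(self.n_features))


def generate_feature_matrix(spec: SyntheticCohortSpec) -> FeatureMatrix:
    """Sample a participants x tasks x features matrix from the trait model."""
    rng = np.random.default_rng(spec.seed)
    rho = np.broadcast_to(np.asarray(spec.rho, dtype=float), (spec.n_features,))
    shift = np.broadcast_to(np.asarray(spec.group_shift, dtype=float),
                            (spec.n_features,))
    n = spec.n_mci + spec.n_intact
    groups = ["MCI"] * spec.n_mci + ["intact"] * spec.n_intact
    pids = [f"M{i + 1:03d}" for i in range(spec.n_mci)] + [
        f"C{i + 1:03d}" for i in range(spec.n_intact)
    ]
    mu = np.where(np.array(groups)[:, None] == "MCI", shift[None, :], 0.0)
    traits = mu + rng.normal(size=(n, spec.n_features)) * np.sqrt(rho)
    noise = rng.normal(size=(n, len(TASKS), spec.n_features)) * np.sqrt(1.0 - rho)
    values = traits[:, None, :] + noise
    is_expository = np.array([t in EXPOSITORY_TASKS for t in TASKS])
    values[:, is_expository, :] += spec.expository_offset

    feats = spec.feature_names
    rows = {
        "participant_id": np.repeat(pids, len(TASKS) * spec.n_features),
        "task_id": np.tile(np.repeat(TASKS, spec.n_features), n),
        "feature_name": np.tile(feats, n * len(TASKS)),
        "value": values.ravel(),
        "group": np.repeat(groups, len(TASKS) * spec.n_features),
    }
    return FeatureMatrix(pd.DataFrame(rows))


# --- transcript-level generation ----------------------------------------


@dataclass(frozen=True)
class SpeakerProfile:
    """Person-stable speech propensities."""

    verbosity: float  # target picture-task word count
    filler_propensity: float  # per-position probability of a filler
    zipf_exponent: float  # vocabulary skew; higher = fewer rare words
    base_speech_rate: float  # words per second
    empty_word_propensity: float  # probability a noun is replaced by an empty word

    def __post_init__(self) -> None:
        if self.verbosity <= 0 or self.base_speech_rate <= 0 or self.zipf_exponent <= 0:
            raise ValidationError("verbosity, speech rate and Zipf exponent must be positive")
        for p in (self.filler_propensity, self.empty_word_propensity):
            if not 0 <= p <= 1:
                raise ValidationError("propensities must lie in [0, 1]")


@dataclass(frozen=True)
class ProfileDistribution:
    """Group-level distribution speaker profiles are drawn from.

    Positive parameters are log-normal around their mean; probabilities are
    logit-normal.  The between-person SDs are the knobs that create (or
    remove) person-stable signal: a zero SD makes that propensity identical
    for everyone, so the corresponding features carry sampling noise only.
    """

    verbosity_mean: float = 240.0
    verbosity_log_sd: float = 0.40
    filler_mean: float = 0.030
    filler_logit_sd: float = 0.80
    zipf_mean: float = 1.10
    zipf_sd: float = 0.05
    rate_mean: float = 2.30
    rate_log_sd: float = 0.15
    empty_mean: float = 0.05
    empty_logit_sd: float = 0.50

    def sample(self, rng: np.random.Generator) -> SpeakerProfile:
        def logit(p):
            return np.log(p / (1 - p))

        def expit(x):
            return 1.0 / (1.0 + np.exp(-x))

        return SpeakerProfile(
            verbosity=float(self.verbosity_mean * np.exp(rng.normal(0, self.verbosity_log_sd))),
            filler_propensity=float(expit(logit(self.filler_mean) + rng.normal(0, self.filler_logit_sd))),
            zipf_exponent=float(max(0.5, rng.normal(self.zipf_mean, self.zipf_sd))),
            base_speech_rate=float(self.rate_mean * np.exp(rng.normal(0, self.rate_log_sd))),
            empty_word_propensity=float(expit(logit(self.empty_mean) + rng.normal(0, self.empty_logit_sd))),
        )


_SYLLABLES = ("ba", "ko", "ti", "ne", "ru", "sa", "lo", "mi", "da", "pu")
_OPEN_CLASS_TAGS = ("NN", "VB", "NN", "JJ", "NN", "VBD", "NNS", "RB")

#: Closed-class head of the synthetic vocabulary: real function words with
#: fixed Penn tags, occupying the highest Zipf ranks.
_CLOSED_CLASS: tuple[tuple[str, str], ...] = (
    ("the", "DT"), ("and", "CC"), ("a", "DT"), ("to", "IN"), ("of", "IN"),
    ("it", "PRP"), ("is", "VBZ"), ("i", "PRP"), ("that", "DT"), ("in", "IN"),
    ("was", "VBD"), ("he", "PRP"), ("she", "PRP"), ("they", "PRP"),
    ("on", "IN"), ("with", "IN"), ("we", "PRP"), ("an", "DT"),
    ("his", "PRP$"), ("her", "PRP$"), ("are", "VBP"), ("this", "DT"),
    ("you", "PRP"), ("at", "IN"), ("were", "VBD"), ("their", "PRP$"),
    ("who", "WP"), ("which", "WDT"), ("all", "PDT"),
)


def build_vocabulary(size: int) -> tuple[tuple[str, str], ...]:
    """Deterministic (word, Penn tag) vocabulary of ``size`` entries:
    a closed-class head followed by noun-heavy synthetic open-class forms."""
    if size < 2:
        raise ValidationError("vocabulary needs at least 2 words")
    vocab = list(_CLOSED_CLASS[:size])
    k = 0
    while len(vocab) < size:
        digits = []
        m = k
        while True:
            digits.append(m % len(_SYLLABLES))
            m //= len(_SYLLABLES)
            if m == 0:
                break
        word = "".join(_SYLLABLES[d] for d in reversed(digits))
        tag = _OPEN_CLASS_TAGS[k % len(_OPEN_CLASS_TAGS)]
        if tag == "NNS":
            word += "s"
        elif tag == "VBD":
            word += "ed"
        elif tag == "RB":
            word += "ly"
        vocab.append((word, tag))
        k += 1
    return tuple(vocab)


def vocabulary_lexicons(
    vocab: Sequence[tuple[str, str]], zipf_exponent: float = 1.1
) -> LexiconResources:
    """Lexicon resources matched to a synthetic vocabulary.

    The frequency table converts the Zipf sampling probabilities (at the
    group-mean exponent) to a per-million scale and covers fillers and empty
    words; stop words are the closed-class head of the vocabulary.
    """
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    p = ranks**-zipf_exponent
    p /= p.sum()
    freq = {w: float(f) for (w, _), f in zip(vocab, 1e6 * p)}
    for i, w in enumerate(_FILLERS):
        freq[w] = float(1e6 * p[min(10 + i, len(p) - 1)])
    for i, w in enumerate(_EMPTY_WORDS):
        freq[w] = float(1e6 * p[min(30 + i, len(p) - 1)])
    closed = frozenset(w for w, _ in _CLOSED_CLASS)
    return LexiconResources(
        fillers=frozenset(_FILLERS),
        empty_words=frozenset(_EMPTY_WORDS),
        stop_words=closed,
        frequency_per_million=freq,
        oov_frequency=min(freq.values()),
    )


@dataclass(frozen=True)
class TranscriptCohortSpec:
    """Generative parameters for a transcript-level corpus."""

    n_mci: int = 10
    n_intact: int = 29
    profiles: Mapping[str, ProfileDistribution] = field(
        default_factory=lambda: {
            "MCI": ProfileDistribution(filler_mean=0.04, empty_mean=0.07),
            "intact": ProfileDistribution(),
        }
    )
    vocab_size: int = 800
    task_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TASK_MULTIPLIERS)
    )
    partial_word_rate: float = 0.010
    nonword_rate: float = 0.005
    with_tscores: bool = True
    seed: int = 0


def _sample_tokens(
    rng: np.random.Generator,
    profile: SpeakerProfile,
    vocab: Sequence[tuple[str, str]],
    n_words: int,
    partial_rate: float,
    nonword_rate: float,
) -> tuple[tuple[Token, ...], tuple[str, ...]]:
    ranks = np.arange(1, len(vocab) + 1, dtype=float)
    p = ranks**-profile.zipf_exponent
    p /= p.sum()
    tokens: list[Token] = []
    tags: list[str] = []
    draws = rng.choice(len(vocab), size=n_words, p=p)
    for idx in draws:
        u = rng.random()
        if u < profile.filler_propensity:
            filler = _FILLERS[rng.integers(len(_FILLERS))]
            tokens.append(Token(filler, "word"))
            tags.append("UH")
        elif u < profile.filler_propensity + nonword_rate:
            tokens.append(Token(_NONWORDS[rng.integers(len(_NONWORDS))], "nonword"))
        word, tag = vocab[idx]
        if tag.startswith("NN") and rng.random() < profile.empty_word_propensity:
            word, tag = _EMPTY_WORDS[rng.integers(len(_EMPTY_WORDS))], "NN"
        if rng.random() < partial_rate and len(word) > 2:
            tokens.append(Token(word[: max(2, len(word) // 2)], "partial_word"))
        else:
            tokens.append(Token(word, "word"))
            tags.append(tag)
    return tuple(tokens), tuple(tags)


def _sample_tscores(rng: np.random.Generator, group: str) -> dict[str, float]:
    """T-scores consistent with the same-domain MCI rule."""
    tests = list(DEFAULT_DOMAIN_MAP)
    scores = {t: float(np.round(rng.normal(52, 7), 1)) for t in tests}
    for t in tests:
        scores[t] = min(max(scores[t], 41.0), 75.0)
    if group == "MCI":
        domain = rng.choice(["memory", "executive", "language"])
        impaired = [t for t, d in DEFAULT_DOMAIN_MAP.items() if d == domain][:2]
        for t in impaired:
            scores[t] = float(np.round(rng.uniform(25, 40), 1))
    return scores


def generate_transcripts(
    spec: TranscriptCohortSpec,
) -> tuple[list[Transcript], list[CohortRecord], LexiconResources]:
    """Generate a full synthetic corpus: 5 transcripts per participant with
    gold tags, cohort records (group label and, optionally, T-scores), and
    matching lexicon resources."""
    rng = np.random.default_rng(spec.seed)
    vocab = build_vocabulary(spec.vocab_size)
    mean_zipf = float(np.mean([d.zipf_mean for d in spec.profiles.values()]))
    lexicons = vocabulary_lexicons(vocab, zipf_exponent=mean_zipf)

    transcripts: list[Transcript] = []
    records: list[CohortRecord] = []
    members = [("MCI", f"M{i + 1:03d}") for i in range(spec.n_mci)] + [
        ("intact", f"C{i + 1:03d}") for i in range(spec.n_intact)
    ]
    for group, pid in members:
        profile = spec.profiles[group].sample(rng)
        for task in TASKS:
            n_words = max(10, int(rng.poisson(
                profile.verbosity * spec.task_multipliers[task])))
            tokens, tags = _sample_tokens(
                rng, profile, vocab, n_words,
                spec.partial_word_rate, spec.nonword_rate,
            )
            duration = len(tokens) / profile.base_speech_rate * float(
                np.exp(rng.normal(0, 0.05))
            )
            transcripts.append(
                Transcript(pid, task, tokens, duration, gold_tags=tags)
            )
        records.append(
            CohortRecord(
                pid,
                group=group,
                tscores=_sample_tscores(rng, group) if spec.with_tscores else {},
                domain_map=dict(DEFAULT_DOMAIN_MAP),
            )
        )
    return transcripts, records, lexicons


def write_corpus(
    transcripts: Sequence[Transcript],
    records: Sequence[CohortRecord],
    out_dir: str | Path,
    lexicons: LexiconResources | None = None,
) -> Path:
    """Write a corpus in the layout :func:`speechlex.corpus.read_corpus`
    reads: one transcript file (and gold-tag sidecar) per participant x task,
    a metadata.tsv, and lexicon files when given.  Returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    durations: dict[str, dict[str, float]] = {}
    for tr in transcripts:
        parts = []
        for tok in tr.tokens:
            if tok.kind == "partial_word":
                parts.append(tok.surface + "-")
            elif tok.kind == "nonword":
                parts.append("&" + tok.surface)
            else:
                parts.append(tok.surface)
        (out / f"{tr.participant_id}_{tr.task_id}.txt").write_text(
            " ".join(parts) + "\n", encoding="utf-8"
        )
        if tr.gold_tags is not None:
            (out / f"{tr.participant_id}_{tr.task_id}.tags").write_text(
                " ".join(tr.gold_tags) + "\n", encoding="utf-8"
            )
        durations.setdefault(tr.participant_id, {})[tr.task_id] = tr.duration_seconds

    rows = []
    for rec in records:
        row: dict[str, object] = {"participant_id": rec.participant_id}
        if rec.group is not None:
            row["group"] = rec.group
        for task in TASKS:
            row[f"duration_{task}"] = durations.get(rec.participant_id, {}).get(task)
        for test, score in rec.tscores.items():
            row[f"tscore_{test}"] = score
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "metadata.tsv", sep="\t", index=False)

    if lexicons is not None:
        lexdir = out / "lexicons"
        lexdir.mkdir(exist_ok=True)
        for name in ("fillers", "empty_words", "stop_words"):
            (lexdir / f"{name}.txt").write_text(
                "\n".join(sorted(getattr(lexicons, name))) + "\n", encoding="utf-8"
            )
        with open(lexdir / "frequency.tsv", "w", encoding="utf-8") as fh:
            for w, f in sorted(lexicons.frequency_per_million.items()):
                fh.write(f"{w}\t{f:.17g}\n")
    return out
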