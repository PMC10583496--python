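"""Transcript corpus I/O, cohort metadata, and the long-format feature matrix.

A corpus is a directory of UTF-8 plain-text transcripts, one file per
participant x task, named ``{participant_id}_{task_id}.txt``, together with a
tab-separated metadata table holding one row per participant (per-task elapsed
durations in seconds, an optional cognitive-status group label, and optional
neuropsychological T-scores).

Transcript dialect
------------------
Transcripts are whitespace-tokenized and lowercased; sentence punctuation is
stripped.  Two inline markers encode token kind:

* a trailing ``-`` marks a partial (interrupted) word: ``cat-``
* a leading ``&`` marks a nonword vocalization: ``&mm``

Everything else is an ordinary lexical word; fillers (*um*, *uh*, ...) are
ordinary word tokens and are identified downstream by lexicon membership.
Partial words and nonwords are never counted as lexical words — they matter
only for speech rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

#: The five speech-elicitation tasks: two expository prompts (describe an
#: important person; describe a meaningful place) and three picture
#: descriptions (cookie theft; lightbulb; cat in tree).
TASKS: tuple[str, ...] = ("ET1", "ET2", "PDT1", "PDT2", "PDT3")
EXPOSITORY_TASKS: tuple[str, ...] = ("ET1", "ET2")
PICTURE_TASKS: tuple[str, ...] = ("PDT1", "PDT2", "PDT3")
TASK_TYPES: Mapping[str, tuple[str, ...]] = {
    "expository": EXPOSITORY_TASKS,
    "picture": PICTURE_TASKS,
}

#: The 16 lexical-semantic features, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "word_count",
    "fillers",
    "empty_words",
    "definite_articles",
    "indefinite_articles",
    "pronouns",
    "nouns",
    "verbs",
    "determiners",
    "content_words",
    "frequency",
    "type_token_ratio",
    "honore",
    "brunet",
    "speech_rate",
    "filler_rate",
)

GROUPS: tuple[str, ...] = ("MCI", "intact")

_STRIP_PUNCT = ".,!?;:\"“”‘’«»()[]{}…"


@dataclass(frozen=True)
class Token:
    """One transcript token: a lowercased surface form plus its kind."""

    surface: str
    kind: str = "word"  # word | partial_word | nonword

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValidationError("token surface must be non-empty")
        if self.kind not in ("word", "partial_word", "nonword"):
            raise ValidationError(f"unknown token kind {self.kind!r}")


@dataclass(frozen=True)
class Transcript:
    """A single participant x task token sequence with elapsed duration.

    ``gold_tags``, when present, is a tuple of Penn Treebank tags aligned to
    the *word-kind* tokens in order (partial words and nonwords are untagged).
    """

    participant_id: str
    task_id: str
    tokens: tuple[Token, ...]
    duration_seconds: float
    gold_tags: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.task_id not in TASKS:
            raise ValidationError(
                f"task_id must be one of {TASKS}, got {self.task_id!r}"
            )
        if not self.duration_seconds > 0:
            raise ValidationError("duration_seconds must be positive")
        if self.gold_tags is not None and len(self.gold_tags) != len(self.word_tokens):
            raise ValidationError(
                f"{self.participant_id}_{self.task_id}: gold tags cover "
                f"{len(self.gold_tags)} tokens but transcript has "
                f"{len(self.word_tokens)} word tokens"
            )

    @property
    def word_tokens(self) -> tuple[Token, ...]:
        """Tokens of kind ``word`` (the lexical words, fillers included)."""
        return tuple(t for t in self.tokens if t.kind == "word")


@dataclass
class CohortRecord:
    """Per-participant metadata: group label and/or neuropsychological T-scores.

    T-scores are on the normative scale (population mean 50, SD 10).
    ``domain_map`` sends each test name to its cognitive domain (memory,
    language, attention, ...), as required by the same-domain MCI rule.
    """

    participant_id: str
    group: str | None = None
    tscores: dict[str, float] = field(default_factory=dict)
    domain_map: dict[str, str] = field(default_factory=dict)


def classify_cognitive_status(
    record: CohortRecord,
    threshold_t: float = 40.0,
    min_tests: int = 2,
    require_same_domain: bool = True,
) -> str:
    """Classify a participant as ``"MCI"`` or ``"intact"`` from T-scores.

    A participant meets criteria for mild cognitive impairment when at least
    ``min_tests`` tests score at or below ``threshold_t`` (T <= 40 is one
    standard deviation below the normative mean; the boundary is inclusive).
    With ``require_same_domain`` (the default) the low scores must fall within
    a single cognitive domain; with it off, any ``min_tests`` low scores
    across the battery suffice.
    """
    if not record.tscores:
        raise ValidationError(f"{record.participant_id}: no T-scores to classify")
    low = [name for name, t in record.tscores.items() if t <= threshold_t]
    if not require_same_domain:
        return "MCI" if len(low) >= min_tests else "intact"
    counts: dict[str, int] = {}
    for name in low:
        if name not in record.domain_map:
            raise ValidationError(
                f"test {name!r} missing from domain map for "
                f"{record.participant_id}"
            )
        domain = record.domain_map[name]
        counts[domain] = counts.get(domain, 0) + 1
    return "MCI" if counts and max(counts.values()) >= min_tests else "intact"


def parse_transcript_text(text: str, source: str = "<string>") -> tuple[Token, ...]:
    """Tokenize raw transcript text according to the dialect above.

    Raises :class:`ValidationError` naming the source and line for a marker
    with no word attached (a bare ``-`` or ``&``).
    """
    tokens: list[Token] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        for raw in line.split():
            tok = raw.lower().strip(_STRIP_PUNCT)
            if not tok:
                continue
            kind = "word"
            if tok.startswith("&"):
                kind = "nonword"
                tok = tok[1:]
            elif tok.endswith("-"):
                kind = "partial_word"
                tok = tok[:-1]
            tok = tok.strip(_STRIP_PUNCT)
            if not tok:
                raise ValidationError(
                    f"{source}:{lineno}: malformed dialect marker {raw!r}"
                )
            tokens.append(Token(tok, kind))
    return tuple(tokens)


def _read_gold_tags(path: Path) -> tuple[str, ...]:
    return tuple(path.read_text(encoding="utf-8").split())


def read_corpus(
    transcript_dir: str | Path,
    metadata: str | Path,
    domain_map: Mapping[str, str] | None = None,
) -> tuple[list[Transcript], list[CohortRecord]]:
    """Read a transcript corpus and its metadata table.

    Participants missing any of the 5 transcripts or durations are excluded
    with a logged warning (complete-case rule).  A ``{pid}_{task}.tags``
    sidecar, when present, supplies gold Penn Treebank tags for the word
    tokens of that transcript.

    Returns ``(transcripts, records)`` where every admitted participant
    contributes exactly 5 transcripts.
    """
    transcript_dir = Path(transcript_dir)
    meta = pd.read_csv(metadata, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in meta.columns:
        raise ValidationError(f"{metadata}: missing participant_id column")

    tscore_cols = [c for c in meta.columns if c.startswith("tscore_")]
    transcripts: list[Transcript] = []
    records: list[CohortRecord] = []
    for _, row in meta.iterrows():
        pid = row["participant_id"]
        batch: list[Transcript] = []
        complete = True
        for task in TASKS:
            path = transcript_dir / f"{pid}_{task}.txt"
            dur_col = f"duration_{task}"
            if not path.exists():
                logger.warning("excluding %s: missing transcript %s", pid, path.name)
                complete = False
                break
            if dur_col not in meta.columns or pd.isna(row[dur_col]):
                logger.warning("excluding %s: missing %s", pid, dur_col)
                complete = False
                break
            tokens = parse_transcript_text(
                path.read_text(encoding="utf-8"), source=str(path)
            )
            tags_path = transcript_dir / f"{pid}_{task}.tags"
            gold = _read_gold_tags(tags_path) if tags_path.exists() else None
            batch.append(
                Transcript(pid, task, tokens, float(row[dur_col]), gold_tags=gold)
            )
        if not complete:
            continue
        transcripts.extend(batch)
        tscores = {
            c[len("tscore_"):]: float(row[c])
            for c in tscore_cols
            if not pd.isna(row[c])
        }
        group = row["group"] if "group" in meta.columns and not pd.isna(row.get("group")) else None
        record = CohortRecord(
            pid,
            group=group,
            tscores=tscores,
            domain_map=dict(domain_map) if domain_map else {},
        )
        if record.group is None and tscores:
            record.group = classify_cognitive_status(record)
        records.append(record)
    return transcripts, records


class FeatureMatrix:
    """Participants x tasks x features, held as a long-format table.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``participant_id, task_id, feature_name, value, group``.  Validation
    enforces the complete-case invariant: every (participant, task) cell
    carries exactly the same feature set.
    """

    COLUMNS = ("participant_id", "task_id", "feature_name", "value", "group")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValidationError(f"feature matrix missing columns {sorted(missing)}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        bad_tasks = set(df["task_id"]) - set(TASKS)
        if bad_tasks:
            raise ValidationError(f"unknown task ids {sorted(bad_tasks)}")
        features = tuple(pd.unique(df["feature_name"]))
        cell_counts = df.groupby(["participant_id", "task_id"], sort=False)[
            "feature_name"
        ].nunique()
        if len(df) and not (cell_counts == len(features)).all():
            raise ValidationError("incomplete cells: some participant x task "
                                  "pairs are missing features")
        self._df = df.reset_index(drop=True)
        self._features = features

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self._features

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(pd.unique(self._df["participant_id"]))

    def group_of(self) -> pd.Series:
        """participant_id -> group label."""
        return self._df.drop_duplicates("participant_id").set_index(
            "participant_id"
        )["group"]

    def participants_in(self, group: str) -> tuple[str, ...]:
        """Participant ids in ``group``; ``"full"`` means everyone."""
        if group == "full":
            return self.participants
        g = self.group_of()
        return tuple(p for p in self.participants if g[p] == group)

    def to_array(
        self,
        tasks: Sequence[str] = TASKS,
        group: str = "full",
        features: Sequence[str] | None = None,
    ):
        """Dense values array of shape (participants, tasks, features).

        Returns ``(array, participant_ids)``; ordering follows first
        appearance in the table.
        """
        import numpy as np

        features = tuple(features) if features is not None else self._features
        pids = self.participants_in(group)
        wide = self._df.pivot_table(
            index="participant_id",
            columns=["task_id", "feature_name"],
            values="value",
            sort=False,
        )
        arr = np.empty((len(pids), len(tasks), len(features)))
        for j, task in enumerate(tasks):
            for k, feat in enumerate(features):
                arr[:, j, k] = wide.loc[list(pids), (task, feat)].to_numpy()
        return arr, pids

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        a = self._df.sort_values(["participant_id", "task_id", "feature_name"]).reset_index(drop=True)
        b = other._df.sort_values(["participant_id", "task_id", "feature_name"]).reset_index(drop=True)
        return a.equals(b)

    def __len__(self) -> int:
        return len(self._df)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix as comma-separated long format, full precision."""
    matrix.df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_feature_matrix(
    path: str | Path, allowed_features: Iterable[str] = FEATURE_NAMES
) -> FeatureMatrix:
    """Read a long-format feature matrix, rejecting unknown feature names."""
    df = pd.read_csv(path, dtype={"participant_id": str},
                     float_precision="round_trip")
    allowed = set(allowed_features)
    unknown = set(df["feature_name"].unique() if len(df) else ()) - allowed
    if unknown:
        raise ValidationError(f"unknown feature names {sorted(unknown)}")
    return FeatureMatrix(df)
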