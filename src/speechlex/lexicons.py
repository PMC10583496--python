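"""Lexicon resources: filler / empty-word / stop-word lists and a
word -> frequency-per-million table.

Defaults bundled under ``speechlex/data`` are documented supersets of the
usual examples (fillers *um, uh, hmm*; empty words *thing, place, stuff*);
the bundled frequency table is a small synthetic fixture on a Zipf-like
scale, meant to be replaced by a real per-million table (SUBTLEX-style)
for real corpora.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ValidationError


@dataclass
class LexiconResources:
    """Word lists plus a per-million frequency table.

    ``oov_frequency`` is the per-million floor assigned to words absent from
    the table; it defaults to the table's minimum observed frequency.
    """

    fillers: frozenset[str]
    empty_words: frozenset[str]
    stop_words: frozenset[str]
    frequency_per_million: dict[str, float] = field(default_factory=dict)
    oov_frequency: float | None = None

    def __post_init__(self) -> None:
        for name in ("fillers", "empty_words", "stop_words"):
            words = getattr(self, name)
            if any(w != w.lower() for w in words):
                raise ValidationError(f"{name} must be lowercased")
        if any(f <= 0 for f in self.frequency_per_million.values()):
            raise ValidationError("frequencies must be positive")
        if self.frequency_per_million and self.oov_frequency is None:
            self.oov_frequency = min(self.frequency_per_million.values())
        if (
            self.oov_frequency is not None
            and self.frequency_per_million
            and self.oov_frequency > min(self.frequency_per_million.values())
        ):
            raise ValidationError(
                "oov_frequency must not exceed the minimum observed frequency"
            )

    def log_frequency(self, word: str) -> float:
        """log10 per-million frequency of ``word``, with the OOV floor."""
        if self.oov_frequency is None:
            raise ValidationError("no frequency table loaded")
        return math.log10(self.frequency_per_million.get(word, self.oov_frequency))


def read_word_list(path: str | Path) -> frozenset[str]:
    """One token per line, UTF-8; blank lines and leading/trailing space ignored."""
    words = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip()
        if w:
            words.append(w.lower())
    return frozenset(words)


def read_frequency_table(path: str | Path) -> dict[str, float]:
    """Two tab-separated columns: word, frequency per million."""
    table: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}:{lineno}: expected word<TAB>per-million")
        table[parts[0].lower()] = float(parts[1])
    return table


def load_lexicons(
    fillers: str | Path | None = None,
    empty_words: str | Path | None = None,
    stop_words: str | Path | None = None,
    frequency_table: str | Path | None = None,
    oov_frequency: float | None = None,
) -> LexiconResources:
    """Load lexicon resources, falling back to the bundled defaults."""
    data = resources.files("speechlex") / "data"

    def _path(user: str | Path | None, default: str) -> Path:
        return Path(user) if user is not None else Path(str(data / default))

    return LexiconResources(
        fillers=read_word_list(_path(fillers, "fillers.txt")),
        empty_words=read_word_list(_path(empty_words, "empty_words.txt")),
        stop_words=read_word_list(_path(stop_words, "stopwords.txt")),
        frequency_per_million=read_frequency_table(
            _path(frequency_table, "frequency_synthetic.tsv")
        ),
        oov_frequency=oov_frequency,
    )
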