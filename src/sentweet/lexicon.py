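"""Sentiment lexicon: per-lemma positivity/negativity/neutrality grades.

Each entry carries three scalar grades in [0, 1] — positivity ``s_plus``,
negativity ``s_minus``, neutrality ``s_neutral`` — normalized so that
``s_plus + s_minus + s_neutral = 1``.  Lookups for lemmas absent from the
lexicon fall back to the fully neutral triplet (0, 0, 1).
"""

from __future__ import annotations

import csv
from collections import defaultdict
from dataclasses import dataclass

from . import resources

SUM_TOLERANCE = 1e-9

#: coarse POS classes: adjective, noun, verb, adverb, other
POS_CLASSES = ("a", "n", "v", "r", "u")

NEUTRAL_TRIPLET = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class LexiconEntry:
    lemma: str
    pos_class: str
    s_plus: float
    s_minus: float
    s_neutral: float

    def __post_init__(self) -> None:
        total = self.s_plus + self.s_minus + self.s_neutral
        if abs(total - 1.0) > SUM_TOLERANCE:
            raise ValueError(
                f"lexicon entry {self.lemma!r}: grades sum to {total!r}, must be 1"
            )
        if min(self.s_plus, self.s_minus, self.s_neutral) < 0:
            raise ValueError(f"lexicon entry {self.lemma!r}: negative grade")

    @property
    def triplet(self) -> tuple[float, float, float]:
        return (self.s_plus, self.s_minus, self.s_neutral)


class Lexicon:
    """Validated collection of :class:`LexiconEntry`, keyed by (lemma, pos_class).

    A lookup first tries the exact (lemma, pos_class) key, then any entry for
    the lemma, then the neutral fallback (0, 0, 1).
    """

    def __init__(self, entries: list[LexiconEntry]):
        self._by_key: dict[tuple[str, str], LexiconEntry] = {}
        self._by_lemma: dict[str, LexiconEntry] = {}
        for e in entries:
            self._by_key[(e.lemma, e.pos_class)] = e
            self._by_lemma.setdefault(e.lemma, e)

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def lookup(self, lemma: str, pos_class: str | None = None) -> tuple[float, float, float]:
        if pos_class is not None:
            entry = self._by_key.get((lemma, pos_class))
            if entry is not None:
                return entry.triplet
        entry = self._by_lemma.get(lemma)
        return entry.triplet if entry is not None else NEUTRAL_TRIPLET

    @classmethod
    def from_tsv(cls, path) -> "Lexicon":
        """Read a TSV lexicon (lemma, pos_class, s_plus, s_minus, s_neutral).

        Malformed rows — wrong field count, grades outside [0, 1], or a triplet
        whose sum deviates from 1 beyond tolerance — are rejected at load time.
        """
        entries = []
        with open(path, encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
                lemma, pos_class, *grades = row
                try:
                    s_plus, s_minus, s_neutral = (float(g) for g in grades)
                except ValueError as err:
                    raise ValueError(f"{path}:{lineno}: non-numeric grade") from err
                entries.append(LexiconEntry(lemma, pos_class, s_plus, s_minus, s_neutral))
        return cls(entries)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for entry in self._by_key.values():
                writer.writerow(
                    [entry.lemma, entry.pos_class, entry.s_plus, entry.s_minus, entry.s_neutral]
                )

    @classmethod
    def bundled(cls) -> "Lexicon":
        return cls.from_tsv(resources.resource_path("lexicon.tsv"))


def lexicon_lookup(
    lemma: str, pos_class: str | None, lexicon: Lexicon
) -> tuple[float, float, float]:
    """Functional wrapper around :meth:`Lexicon.lookup`."""
    return lexicon.lookup(lemma, pos_class)


_PENN_TO_COARSE = {"J": "a", "N": "n", "V": "v", "R": "r"}


def coarse_pos(penn_tag: str) -> str:
    """Collapse a Penn Treebank tag to the lexicon's coarse POS class."""
    return _PENN_TO_COARSE.get(penn_tag[:1], "u")


def from_sentiwordnet(path) -> Lexicon:
    """Adapter for the SentiWordNet 3.0 file format.

    Rows are ``POS  ID  PosScore  NegScore  SynsetTerms  Gloss`` with ``#``
    comments; a term may appear in several synsets with sense ranks attached
    as ``term#rank``.  Scores are aggregated per (term, POS) by a mean
    weighted by reciprocal sense rank, and neutrality is 1 − pos − neg.
    """
    sums: dict[tuple[str, str], list[float]] = defaultdict(lambda: [0.0, 0.0, 0.0])
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                continue
            pos, _, pos_score, neg_score, terms = fields[:5]
            try:
                p, m = float(pos_score), float(neg_score)
            except ValueError:
                continue
            for term in terms.split():
                name, _, rank = term.partition("#")
                try:
                    weight = 1.0 / max(int(rank), 1)
                except ValueError:
                    weight = 1.0
                acc = sums[(name.lower(), pos)]
                acc[0] += weight * p
                acc[1] += weight * m
                acc[2] += weight
        entries = []
        for (lemma, pos), (wp, wm, wt) in sums.items():
            p, m = wp / wt, wm / wt
            entries.append(LexiconEntry(lemma, pos, p, m, max(1.0 - p - m, 0.0)))
    return Lexicon(entries)


__all__ = [
    "LexiconEntry",
    "Lexicon",
    "lexicon_lookup",
    "coarse_pos",
    "from_sentiwordnet",
    "NEUTRAL_TRIPLET",
    "SUM_TOLERANCE",
]
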