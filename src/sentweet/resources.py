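"""Loaders for the versioned fixture resources bundled with the package.

Every resource is a small plain-text file (TSV or one item per line) shipped
under ``sentweet/resources``; identical inputs therefore yield byte-identical
pipeline output across machines.  All loaders are cached — the files are
read once per process.
"""

from __future__ import annotations

import functools
from importlib import resources as _ir


def _read_text(name: str) -> str:
    return _ir.files("sentweet").joinpath("resources", name).read_text(encoding="utf-8")


def resource_path(name: str):
    """Filesystem path of a bundled resource (resources are plain files)."""
    return _ir.files("sentweet").joinpath("resources", name)


@functools.lru_cache(maxsize=None)
def stopwords() -> frozenset[str]:
    return frozenset(w for w in _read_text("stopwords.txt").split() if w)


@functools.lru_cache(maxsize=None)
def emoticon_table() -> dict[str, str]:
    """Emoticon surface -> category token (``<smile>`` for every bundled row)."""
    table = {}
    for line in _read_text("emoticons.tsv").splitlines():
        if line.strip():
            pattern, token = line.split("\t")
            table[pattern] = token
    return table


@functools.lru_cache(maxsize=None)
def word_frequencies() -> dict[str, float]:
    """Unigram relative frequencies for hashtag segmentation and elongation."""
    counts: dict[str, float] = {}
    for line in _read_text("wordfreq.tsv").splitlines():
        if line.strip():
            word, count = line.split("\t")
            counts[word] = float(count)
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()}


@functools.lru_cache(maxsize=None)
def gazetteer() -> dict[str, str]:
    entries = {}
    for line in _read_text("gazetteer.tsv").splitlines():
        if line.strip():
            surface, cls = line.split("\t")
            entries[surface] = cls
    return entries


@functools.lru_cache(maxsize=None)
def negation_cues() -> frozenset[str]:
    return frozenset(w for w in _read_text("negation_cues.txt").split() if w)


@functools.lru_cache(maxsize=None)
def clause_boundaries() -> frozenset[str]:
    return frozenset(
        w.strip() for w in _read_text("clause_boundaries.txt").splitlines() if w.strip()
    )


@functools.lru_cache(maxsize=None)
def pos_lexicon() -> dict[str, tuple[str, ...]]:
    """Word -> candidate Penn Treebank tags, most likely first."""
    lex = {}
    for line in _read_text("pos_lexicon.tsv").splitlines():
        if line.strip():
            word, tags = line.split("\t")
            lex[word] = tuple(tags.split("|"))
    return lex


@functools.lru_cache(maxsize=None)
def irregular_verbs() -> dict[str, str]:
    table = {}
    for line in _read_text("irregular_verbs.tsv").splitlines():
        if line.strip():
            form, base = line.split("\t")
            table[form] = base
    return table
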