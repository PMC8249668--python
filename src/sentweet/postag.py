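"""Rule-and-lexicon Penn Treebank POS tagging and POS-conditioned lemmatization.

A compact deterministic tagger over the 36 Penn Treebank tags: closed-class
words and frequent ambiguous words come from a bundled tag lexicon; everything
else is resolved by suffix and context rules.  Tagging runs on the surface
forms (capitalization is informative), and the lemma is derived afterwards,
conditioned on the chosen tag — so "saw" lemmatizes to "see" as a past-tense
verb but stays "saw" as a noun, and "builds"/"built"/"building" all reduce to
"build" in verb contexts.
"""

from __future__ import annotations

import re

from . import resources
from .types import SPECIAL_POS

#: The 36 Penn Treebank part-of-speech tags (word-level tagset).
PENN_TAGS = (
    "CC", "CD", "DT", "EX", "FW", "IN", "JJ", "JJR", "JJS", "LS", "MD",
    "NN", "NNP", "NNPS", "NNS", "PDT", "POS", "PRP", "PRP$", "RB", "RBR",
    "RBS", "RP", "SYM", "TO", "UH", "VB", "VBD", "VBG", "VBN", "VBP",
    "VBZ", "WDT", "WP", "WP$", "WRB",
)

_SPECIAL_RE = re.compile(r"^<[a-z3/]+>$")
_NUMBER_RE = re.compile(r"^\d+([.,:/]\d+)*(st|nd|rd|th|s|am|pm|k|m)?$", re.IGNORECASE)

# tags after which an ambiguous word is read as a verb / as a noun
_VERBISH_LEFT = {"PRP", "NNP", "NNPS", "WP", "RB", "MD", "TO"}
_NOUNISH_LEFT = {"DT", "JJ", "JJR", "JJS", "PRP$", "CD", "PDT", "POS"}


def is_special_token(word: str) -> bool:
    return bool(_SPECIAL_RE.match(word))


def _suffix_tag(word: str, prev_tag: str | None) -> str:
    lower = word.lower()
    if prev_tag in ("MD", "TO"):
        return "VB"
    if lower.endswith("ing") and len(lower) > 4:
        return "VBG"
    if lower.endswith("ed") and len(lower) > 3:
        return "VBN" if prev_tag in ("VBZ", "VBP", "VBD") else "VBD"
    if lower.endswith("ly") and len(lower) > 3:
        return "RB"
    if lower.endswith(("ous", "ful", "ive", "able", "ible", "al", "ic", "less")):
        return "JJ"
    if lower.endswith(("ness", "ment", "tion", "sion", "ship", "ity")):
        return "NN"
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")) and len(lower) > 3:
        # could be plural noun or 3rd-person verb; left context decides
        if prev_tag in _VERBISH_LEFT and prev_tag != "MD":
            return "VBZ"
        return "NNS"
    return "NN"


def _disambiguate(candidates: tuple[str, ...], prev_tag: str | None) -> str:
    if len(candidates) == 1:
        return candidates[0]
    verbish = [t for t in candidates if t.startswith("V")]
    nounish = [t for t in candidates if t.startswith("N")]
    if prev_tag in _VERBISH_LEFT and verbish:
        return verbish[0]
    if prev_tag in _NOUNISH_LEFT and nounish:
        return nounish[0]
    if prev_tag in ("MD", "TO"):
        vb = [t for t in candidates if t == "VB"]
        if vb:
            return vb[0]
    return candidates[0]


def pos_tag(words: list[str]) -> list[str]:
    """Tag a tokenized sentence; special ``<...>`` tokens get the marker tag."""
    lexicon = resources.pos_lexicon()
    tags: list[str] = []
    prev_tag: str | None = None
    for i, word in enumerate(words):
        if is_special_token(word):
            tags.append(SPECIAL_POS)
            # specials are transparent to context rules
            continue
        lower = word.lower()
        if _NUMBER_RE.match(word):
            tag = "CD"
        elif lower in lexicon:
            tag = _disambiguate(lexicon[lower], prev_tag)
        elif i > 0 and word[:1].isupper() and word[1:].islower():
            tag = "NNP"
        elif word.isupper() and len(word) > 1:
            tag = "NNP"
        else:
            tag = _suffix_tag(word, prev_tag)
        tags.append(tag)
        prev_tag = tag
    return tags


_DOUBLED = re.compile(r"(.)\1$")
_VOWELS = set("aeiou")


def _strip_verb_suffix(lower: str) -> str:
    irregular = resources.irregular_verbs()
    if lower in irregular:
        return irregular[lower]
    freq = resources.word_frequencies()
    for suffix in ("ing", "ed", "es", "s"):
        if lower.endswith(suffix) and len(lower) - len(suffix) >= 2:
            stem = lower[: -len(suffix)]
            if suffix in ("ing", "ed", "es") and stem + "e" in freq:  # making -> make
                return stem + "e"
            if suffix in ("ing", "ed") and _DOUBLED.search(stem) and stem[:-1] in freq:
                return stem[:-1]  # hitting -> hit
            if stem in freq:
                return stem
            # unknown stem: leave the surface form intact rather than guess
            return lower
    return lower


def _strip_noun_suffix(lower: str) -> str:
    freq = resources.word_frequencies()
    if lower.endswith("ies") and len(lower) > 4:
        return lower[:-3] + "y"
    if lower.endswith("es") and len(lower) > 3:
        stem = lower[:-2]
        if lower.endswith(("ches", "shes", "xes", "sses", "zes")):
            return stem
        if stem + "e" in freq:
            return stem + "e"
        if lower[:-1] in freq:
            return lower[:-1]
        return lower
    if lower.endswith("s") and not lower.endswith(("ss", "us", "is")) and len(lower) > 3:
        return lower[:-1]
    return lower


def lemmatize(word: str, tag: str) -> str:
    """Lowercase lemma of ``word`` given its Penn Treebank tag."""
    if tag == SPECIAL_POS:
        return word
    lower = word.lower()
    if tag.startswith("V"):
        return _strip_verb_suffix(lower)
    if tag in ("NNS", "NNPS"):
        return _strip_noun_suffix(lower)
    if tag in ("JJR", "RBR") and lower.endswith("er") and len(lower) > 4:
        stem = lower[:-2]
        freq = resources.word_frequencies()
        return stem + "e" if stem + "e" in freq else (stem if stem in freq else lower)
    if tag in ("JJS", "RBS") and lower.endswith("est") and len(lower) > 5:
        stem = lower[:-3]
        freq = resources.word_frequencies()
        return stem + "e" if stem + "e" in freq else (stem if stem in freq else lower)
    return lower
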