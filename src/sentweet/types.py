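"""Core domain containers shared across the pipeline.

The unit of analysis is a single tweet: a short (<= 280 character) informal
message carrying an optional gold sentiment label.  Sentiment is a stance
toward the health risk discussed in the text, not toward the event itself:
``positive`` marks recognition of the risk, ``negative`` marks disregard or
lack of concern, ``neutral`` marks no stance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

LABELS = ("positive", "negative", "neutral")
"""Global class order used everywhere votes or probabilities are indexed."""

#: Marker POS assigned to special tokens (<user>, <url>, <hashtag>, <smile>,
#: and the seven entity masks); they carry no Penn Treebank tag.
SPECIAL_POS = "SPECIAL"

ENTITY_TAGS = (
    "<person>",
    "<location>",
    "<organization>",
    "<money>",
    "<percent>",
    "<date>",
    "<time>",
)

ENTITY_CLASSES = ("person", "location", "organization", "money", "percent", "date", "time")


@dataclass(frozen=True)
class Tweet:
    id: str
    text: str
    label: str | None = None
    is_retweet: bool = False

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.text.strip():
            raise ValueError("tweet text is empty after whitespace stripping")


@dataclass(frozen=True)
class Token:
    surface: str
    lemma: str
    pos_tag: str
    entity: str = "none"
    is_special: bool = False

    def __post_init__(self) -> None:
        if self.is_special and self.entity not in ("none", *ENTITY_CLASSES):
            raise ValueError(f"bad entity class {self.entity!r}")

    def with_entity(self, entity: str, surface: str) -> "Token":
        return replace(self, entity=entity, surface=surface, lemma=surface, is_special=True)


@dataclass
class TokenSequence:
    """Normalized token stream for one tweet (cleaning + normalization output)."""

    tokens: list[Token] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def lemmas(self) -> list[str]:
        return [t.lemma for t in self.tokens]
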