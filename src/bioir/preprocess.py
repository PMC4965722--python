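"""Text normalisation pipeline: markup stripping, tokenisation, stopword
removal and Porter stemming.

Queries and documents must pass through the *same* :class:`PipelineConfig`,
otherwise query terms cannot match index terms. The default configuration —
lowercase, minimum token length 2, the bundled Glasgow IR English stop list,
Porter stemming — is what every other module assumes unless told otherwise.
"""

from __future__ import annotations

import html
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .porter import stem_word

__all__ = [
    "PipelineConfig",
    "load_stopwords",
    "default_stopwords",
    "strip_markup",
    "tokenize",
    "remove_stopwords",
    "stem",
    "preprocess",
]


def load_stopwords(path: str | Path) -> frozenset[str]:
    """Read a stopword file: one token per line, ``#`` comments ignored."""
    words: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.add(line.lower())
    return frozenset(words)


def default_stopwords() -> frozenset[str]:
    """The packaged Glasgow IR English stop list (318 words)."""
    text = resources.files("bioir").joinpath("data/stopwords.txt").read_text("utf-8")
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Normalisation settings shared by indexing, querying and expansion.

    Parameters
    ----------
    lowercase:
        Fold tokens to lowercase (required for stopword and stemmer matching).
    min_token_length:
        Tokens shorter than this are dropped; the default of 2 removes
        single letters while keeping gene symbols such as ``p53``.
    stopwords:
        Lowercased words removed after tokenisation.
    stemmer:
        ``"porter"`` for Porter suffix stripping, ``"none"`` for identity.
    """

    lowercase: bool = True
    min_token_length: int = 2
    stopwords: frozenset[str] = field(default_factory=default_stopwords)
    stemmer: str = "porter"

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")
        if self.stemmer not in ("porter", "none"):
            raise ValueError(f"unknown stemmer {self.stemmer!r}")


# Tag spans are removed greedily up to the next '>'; an unterminated '<'
# swallows the rest of the string.
_TAG_RE = re.compile(r"<[^>]*>")
_OPEN_TAG_RE = re.compile(r"<[^>]*$")
_TOKEN_SPLIT_RE = re.compile(r"[^0-9A-Za-z]+")


def strip_markup(raw_text: str) -> str:
    """Remove angle-bracket tags and decode HTML entity references.

    Inter-tag text is preserved in order; a tag never closed drops everything
    from its ``<`` to the end of the string.
    """
    text = _TAG_RE.sub("", raw_text)
    text = _OPEN_TAG_RE.sub("", text)
    return html.unescape(text)


def tokenize(text: str, config: PipelineConfig) -> list[str]:
    """Split tag-free text into raw tokens.

    Splits on every character that is not an ASCII letter or digit,
    lowercases when configured, and drops purely numeric tokens and tokens
    shorter than ``min_token_length``. Hyphenated forms are therefore split:
    ``NF-kappaB`` becomes ``nf``, ``kappab``.
    """
    tokens = []
    for tok in _TOKEN_SPLIT_RE.split(text):
        if not tok:
            continue
        if config.lowercase:
            tok = tok.lower()
        if len(tok) < config.min_token_length or tok.isdigit():
            continue
        tokens.append(tok)
    return tokens


def remove_stopwords(terms: list[str], config: PipelineConfig) -> list[str]:
    """Order-preserving removal of configured stopwords."""
    return [t for t in terms if t not in config.stopwords]


def stem(terms: list[str], config: PipelineConfig) -> list[str]:
    """Apply the configured stemmer to each term, preserving order."""
    if config.stemmer == "none":
        return list(terms)
    return [stem_word(t) for t in terms]


def preprocess(raw_text: str, config: PipelineConfig | None = None) -> list[str]:
    """Full pipeline: strip markup, tokenise, drop stopwords, stem."""
    if config is None:
        config = PipelineConfig()
    return stem(remove_stopwords(tokenize(strip_markup(raw_text), config), config), config)
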