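"""Text cleaning, tokenization and token filtering.

Raw PubMed title/abstract text is reduced to lowercase bags of words before
vectorization: markup and non-alphanumeric characters are removed, whitespace
is collapsed, and tokens that are PubMed stop-words or shorter than a minimum
length (3 characters by default) are discarded — very short tokens inflate
the sparsity of the feature space more than they discriminate.

Hyphen/punctuation handling is parameterized by a *policy*:

``join``
    punctuation is deleted in place, concatenating its neighbours
    ("white-rot" -> "whiterot").  Used for annotation-content features.
``split``
    punctuation is replaced by a space ("white-rot" -> "white rot").
    Used for the plain bag-of-words over the whole text fields.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

JOIN = "join"
SPLIT = "split"
_POLICIES = (JOIN, SPLIT)

_MARKUP_RE = re.compile(r"<[^>]*>")
# Anything that is not an ASCII letter/digit and not whitespace: ASCII
# punctuation and all non-ASCII symbols alike.
_PUNCT_RE = re.compile(r"[^0-9A-Za-z\s]+")
_WS_RE = re.compile(r"\s+")


def clean_text(text: str, hyphen_policy: str = SPLIT) -> str:
    """Normalize raw text to a lowercase, punctuation-free string.

    Markup tags are stripped (replaced by a space so they still delimit
    words), punctuation and non-ASCII symbols are handled per the policy,
    whitespace runs collapse to single spaces, and the result is lowercased.
    Idempotent under both policies.
    """
    if hyphen_policy not in _POLICIES:
        raise ValueError(f"unknown hyphen policy {hyphen_policy!r}")
    text = _MARKUP_RE.sub(" ", text)
    text = _PUNCT_RE.sub("" if hyphen_policy == JOIN else " ", text)
    return _WS_RE.sub(" ", text).strip().lower()


def tokenize(cleaned: str) -> list[str]:
    """Whitespace-split an already-cleaned string, order preserved."""
    return cleaned.split()


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Load a stop-word list (one word per line); default: packaged PubMed list."""
    if path is None:
        text = (
            resources.files("triagesort.data")
            .joinpath("pubmed_stopwords.txt")
            .read_text(encoding="utf-8")
        )
    else:
        text = Path(path).read_text(encoding="utf-8")
    words = frozenset(w.strip().lower() for w in text.splitlines() if w.strip())
    if not words:
        raise ValueError("stop-word list is empty")
    return words


#: Packaged PubMed stop-word list, loaded once.
PUBMED_STOPWORDS: frozenset[str] = load_stopwords()


def filter_tokens(
    tokens: list[str],
    stopwords: frozenset[str] | set[str] | None = None,
    min_len: int = 3,
) -> list[str]:
    """Drop stop-words and tokens shorter than ``min_len``, keeping order."""
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    sw = PUBMED_STOPWORDS if stopwords is None else stopwords
    return [t for t in tokens if len(t) >= min_len and t not in sw]
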