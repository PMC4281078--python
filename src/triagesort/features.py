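"""Feature families, feature settings, vocabularies and count vectors.

Five feature families are extracted from an annotated abstract:

F1
    Bio-entity annotation *types* (one occurrence per annotation).
F2
    Annotated *contents* of entity spans, paired with their type
    ("ligninase|enzyme").
F3
    Bag-of-words over the contents of *sentence* spans, each token paired
    with the sentence annotation type ("substrate|substratespecificity").
    Text covered by a nested entity span stays one whole token.
F4
    Enzyme Commission numbers normalized to a digit string
    ("EC 1.14.99.-" -> "11499").
F5
    Plain bag-of-words over the entire title + abstract fields.

Four *feature settings* combine the families: #1 = F1, #2 = F1+F4, #3 = F5,
#4 = F1+F2+F3+F4.  A vocabulary is built from training documents only; token
features (the F3 token part and F5) must occur at least ``min_count`` times
in the training corpus and be at least ``min_len`` characters long.  Annotation
types, entity contents and EC numbers are exempt from the occurrence filter —
the type inventory is a fixed 22-entry schema and must stay intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp

from .corpus_io import Corpus, Document
from .preprocessing import JOIN, SPLIT, clean_text, filter_tokens, tokenize
from .schema import ENTITY_SPAN, NEGATIVE, POSITIVE, SENTENCE_SPAN

logger = logging.getLogger(__name__)

F1, F2, F3, F4, F5 = "f1", "f2", "f3", "f4", "f5"
TOKEN_KINDS = frozenset({F3, F5})  # subject to the occurrence filter


class Feature(NamedTuple):
    kind: str
    key: str


@dataclass(frozen=True)
class FeatureSetting:
    setting_id: int
    families: tuple[str, ...]


#: The four printed feature settings.
SETTINGS: dict[int, FeatureSetting] = {
    1: FeatureSetting(1, (F1,)),
    2: FeatureSetting(2, (F1, F4)),
    3: FeatureSetting(3, (F5,)),
    4: FeatureSetting(4, (F1, F2, F3, F4)),
}


def get_setting(setting: int | FeatureSetting) -> FeatureSetting:
    if isinstance(setting, FeatureSetting):
        return setting
    try:
        return SETTINGS[setting]
    except KeyError:
        raise ValueError(f"unknown feature setting {setting!r} (expected 1-4)")


# ---------------------------------------------------------------------------
# family extractors
# ---------------------------------------------------------------------------

def extract_f1(doc: Document) -> Counter:
    """One feature occurrence per annotation, keyed by its entity type."""
    return Counter(Feature(F1, a.entity_type) for a in doc.iter_annotations())


def extract_f2(doc: Document) -> Counter:
    """(content, type) features from entity-span annotations."""
    out: Counter = Counter()
    for a in doc.iter_annotations():
        if a.span_kind != ENTITY_SPAN:
            continue
        content = clean_text(a.covered_text, JOIN)
        if content:
            out[Feature(F2, f"{content}|{a.entity_type.lower()}")] += 1
    return out


def _sentence_tokens(ann) -> list[str]:
    """Tokenize a sentence span; nested entity spans stay whole tokens."""
    tokens: list[str] = []
    cursor = ann.start
    children = sorted(
        (c for c in ann.children if c.span_kind == ENTITY_SPAN),
        key=lambda c: c.start,
    )
    text = ann.covered_text

    def add_segment(lo: int, hi: int) -> None:
        seg = text[lo - ann.start : hi - ann.start]
        tokens.extend(tokenize(clean_text(seg, JOIN)))

    for child in children:
        add_segment(cursor, child.start)
        whole = clean_text(child.covered_text, JOIN)
        if whole:
            tokens.append(whole)
        cursor = child.end
    add_segment(cursor, ann.end)
    return tokens


def extract_f3(
    doc: Document,
    stopwords: frozenset[str] | None = None,
    min_len: int = 3,
) -> Counter:
    """(token, type) features from sentence-span annotation contents."""
    out: Counter = Counter()
    for ann in doc.iter_annotations():
        if ann.span_kind != SENTENCE_SPAN:
            continue
        for tok in filter_tokens(_sentence_tokens(ann), stopwords, min_len):
            out[Feature(F3, f"{tok}|{ann.entity_type.lower()}")] += 1
    return out


_NON_DIGIT_RE = re.compile(r"\D")


def normalize_ec(registry: str) -> str:
    """Normalize an EC registry string to its concatenated digits."""
    return _NON_DIGIT_RE.sub("", registry)


def extract_f4(doc: Document) -> Counter:
    """Normalized EC-number features from the registry fields."""
    out: Counter = Counter()
    for raw in doc.registry_numbers:
        digits = normalize_ec(raw)
        if not digits:
            logger.warning(
                "document %s: registry string %r has no digits; skipped",
                doc.doc_id,
                raw,
            )
            continue
        out[Feature(F4, digits)] += 1
    return out


def _field_text_with_boundaries(doc: Document, field: str) -> str:
    """Field text with a space injected at every annotation boundary.

    Annotation span boundaries are word boundaries: the annotator wraps whole
    words/sentences, and the raw records do not always keep a space between a
    span's end and the following text.
    """
    text = doc.field_text(field)
    cuts = sorted(
        {a.start for a in doc.iter_annotations(field)}
        | {a.end for a in doc.iter_annotations(field)}
        | {0, len(text)}
    )
    return " ".join(text[lo:hi] for lo, hi in zip(cuts, cuts[1:]))


def extract_f5(
    doc: Document,
    stopwords: frozenset[str] | None = None,
    min_len: int = 3,
) -> Counter:
    """Bag-of-words over the whole title + abstract, counts merged."""
    out: Counter = Counter()
    for field in ("title", "abstract"):
        cleaned = clean_text(_field_text_with_boundaries(doc, field), SPLIT)
        for tok in filter_tokens(tokenize(cleaned), stopwords, min_len):
            out[Feature(F5, tok)] += 1
    return out


def compose_features(
    doc: Document,
    setting: int | FeatureSetting,
    stopwords: frozenset[str] | None = None,
    min_len: int = 3,
) -> Counter:
    """Union (with counts) of the selected families' extractions."""
    setting = get_setting(setting)
    out: Counter = Counter()
    for fam in setting.families:
        if fam == F1:
            out += extract_f1(doc)
        elif fam == F2:
            out += extract_f2(doc)
        elif fam == F3:
            out += extract_f3(doc, stopwords, min_len)
        elif fam == F4:
            out += extract_f4(doc)
        elif fam == F5:
            out += extract_f5(doc, stopwords, min_len)
    return out


# ---------------------------------------------------------------------------
# vocabulary and vectorization
# ---------------------------------------------------------------------------

def corpus_fingerprint(corpus: Corpus) -> str:
    h = hashlib.sha256()
    for d in corpus.documents:
        h.update(d.doc_id.encode())
        h.update(b"\x00")
        h.update((d.label or "").encode())
        h.update(b"\x01")
    return h.hexdigest()[:16]


@dataclass
class Vocabulary:
    """Ordered feature set for one setting, built from training data only."""

    features: list[Feature]
    setting_id: int
    min_count: int
    min_len: int
    provenance: str = ""
    index: dict[Feature, int] = dc_field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {f: i for i, f in enumerate(self.features)}

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature: Feature) -> bool:
        return feature in self.index

    def keys(self) -> list[str]:
        return [f.key for f in self.features]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "format": "triagesort-vocabulary-v1",
                    "setting_id": self.setting_id,
                    "min_count": self.min_count,
                    "min_len": self.min_len,
                    "provenance": self.provenance,
                    "features": [[f.kind, f.key] for f in self.features],
                },
                indent=0,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            features=[Feature(k, key) for k, key in data["features"]],
            setting_id=data["setting_id"],
            min_count=data["min_count"],
            min_len=data["min_len"],
            provenance=data.get("provenance", ""),
        )


def build_vocabulary(
    train_corpus: Corpus,
    setting: int | FeatureSetting,
    min_count: int = 2,
    min_len: int = 3,
    stopwords: frozenset[str] | None = None,
) -> Vocabulary:
    """Collect and filter the training corpus's features into a vocabulary.

    Token-valued features (F3 token part, F5) are kept only when their total
    occurrence count across the training corpus reaches ``min_count``;
    F1/F2/F4 features are exempt.  Ordering is lexicographic by (kind, key).
    """
    if not train_corpus.documents:
        raise ValueError("training corpus is empty")
    setting = get_setting(setting)
    totals: Counter = Counter()
    for doc in train_corpus.documents:
        totals += compose_features(doc, setting, stopwords, min_len)
    kept = [
        f
        for f, n in totals.items()
        if f.kind not in TOKEN_KINDS or n >= min_count
    ]
    if not kept:
        raise ValueError(
            "vocabulary is empty after filtering; lower min_count/min_len "
            "or provide more training data"
        )
    kept.sort()
    return Vocabulary(
        features=kept,
        setting_id=setting.setting_id,
        min_count=min_count,
        min_len=min_len,
        provenance=corpus_fingerprint(train_corpus),
    )


@dataclass
class CorpusMatrix:
    """Documents x features count matrix plus aligned labels."""

    counts: sp.csr_matrix
    doc_ids: list[str]
    labels: list[str | None]
    vocabulary: Vocabulary

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def y(self) -> np.ndarray:
        """Labels as 0/1 (negative/positive); raises if any label missing."""
        if any(l is None for l in self.labels):
            raise ValueError("matrix has unlabeled rows")
        return np.asarray([1 if l == POSITIVE else 0 for l in self.labels])


def vectorize(
    corpus: Corpus,
    vocab: Vocabulary,
    setting: int | FeatureSetting | None = None,
    stopwords: frozenset[str] | None = None,
) -> CorpusMatrix:
    """Count in-vocabulary feature occurrences per document.

    Features absent from the vocabulary are silently dropped (closed
    vocabulary: the test-time out-of-vocabulary contract).
    """
    setting = get_setting(vocab.setting_id if setting is None else setting)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for i, doc in enumerate(corpus.documents):
        for f, n in compose_features(doc, setting, stopwords, vocab.min_len).items():
            j = vocab.index.get(f)
            if j is not None:
                rows.append(i)
                cols.append(j)
                vals.append(n)
    counts = sp.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(corpus.documents), len(vocab)),
        dtype=np.int64,
    )
    return CorpusMatrix(
        counts=counts,
        doc_ids=corpus.doc_ids(),
        labels=[d.label for d in corpus.documents],
        vocabulary=vocab,
    )


# ---------------------------------------------------------------------------
# matrix export / import
# ---------------------------------------------------------------------------

def export_matrix(matrix: CorpusMatrix, path: str | Path, format: str) -> None:
    """Write a CorpusMatrix as sparse ARFF or SVMlight."""
    if matrix.counts.shape[0] == 0 or matrix.counts.shape[1] == 0:
        raise ValueError("cannot export an empty matrix")
    if format == "arff":
        _export_arff(matrix, path)
    elif format == "svmlight":
        _export_svmlight(matrix, path)
    else:
        raise ValueError(f"unsupported export format {format!r}")


def import_matrix(path: str | Path, format: str, vocab: Vocabulary) -> CorpusMatrix:
    """Read a matrix previously written by :func:`export_matrix`."""
    if format == "arff":
        return _import_arff(path, vocab)
    if format == "svmlight":
        return _import_svmlight(path, vocab)
    raise ValueError(f"unsupported export format {format!r}")


def _attr_name(f: Feature) -> str:
    return f"{f.kind}:{f.key}"


def _export_arff(matrix: CorpusMatrix, path: str | Path) -> None:
    lines = ["@relation triagesort"]
    for f in matrix.vocabulary.features:
        name = _attr_name(f).replace('"', "'")
        lines.append(f'@attribute "{name}" numeric')
    lines.append(f"@attribute class {{{NEGATIVE},{POSITIVE}}}")
    lines.append("@data")
    csr = matrix.counts.tocsr()
    n_feat = len(matrix.vocabulary)
    for i in range(csr.shape[0]):
        row = csr.getrow(i)
        cells = [f"{j} {row[0, j]}" for j in sorted(row.indices)]
        cells.append(f"{n_feat} {matrix.labels[i] or '?'}")
        lines.append("{" + ",".join(cells) + "}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _import_arff(path: str | Path, vocab: Vocabulary) -> CorpusMatrix:
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    labels: list[str | None] = []
    n_feat = len(vocab)
    data_started = False
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not data_started:
            if line.lower() == "@data":
                data_started = True
            continue
        if not line:
            continue
        if not (line.startswith("{") and line.endswith("}")):
            raise ValueError(f"not a sparse ARFF data row: {line!r}")
        i = len(labels)
        label: str | None = None
        for cell in line[1:-1].split(","):
            idx_s, value = cell.strip().split(" ", 1)
            idx = int(idx_s)
            if idx == n_feat:
                label = None if value == "?" else value
            else:
                rows.append(i)
                cols.append(idx)
                vals.append(int(value))
        labels.append(label)
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(labels), n_feat), dtype=np.int64
    )
    return CorpusMatrix(
        counts=counts,
        doc_ids=[str(i) for i in range(len(labels))],
        labels=labels,
        vocabulary=vocab,
    )


def _export_svmlight(matrix: CorpusMatrix, path: str | Path) -> None:
    from sklearn.datasets import dump_svmlight_file

    y = np.asarray(
        [1 if l == POSITIVE else -1 if l == NEGATIVE else 0 for l in matrix.labels]
    )
    dump_svmlight_file(matrix.counts, y, str(path), zero_based=True)


def _import_svmlight(path: str | Path, vocab: Vocabulary) -> CorpusMatrix:
    from sklearn.datasets import load_svmlight_file

    X, y = load_svmlight_file(str(path), n_features=len(vocab), zero_based=True)
    labels: list[str | None] = [
        POSITIVE if v > 0 else NEGATIVE if v < 0 else None for v in y
    ]
    return CorpusMatrix(
        counts=sp.csr_matrix(X, dtype=np.int64),
        doc_ids=[str(i) for i in range(X.shape[0])],
        labels=labels,
        vocabulary=vocab,
    )
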