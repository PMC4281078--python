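"""Synthetic annotated two-class corpora with controllable signal.

The generator emulates the structure of a triage corpus of annotated PubMed
abstracts: ~90/10 negative/positive imbalance, titles and multi-sentence
abstracts built from a Zipf-distributed background vocabulary, inline
bio-entity annotations (entity spans nested inside sentence spans) drawn
from the 22-type schema, EC registry numbers, and a fraction of records
with no abstract text.  Positive documents carry *planted* discriminative
features — specific enzyme-name entity contents, EC numbers and tokens — at
an elevated rate controlled by ``signal_strength``:

    P(planted feature | positive) = background_rate
                                    + signal_strength * (1 - background_rate)
    P(planted feature | negative) = background_rate

so ``signal_strength = 0`` yields class-independent documents (a null model)
and 1 makes every positive document carry every planted feature.

Documents are emitted in the corpus_io record dialect and re-parsed through
:func:`triagesort.corpus_io.parse_document`, so a generated corpus always
round-trips through the package's own reader.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .corpus_io import Corpus, Document, parse_document, write_corpus
from .features import extract_f2, extract_f4, extract_f5, Feature, F2, F4, F5
from .schema import (
    ENTITY_SCHEMA,
    ENTITY_SPAN,
    ENTITY_SPAN_TYPES,
    NEGATIVE,
    POSITIVE,
    SENTENCE_SPAN_TYPES,
)

DEFAULT_PLANTED_ENZYMES = (
    "ligninase",
    "laccase",
    "xylanase",
    "mannanase",
    "cellobiohydrolase",
)
DEFAULT_PLANTED_ECS = ("EC 1.14.99.-", "EC 3.2.1.21", "EC 3.2.1.4")
DEFAULT_PLANTED_TOKENS = ("thermostable", "delignification")

_SYLLABLES = (
    "al an ase bio cel chi dex en fun gal gen hydro lac lig lip man myc "
    "nase oxi pec per poly sac syn tin tro xy zym cul tur pro tein fer"
).split()


def background_vocabulary(size: int) -> list[str]:
    """Deterministic pseudo-biomedical word list (syllable combinations)."""
    words = []
    for a, b in itertools.product(_SYLLABLES, repeat=2):
        w = a + b
        if len(w) >= 3:
            words.append(w)
        if len(words) >= size:
            return words
    for a, b, c in itertools.product(_SYLLABLES, repeat=3):
        words.append(a + b + c)
        if len(words) >= size:
            return words
    raise ValueError(f"cannot build a background vocabulary of size {size}")


@dataclass(frozen=True)
class GeneratorSpec:
    n_pos: int = 75
    n_neg: int = 675
    signal_strength: float = 0.5
    background_rate: float = 0.15
    background_vocab_size: int = 400
    zipf_exponent: float = 1.1
    empty_abstract_fraction: float = 0.09
    ensure_all_entity_types: bool = True
    planted_enzymes: tuple[str, ...] = DEFAULT_PLANTED_ENZYMES
    planted_ecs: tuple[str, ...] = DEFAULT_PLANTED_ECS
    planted_tokens: tuple[str, ...] = DEFAULT_PLANTED_TOKENS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("document counts must be >= 0")
        for p in (
            self.signal_strength,
            self.background_rate,
            self.empty_abstract_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.background_vocab_size < 10:
            raise ValueError("background vocabulary too small")

    @property
    def p_planted_pos(self) -> float:
        return self.background_rate + self.signal_strength * (
            1.0 - self.background_rate
        )

    @property
    def p_planted_neg(self) -> float:
        return self.background_rate


class _DocBuilder:
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        self.rng = rng
        self.vocab = background_vocabulary(spec.background_vocab_size)
        ranks = np.arange(1, len(self.vocab) + 1, dtype=np.float64)
        p = ranks ** -spec.zipf_exponent
        self.probs = p / p.sum()
        # per-class counters driving the forced entity-type rotation
        self.type_cursor = {POSITIVE: 0, NEGATIVE: 0}
        self.all_types = tuple(ENTITY_SCHEMA)

    def words(self, n: int) -> list[str]:
        idx = self.rng.choice(len(self.vocab), size=n, p=self.probs)
        return [self.vocab[i] for i in idx]

    def _wrap_entity(self, word: str, etype: str) -> str:
        return f"<{etype}>{word}</{etype}>"

    def _sentence(
        self,
        label: str,
        enzymes: list[str],
        tokens: list[str],
        forced_type: str | None,
    ) -> str:
        n = int(self.rng.integers(8, 15))
        words = self.words(n)
        for tok in tokens:
            words.insert(int(self.rng.integers(0, len(words) + 1)), tok)
        # random entity annotations on single words
        if self.rng.random() < 0.4:
            k = int(self.rng.integers(0, len(words)))
            etype = ENTITY_SPAN_TYPES[
                int(self.rng.integers(0, len(ENTITY_SPAN_TYPES)))
            ]
            words[k] = self._wrap_entity(words[k], etype)
        for enzyme in enzymes:
            words.insert(
                int(self.rng.integers(0, len(words) + 1)),
                self._wrap_entity(enzyme, "Enzyme"),
            )
        body = " ".join(words) + "."
        wrap_type = None
        if forced_type is not None:
            wrap_type = forced_type
        elif self.rng.random() < 0.35:
            wrap_type = SENTENCE_SPAN_TYPES[
                int(self.rng.integers(0, len(SENTENCE_SPAN_TYPES)))
            ]
        if wrap_type is not None:
            return f"<{wrap_type}>{body}</{wrap_type}>"
        return body

    def build(self, doc_id: str, label: str) -> Document:
        spec, rng = self.spec, self.rng
        p = spec.p_planted_pos if label == POSITIVE else spec.p_planted_neg

        enzymes = [e for e in spec.planted_enzymes if rng.random() < p]
        ecs = [e for e in spec.planted_ecs if rng.random() < p]
        tokens = [t for t in spec.planted_tokens if rng.random() < p]

        forced_type: str | None = None
        if spec.ensure_all_entity_types:
            cursor = self.type_cursor[label]
            forced_type = self.all_types[cursor % len(self.all_types)]
            self.type_cursor[label] = cursor + 1

        title_words = self.words(int(rng.integers(4, 9)))
        if forced_type is not None and ENTITY_SCHEMA[forced_type] == ENTITY_SPAN:
            k = int(rng.integers(0, len(title_words)))
            title_words[k] = self._wrap_entity(title_words[k], forced_type)
            forced_type = None
        elif rng.random() < 0.5:
            k = int(rng.integers(0, len(title_words)))
            etype = ENTITY_SPAN_TYPES[int(rng.integers(0, len(ENTITY_SPAN_TYPES)))]
            title_words[k] = self._wrap_entity(title_words[k], etype)
        title = " ".join(title_words)

        empty_abstract = rng.random() < spec.empty_abstract_fraction
        if empty_abstract:
            if forced_type is not None:  # a pending sentence-span type
                title = f"<{forced_type}>{title}</{forced_type}>"
            abstract = ""
        else:
            n_sent = int(rng.integers(2, 5))
            per_sent: list[list[str]] = [[] for _ in range(n_sent)]
            for enzyme in enzymes:
                per_sent[int(rng.integers(0, n_sent))].append(enzyme)
            per_tok: list[list[str]] = [[] for _ in range(n_sent)]
            for tok in tokens:
                per_tok[int(rng.integers(0, n_sent))].append(tok)
            sentences = []
            for s in range(n_sent):
                sentences.append(
                    self._sentence(
                        label,
                        per_sent[s],
                        per_tok[s],
                        forced_type if s == 0 else None,
                    )
                )
            abstract = " ".join(sentences)

        registry = list(ecs)
        for _ in range(rng.poisson(0.5)):
            parts = rng.integers(1, 100, size=4)
            registry.append("EC {}.{}.{}.{}".format(*parts))

        record = [f'<Document pmid="{doc_id}">']
        record.append(f"<ArticleTitle>{title}</ArticleTitle>")
        record.append(f"<AbstractText>{abstract}</AbstractText>")
        record.extend(f"<RegistryNumber>{r}</RegistryNumber>" for r in registry)
        record.append("</Document>")
        return parse_document("\n".join(record), label)


def generate_corpus(spec: GeneratorSpec) -> Corpus:
    """Generate a labeled, annotated corpus per the generator spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    builder = _DocBuilder(spec, rng)
    labels = [POSITIVE] * spec.n_pos + [NEGATIVE] * spec.n_neg
    order = rng.permutation(len(labels))
    docs = []
    for i, k in enumerate(order):
        docs.append(builder.build(f"SYN{i + 1:07d}", labels[k]))
    return Corpus(docs)


def planted_features(spec: GeneratorSpec) -> list[Feature]:
    """The ground-truth discriminative features the generator plants."""
    if spec.signal_strength == 0:
        return []
    feats = [Feature(F2, f"{e}|enzyme") for e in spec.planted_enzymes]
    feats += [
        Feature(F4, "".join(ch for ch in e if ch.isdigit()))
        for e in spec.planted_ecs
    ]
    feats += [Feature(F5, t) for t in spec.planted_tokens]
    feats += [Feature(F5, e) for e in spec.planted_enzymes]
    return feats


def planted_feature_report(corpus: Corpus, spec: GeneratorSpec) -> dict:
    """Ground-truth signal features with their per-class document frequency."""
    feats = planted_features(spec)
    counts: dict[str, dict[str, int]] = {
        f"{f.kind}:{f.key}": {POSITIVE: 0, NEGATIVE: 0} for f in feats
    }
    if feats:
        for doc in corpus.documents:
            present = set(extract_f2(doc)) | set(extract_f4(doc)) | set(
                extract_f5(doc)
            )
            for f in feats:
                if f in present and doc.label in (POSITIVE, NEGATIVE):
                    counts[f"{f.kind}:{f.key}"][doc.label] += 1
    return {"features": feats, "document_frequency": counts}


def write_synthetic(
    corpus: Corpus, spec: GeneratorSpec, outdir: str | Path
) -> tuple[Path, Path]:
    """Write documents, labels and the generator spec (for provenance)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    docs_path = outdir / "documents.xml"
    labels_path = outdir / "labels.tsv"
    write_corpus(corpus, docs_path, labels_path)
    (outdir / "generator_spec.json").write_text(
        json.dumps(asdict(spec), indent=2), encoding="utf-8"
    )
    return docs_path, labels_path
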