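"""Reading and writing annotated abstract corpora.

A corpus file holds one XML-like ``<Document>`` record per abstract.  Each
record carries a PubMed id, an ``<ArticleTitle>`` and an ``<AbstractText>``
field whose content may contain inline bio-entity annotations (tags from
:mod:`triagesort.schema`), plus ``<RegistryNumber>`` elements for Enzyme
Commission identifiers.  Class labels live in a separate two-column TSV file
of ``pmid<TAB>positive|negative`` pairs, mirroring the form in which triage
corpora are typically released (the document texts and the curation labels
travel separately).

Character offsets of annotations are 0-based, half-open, and refer to the
tag-stripped plain text of the field they annotate, so
``field_text[start:end] == covered_text`` always holds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator

from .schema import CLASSES, ENTITY_SCHEMA


class ParseError(ValueError):
    """Malformed annotated-document input."""


class CorpusError(ValueError):
    """Inconsistent corpus / label-file combination."""


@dataclass
class Annotation:
    """A typed text span, either a single entity or a whole sentence."""

    entity_type: str
    span_kind: str
    field: str  # "title" or "abstract"
    start: int
    end: int
    covered_text: str
    children: list["Annotation"] = dc_field(default_factory=list)

    def walk(self) -> Iterator["Annotation"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Document:
    doc_id: str
    title: str = ""
    abstract: str = ""
    annotations: list[Annotation] = dc_field(default_factory=list)
    registry_numbers: list[str] = dc_field(default_factory=list)
    label: str | None = None
    # Where each registry number sat in the record: ("abstract", pos) for an
    # inline element, None for a stand-alone sibling element.  Parallel to
    # registry_numbers; used only to make write_document round-trip exactly.
    registry_sites: list[tuple[str, int] | None] = dc_field(default_factory=list)

    def iter_annotations(self, field: str | None = None) -> Iterator[Annotation]:
        """All annotations (nested ones included), optionally one field only."""
        for ann in self.annotations:
            for a in ann.walk():
                if field is None or a.field == field:
                    yield a

    def field_text(self, field: str) -> str:
        return self.title if field == "title" else self.abstract


@dataclass
class Corpus:
    documents: list[Document]
    schema: dict[str, str] = dc_field(default_factory=lambda: dict(ENTITY_SCHEMA))

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for d in self.documents:
            if d.label is not None:
                counts[d.label] = counts.get(d.label, 0) + 1
        return counts

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        wanted = set(doc_ids)
        return Corpus(
            [d for d in self.documents if d.doc_id in wanted], dict(self.schema)
        )


_TAG_RE = re.compile(r"<(/?)([A-Za-z][A-Za-z0-9]*)>")
_DOC_OPEN_RE = re.compile(r'<Document\s+pmid="([^"]*)"\s*>')


def _parse_field(raw: str, field: str, schema: dict[str, str], strict: bool):
    """Parse one field's raw content into (plain_text, annotations, registry).

    Returns the tag-stripped text, the top-level annotations (children
    nested), and a list of (value, position) inline registry numbers.
    """
    plain: list[str] = []
    pos = 0  # cursor in raw
    out = 0  # length of plain text so far
    top: list[Annotation] = []
    stack: list[tuple[str, int, list[Annotation]]] = []  # (type, start, children)
    registry: list[tuple[str, int]] = []

    while True:
        m = _TAG_RE.search(raw, pos)
        if m is None:
            break
        plain.append(raw[pos : m.start()])
        out += m.start() - pos
        pos = m.end()
        closing, name = m.group(1) == "/", m.group(2)

        if name == "RegistryNumber":
            if closing:
                raise ParseError(
                    f"{field}: unbalanced closing tag </RegistryNumber> "
                    f"at position {m.start()}"
                )
            if stack:
                raise ParseError(
                    f"{field}: RegistryNumber inside <{stack[-1][0]}> "
                    f"at position {m.start()} is not allowed"
                )
            close = raw.find("</RegistryNumber>", pos)
            if close < 0:
                raise ParseError(
                    f"{field}: unclosed <RegistryNumber> at position {m.start()}"
                )
            registry.append((raw[pos:close], out))
            pos = close + len("</RegistryNumber>")
            continue

        if name not in schema:
            if strict:
                raise ParseError(
                    f"{field}: unknown annotation tag <{'/' if closing else ''}"
                    f"{name}> at position {m.start()}"
                )
            continue  # permissive: drop the tag, keep surrounding text

        if not closing:
            stack.append((name, out, []))
        else:
            if not stack or stack[-1][0] != name:
                raise ParseError(
                    f"{field}: unbalanced closing tag </{name}> "
                    f"at position {m.start()}"
                )
            open_name, start, children = stack.pop()
            text = "".join(plain)[start:out]
            ann = Annotation(
                entity_type=open_name,
                span_kind=schema[open_name],
                field=field,
                start=start,
                end=out,
                covered_text=text,
                children=children,
            )
            (stack[-1][2] if stack else top).append(ann)

    if stack:
        raise ParseError(f"{field}: unclosed tag <{stack[-1][0]}>")
    plain.append(raw[pos:])
    return "".join(plain), top, registry


def _extract_element(raw: str, name: str) -> tuple[str | None, str]:
    """Pop the first ``<name>...</name>`` element; return (content, rest)."""
    m = re.search(rf"<{name}>(.*?)</{name}>", raw, flags=re.S)
    if m is None:
        return None, raw
    return m.group(1), raw[: m.start()] + raw[m.end() :]


def parse_document(
    raw_record: str,
    label: str | None = None,
    *,
    schema: dict[str, str] | None = None,
    strict: bool = True,
) -> Document:
    """Parse one annotated ``<Document>`` record.

    Parameters
    ----------
    raw_record : str
        The record text, ``<Document pmid="...">`` through ``</Document>``.
    label : str, optional
        Class label to attach ("positive" / "negative").
    schema : dict, optional
        Annotation-type -> span-kind table; defaults to the 22-type schema.
    strict : bool
        If True (default), an unknown annotation tag is a :class:`ParseError`;
        if False the tag is dropped and its inner text kept.
    """
    schema = dict(ENTITY_SCHEMA) if schema is None else schema
    if label is not None and label not in CLASSES:
        raise CorpusError(f"unknown class label {label!r} (expected one of {CLASSES})")

    m = _DOC_OPEN_RE.search(raw_record)
    if m is None or not m.group(1):
        raise ParseError("missing document id: no <Document pmid=...> header found")
    doc_id = m.group(1)
    close = raw_record.rfind("</Document>")
    if close < 0:
        raise ParseError(f"document {doc_id}: unclosed <Document>")
    body = raw_record[m.end() : close]

    title_raw, body = _extract_element(body, "ArticleTitle")
    abstract_raw, body = _extract_element(body, "AbstractText")

    annotations: list[Annotation] = []
    registry_numbers: list[str] = []
    registry_sites: list[tuple[str, int] | None] = []

    title, abstract = "", ""
    if title_raw is not None:
        title, anns, regs = _parse_field(title_raw, "title", schema, strict)
        annotations.extend(anns)
        for value, pos in regs:
            registry_numbers.append(value)
            registry_sites.append(("title", pos))
    if abstract_raw is not None:
        abstract, anns, regs = _parse_field(abstract_raw, "abstract", schema, strict)
        annotations.extend(anns)
        for value, pos in regs:
            registry_numbers.append(value)
            registry_sites.append(("abstract", pos))

    # stand-alone sibling RegistryNumber elements
    for rm in re.finditer(r"<RegistryNumber>(.*?)</RegistryNumber>", body, flags=re.S):
        registry_numbers.append(rm.group(1))
        registry_sites.append(None)

    return Document(
        doc_id=doc_id,
        title=title,
        abstract=abstract,
        annotations=annotations,
        registry_numbers=registry_numbers,
        label=label,
        registry_sites=registry_sites,
    )


def _render_field(doc: Document, field: str) -> str:
    """Re-insert annotation tags (and inline registry elements) into a field."""
    text = doc.field_text(field)
    # open/close tag events: (position, order_key, string)
    events: list[tuple[int, int, str]] = []

    def add(ann: Annotation, depth: int) -> None:
        # At equal positions: outer opens first, inner closes first.
        events.append((ann.start, depth, f"<{ann.entity_type}>"))
        events.append((ann.end, -depth, f"</{ann.entity_type}>"))
        for child in ann.children:
            add(child, depth + 1)

    for ann in doc.annotations:
        if ann.field == field:
            add(ann, 1)
    for value, site in zip(doc.registry_numbers, doc.registry_sites):
        if site is not None and site[0] == field:
            events.append(
                (site[1], 0, f"<RegistryNumber>{value}</RegistryNumber>")
            )

    out: list[str] = []
    cursor = 0
    for pos, _key, tag in sorted(events, key=lambda e: (e[0], e[1])):
        out.append(text[cursor:pos])
        out.append(tag)
        cursor = pos
    out.append(text[cursor:])
    return "".join(out)


def write_document(doc: Document) -> str:
    """Serialize a Document back to the annotated-record dialect."""
    parts = [f'<Document pmid="{doc.doc_id}">']
    parts.append(f"<ArticleTitle>{_render_field(doc, 'title')}</ArticleTitle>")
    parts.append(f"<AbstractText>{_render_field(doc, 'abstract')}</AbstractText>")
    for value, site in zip(doc.registry_numbers, doc.registry_sites):
        if site is None:
            parts.append(f"<RegistryNumber>{value}</RegistryNumber>")
    parts.append("</Document>")
    return "\n".join(parts)


def parse_corpus_text(
    text: str, *, schema: dict[str, str] | None = None, strict: bool = True
) -> list[Document]:
    """Parse every ``<Document>`` record found in a corpus file's text."""
    docs = []
    for m in re.finditer(r"<Document\b.*?</Document>", text, flags=re.S):
        docs.append(parse_document(m.group(0), schema=schema, strict=strict))
    return docs


def read_labels(labels_path: str | Path) -> dict[str, str]:
    """Read a ``pmid<TAB>class`` TSV (header row optional)."""
    labels: dict[str, str] = {}
    for lineno, line in enumerate(
        Path(labels_path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CorpusError(f"{labels_path}:{lineno}: expected 2 columns")
        pmid, cls = parts[0].strip(), parts[1].strip().lower()
        if lineno == 1 and pmid.lower() in ("pmid", "id", "doc_id"):
            continue  # header row
        if cls not in CLASSES:
            raise CorpusError(
                f"{labels_path}:{lineno}: unknown class {cls!r} "
                f"(expected one of {CLASSES})"
            )
        if pmid in labels:
            raise CorpusError(f"{labels_path}:{lineno}: duplicate id {pmid}")
        labels[pmid] = cls
    return labels


def load_corpus(
    documents_path: str | Path,
    labels_path: str | Path,
    *,
    schema: dict[str, str] | None = None,
    strict: bool = True,
) -> Corpus:
    """Load documents and join class labels onto them.

    Every document id must appear exactly once in the label file and vice
    versa; any discrepancy raises :class:`CorpusError` listing the ids.
    """
    docs = parse_corpus_text(
        Path(documents_path).read_text(encoding="utf-8"), schema=schema, strict=strict
    )
    labels = read_labels(labels_path)

    doc_ids = [d.doc_id for d in docs]
    dup = {i for i in doc_ids if doc_ids.count(i) > 1} if len(set(doc_ids)) != len(
        doc_ids
    ) else set()
    if dup:
        raise CorpusError(f"duplicate document ids: {sorted(dup)}")
    missing = sorted(set(doc_ids) - set(labels))
    extra = sorted(set(labels) - set(doc_ids))
    if missing or extra:
        raise CorpusError(
            f"document/label mismatch: unlabeled documents {missing}, "
            f"labels without documents {extra}"
        )
    for d in docs:
        d.label = labels[d.doc_id]
    return Corpus(docs, dict(ENTITY_SCHEMA) if schema is None else dict(schema))


def write_corpus(
    corpus: Corpus, documents_path: str | Path, labels_path: str | Path
) -> None:
    """Write a corpus as a document file plus a label TSV."""
    Path(documents_path).write_text(
        "\n".join(write_document(d) for d in corpus.documents) + "\n",
        encoding="utf-8",
    )
    lines = ["pmid\tclass"]
    lines += [f"{d.doc_id}\t{d.label}" for d in corpus.documents]
    Path(labels_path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def corpus_stats(corpus: Corpus) -> dict:
    """Summary counts: totals, per-class counts/percentages, text coverage.

    Percentages are ``100 * count / total`` rounded to 2 decimals.
    """
    total = len(corpus.documents)
    if total == 0:
        raise CorpusError("empty corpus")
    counts = corpus.class_counts()
    with_text = sum(1 for d in corpus.documents if d.abstract.strip())
    return {
        "total": total,
        "class_counts": counts,
        "class_percent": {
            c: round(100.0 * n / total, 2) for c, n in counts.items()
        },
        "with_abstract_text": with_text,
        "with_abstract_text_percent": round(100.0 * with_text / total, 2),
    }
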