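"""Shared fixtures: the annotated sample fragment and tiny corpus builders."""

from __future__ import annotations

import pytest

from triagesort.corpus_io import Corpus, Document, parse_document

# The annotated sample sentence used throughout: a substrate-specificity
# sentence span containing an Enzyme and a Fungus entity span, plus an EC
# registry number.  Note the missing space after the Fungus span and the
# trailing-space enzyme content — both quirks are intentional.
WORKED_RECORD = (
    '<Document pmid="2167173">\n'
    "<ArticleTitle></ArticleTitle>\n"
    "<AbstractText><SubstrateSpecificity>The substrate specificity of three "
    "<Enzyme>ligninase </Enzyme> isozymes from the white-rot fungus "
    "<Fungus>Trametes versicolor</Fungus>has been investigated (…). "
    "</SubstrateSpecificity>(…) "
    "<RegistryNumber>EC 1.14.99.-</RegistryNumber></AbstractText>\n"
    "</Document>"
)


@pytest.fixture
def worked_doc() -> Document:
    return parse_document(WORKED_RECORD, "positive")


def make_record(
    doc_id: str,
    title: str = "",
    abstract: str = "",
    registry: tuple[str, ...] = (),
) -> str:
    parts = [f'<Document pmid="{doc_id}">']
    parts.append(f"<ArticleTitle>{title}</ArticleTitle>")
    parts.append(f"<AbstractText>{abstract}</AbstractText>")
    parts.extend(f"<RegistryNumber>{r}</RegistryNumber>" for r in registry)
    parts.append("</Document>")
    return "\n".join(parts)


def make_doc(
    doc_id: str,
    title: str = "",
    abstract: str = "",
    label: str | None = None,
    registry: tuple[str, ...] = (),
) -> Document:
    return parse_document(make_record(doc_id, title, abstract, registry), label)


def make_corpus(n_pos: int, n_neg: int, text: str = "plain background text") -> Corpus:
    """Minimal labeled corpus of unannotated documents."""
    docs = [
        make_doc(f"P{i}", title=text, label="positive") for i in range(n_pos)
    ] + [make_doc(f"N{i}", title=text, label="negative") for i in range(n_neg)]
    return Corpus(docs)
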