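"""Reading and segmenting abstract corpora.

Two corpus formats are supported: MEDLINE/PubMed XML (``PubmedArticle``
records) and a plain JSONL format with one document per line.  Documents are
split into sentences with stable character offsets; annotated sentences can be
persisted to JSONL and reloaded without loss.

Offsets are 0-based, half-open, counted in Unicode code points.  Sentence
segmentation is deliberately rule-based and deterministic: a boundary is a run
of ``.?!`` followed by whitespace and an uppercase letter or digit, unless the
text up to the punctuation ends in a known abbreviation.  A bit-stable splitter
makes every downstream count reproducible, which matters more here than
matching any particular NLP library's segmentation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator

from lxml import etree

if TYPE_CHECKING:  # pragma: no cover
    from .vocab import Mention

logger = logging.getLogger(__name__)

__all__ = [
    "Document",
    "SentenceRecord",
    "read_medline_xml",
    "read_jsonl_corpus",
    "segment_sentences",
    "write_annotations",
    "read_annotations",
]


@dataclass(frozen=True)
class Document:
    """A single abstract: stable identifier plus body text."""

    doc_id: str
    text: str
    year: int | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.text:
            raise ValueError(f"document {self.doc_id!r}: text must be non-empty")


@dataclass
class SentenceRecord:
    """One sentence of a document, the unit of co-occurrence counting.

    Invariant: ``text == parent_document.text[start:end]``.
    """

    doc_id: str
    sent_index: int
    start: int
    end: int
    text: str
    mentions: list["Mention"] = field(default_factory=list)


# --------------------------------------------------------------------------
# corpus readers


def read_medline_xml(path: str | Path, include_titles: bool = False) -> Iterator[Document]:
    """Stream :class:`Document` objects from a MEDLINE/PubMed XML file.

    One document is yielded per ``PubmedArticle`` record that carries a
    non-empty abstract; multiple ``AbstractText`` sections are concatenated
    with a single space in document order.  When *include_titles* is true the
    article title is prepended (followed by a space).  Records without an
    abstract are skipped and counted in a summary log line; records without a
    PMID are skipped with a warning.  Malformed XML raises
    :class:`lxml.etree.XMLSyntaxError`, which names the offending position.
    """
    skipped_no_abstract = 0
    for _event, elem in etree.iterparse(str(path), events=("end",), tag="PubmedArticle"):
        pmid_el = elem.find("MedlineCitation/PMID")
        pmid = "".join(pmid_el.itertext()).strip() if pmid_el is not None else ""
        abstract_parts = [
            " ".join("".join(node.itertext()).split())
            for node in elem.findall("MedlineCitation/Article/Abstract/AbstractText")
        ]
        abstract = " ".join(p for p in abstract_parts if p)
        if not pmid:
            logger.warning("record without PMID skipped")
        elif not abstract:
            skipped_no_abstract += 1
        else:
            text = abstract
            if include_titles:
                title_el = elem.find("MedlineCitation/Article/ArticleTitle")
                title = " ".join("".join(title_el.itertext()).split()) if title_el is not None else ""
                if title:
                    text = f"{title} {abstract}"
            year_text = elem.findtext(
                "MedlineCitation/Article/Journal/JournalIssue/PubDate/Year"
            )
            year = int(year_text) if year_text and year_text.strip().isdigit() else None
            yield Document(doc_id=pmid, text=text, year=year)
        elem.clear()
    if skipped_no_abstract:
        logger.info("skipped %d records without abstract", skipped_no_abstract)


def read_jsonl_corpus(path: str | Path) -> Iterator[Document]:
    """Stream documents from a JSONL file (``{"id": ..., "text": ...}`` per line)."""
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"invalid JSON at line {lineno}: {exc}") from exc
            for key in ("id", "text"):
                if key not in obj:
                    raise ValueError(f"missing field {key!r} at line {lineno}")
            doc_id = str(obj["id"])
            if doc_id in seen:
                raise ValueError(f"duplicate id {doc_id!r} at line {lineno}")
            seen.add(doc_id)
            yield Document(doc_id=doc_id, text=obj["text"], year=obj.get("year"))


# --------------------------------------------------------------------------
# sentence segmentation

#: Trailing strings that do NOT terminate a sentence even when followed by
#: whitespace + uppercase.  Checked case-insensitively at a word boundary.
ABBREVIATIONS: tuple[str, ...] = (
    "e.g.",
    "i.e.",
    "et al.",
    "fig.",
    "figs.",
    "vs.",
    "cf.",
    "etc.",
    "ca.",
    "approx.",
    "resp.",
)

_BOUNDARY = re.compile(r"[.?!]+(?=\s+[A-Z0-9])")


def _ends_with_abbreviation(prefix: str) -> bool:
    low = prefix.casefold()
    for abbr in ABBREVIATIONS:
        if low.endswith(abbr):
            cut = len(low) - len(abbr)
            if cut == 0 or not low[cut - 1].isalnum():
                return True
    return False


def segment_sentences(doc: Document) -> list[SentenceRecord]:
    """Split a document into sentences with exact character offsets.

    The split is a partition: concatenating the sentence slices together with
    the skipped (whitespace) separators reproduces ``doc.text`` exactly.  In
    the worst case the whole text is one sentence.
    """
    text = doc.text
    boundaries: list[int] = []
    for match in _BOUNDARY.finditer(text):
        if not _ends_with_abbreviation(text[: match.end()]):
            boundaries.append(match.end())

    records: list[SentenceRecord] = []

    def _advance(pos: int) -> int:
        while pos < len(text) and text[pos].isspace():
            pos += 1
        return pos

    start = _advance(0)
    for bound in boundaries:
        if bound <= start:
            continue
        records.append(
            SentenceRecord(
                doc_id=doc.doc_id,
                sent_index=len(records),
                start=start,
                end=bound,
                text=text[start:bound],
            )
        )
        start = _advance(bound)
    tail_end = len(text.rstrip())
    if start < tail_end:
        records.append(
            SentenceRecord(
                doc_id=doc.doc_id,
                sent_index=len(records),
                start=start,
                end=tail_end,
                text=text[start:tail_end],
            )
        )
    return records


# --------------------------------------------------------------------------
# annotated-corpus persistence (JSONL, one sentence per line)


def _sentence_to_obj(sent: SentenceRecord) -> dict:
    return {
        "doc_id": sent.doc_id,
        "sent_index": sent.sent_index,
        "start": sent.start,
        "end": sent.end,
        "text": sent.text,
        "mentions": [
            {
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
                "entity_type": m.entity_type.value,
                "cui": m.cui,
                "link_score": m.link_score,
            }
            for m in sent.mentions
        ],
    }


def write_annotations(sentences: Iterable[SentenceRecord], path: str | Path) -> None:
    """Write annotated sentences to JSONL; repeated writes are byte-identical."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sent in sentences:
            fh.write(json.dumps(_sentence_to_obj(sent), ensure_ascii=False))
            fh.write("\n")


def read_annotations(path: str | Path) -> list[SentenceRecord]:
    """Load annotated sentences written by :func:`write_annotations`."""
    from .vocab import EntityType, Mention  # deferred: vocab imports this module

    records: list[SentenceRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            try:
                mentions = [
                    Mention(
                        start=m["start"],
                        end=m["end"],
                        surface=m["surface"],
                        entity_type=EntityType(m["entity_type"]),
                        cui=m["cui"],
                        link_score=m["link_score"],
                    )
                    for m in obj["mentions"]
                ]
                records.append(
                    SentenceRecord(
                        doc_id=obj["doc_id"],
                        sent_index=obj["sent_index"],
                        start=obj["start"],
                        end=obj["end"],
                        text=obj["text"],
                        mentions=mentions,
                    )
                )
            except KeyError as exc:
                raise ValueError(f"missing field {exc} at line {lineno}") from exc
    return records
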