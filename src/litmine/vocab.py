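"""Entity vocabularies, dictionary mention matching, and concept linking.

Recognition is dictionary-based: greedy longest match over token boundaries
against the alias set of a vocabulary of typed concepts (gene, disease, drug,
cell type), each carrying a CUI-style identifier.  Matching is
case-insensitive for aliases of length >= 4 and case-sensitive for shorter
aliases, so three-letter symbols like "GBA" are not confused with common
lowercase words.

Normalization maps a surface string to the nearest concept by cosine
similarity between character-3gram TF-IDF vectors (aliases padded with one
``#`` boundary marker per side; log-scaled smoothed IDF, L2-normalized).  At
the vocabulary sizes handled here the nearest-neighbour search is exact;
approximate search is an optimisation for corpus-scale vocabularies, not a
semantic change.

The dictionary matcher is the bundled default tagger.  Any external tagger can
be slotted in instead: the contract is simply ``sentence text -> typed raw
spans`` (a callable returning :class:`Mention` objects with ``cui=None``),
which :func:`annotate_corpus` accepts via its ``tagger`` argument.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus import Document, SentenceRecord, segment_sentences

__all__ = [
    "EntityType",
    "Concept",
    "Mention",
    "Vocabulary",
    "build_alias_index",
    "match_mentions",
    "link_mention",
    "annotate_corpus",
    "read_vocabulary_tsv",
    "write_vocabulary_tsv",
    "read_vocabulary_jsonl",
]

DEFAULT_LINK_THRESHOLD = 0.7
DEFAULT_LINK_K = 5

#: Alias length at and above which matching is case-insensitive.
CASEFOLD_MIN_LEN = 4


class EntityType(str, Enum):
    GENE = "GENE"
    DISEASE = "DISEASE"
    DRUG = "DRUG"
    CELL_TYPE = "CELL_TYPE"


@dataclass(frozen=True)
class Concept:
    """A normalized vocabulary entry: identifier, canonical name, type, aliases."""

    cui: str
    name: str
    entity_type: EntityType
    aliases: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.cui or not self.name:
            raise ValueError("concept cui and name must be non-empty")
        aliases = tuple(dict.fromkeys((self.name, *self.aliases)))
        if any(not a for a in aliases):
            raise ValueError(f"concept {self.cui}: empty alias")
        object.__setattr__(self, "aliases", aliases)


@dataclass(frozen=True)
class Mention:
    """A typed entity span inside one sentence (offsets sentence-relative)."""

    start: int
    end: int
    surface: str
    entity_type: EntityType
    cui: str | None = None
    link_score: float = 0.0


def _char_trigrams(surface: str) -> list[str]:
    padded = f"#{surface.casefold()}#"
    return [padded[i : i + 3] for i in range(len(padded) - 2)]


_TOKEN = re.compile(r"\w+", re.UNICODE)


class Vocabulary:
    """A concept collection with alias and character-3gram indices.

    The TF-IDF matrix has one row per (alias, concept) pair so that an alias
    shared by several concepts is retrievable for each of them; disambiguation
    happens at link time.
    """

    def __init__(self, concepts: Iterable[Concept]):
        concepts = sorted(concepts, key=lambda c: c.cui)
        if not concepts:
            raise ValueError("vocabulary must contain at least one concept")
        cuis = [c.cui for c in concepts]
        if len(set(cuis)) != len(cuis):
            dupes = sorted({c for c in cuis if cuis.count(c) > 1})
            raise ValueError(f"duplicate CUIs in vocabulary: {dupes}")
        self.concepts: dict[str, Concept] = {c.cui: c for c in concepts}

        rows: list[tuple[str, str]] = []  # (alias, cui)
        self._alias_exact: dict[str, set[str]] = {}
        self._alias_folded: dict[str, set[str]] = {}
        max_tokens = 1
        for concept in concepts:
            for alias in concept.aliases:
                rows.append((alias, concept.cui))
                self._alias_exact.setdefault(alias, set()).add(concept.cui)
                if len(alias) >= CASEFOLD_MIN_LEN:
                    self._alias_folded.setdefault(alias.casefold(), set()).add(concept.cui)
                max_tokens = max(max_tokens, len(_TOKEN.findall(alias)))
        self._rows = rows
        self._max_alias_tokens = max_tokens
        self._vectorizer = TfidfVectorizer(analyzer=_char_trigrams, norm="l2")
        self._matrix = self._vectorizer.fit_transform([alias for alias, _ in rows])
        self._row_cuis = np.array([cui for _, cui in rows])
        self._row_types = np.array([self.concepts[cui].entity_type.value for _, cui in rows])

    # -- dictionary lookup -------------------------------------------------

    def alias_concepts(self, surface: str) -> set[str]:
        """CUIs whose alias matches *surface* under the case rule."""
        hits = set(self._alias_exact.get(surface, ()))
        folded = surface.casefold()
        if len(folded) >= CASEFOLD_MIN_LEN:
            hits |= self._alias_folded.get(folded, set())
        return hits

    @property
    def n_aliases(self) -> int:
        return len(self._rows)

    def entity_types(self) -> set[EntityType]:
        return {c.entity_type for c in self.concepts.values()}

    # -- 3-gram linking ----------------------------------------------------

    def link(
        self,
        surface: str,
        threshold: float = DEFAULT_LINK_THRESHOLD,
        k: int = DEFAULT_LINK_K,
        entity_type: EntityType | None = None,
    ) -> tuple[str, float] | None:
        """Link *surface* to the most similar concept, or ``None`` if below threshold.

        Cosine similarity over character-3gram TF-IDF vectors; the best of the
        top-*k* alias candidates at or above *threshold* wins, ties broken by
        lexicographically smallest CUI.
        """
        if not 0.0 <= threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if not surface:
            return None
        query = self._vectorizer.transform([surface])
        if query.nnz == 0:
            return None
        sims = np.asarray((self._matrix @ query.T).todense()).ravel()
        if entity_type is not None:
            sims = np.where(self._row_types == entity_type.value, sims, 0.0)
        k = min(max(k, 1), sims.size)
        top = np.argpartition(-sims, k - 1)[:k]
        best_cui: str | None = None
        best_sim = 0.0
        for row in top:
            sim = min(float(sims[row]), 1.0)
            cui = str(self._row_cuis[row])
            if sim > best_sim or (sim == best_sim and best_cui is not None and cui < best_cui):
                best_cui, best_sim = cui, sim
        if best_cui is None or best_sim < threshold or best_sim <= 0.0:
            return None
        return best_cui, best_sim


def build_alias_index(vocabulary: Vocabulary | Iterable[Concept]) -> Vocabulary:
    """Return a :class:`Vocabulary` with alias and 3-gram indices built."""
    if isinstance(vocabulary, Vocabulary):
        return vocabulary
    return Vocabulary(vocabulary)


def link_mention(
    surface: str,
    vocabulary: Vocabulary,
    threshold: float = DEFAULT_LINK_THRESHOLD,
    k: int = DEFAULT_LINK_K,
    entity_type: EntityType | None = None,
) -> tuple[str, float] | None:
    """Functional wrapper around :meth:`Vocabulary.link`."""
    return vocabulary.link(surface, threshold=threshold, k=k, entity_type=entity_type)


def match_mentions(sentence: SentenceRecord | str, vocabulary: Vocabulary) -> list[Mention]:
    """Dictionary-match mentions in a sentence (unlinked: ``cui=None``).

    Greedy longest match over token boundaries; overlapping candidates are
    resolved by longer span first, then leftmost.  A candidate whose matched
    concepts span several entity types yields one mention per type.
    """
    text = sentence.text if isinstance(sentence, SentenceRecord) else sentence
    tokens = [(m.start(), m.end()) for m in _TOKEN.finditer(text)]
    candidates: list[tuple[int, int, str, set[str]]] = []
    for i in range(len(tokens)):
        for n in range(min(vocabulary._max_alias_tokens, len(tokens) - i), 0, -1):
            start, end = tokens[i][0], tokens[i + n - 1][1]
            surface = text[start:end]
            cuis = vocabulary.alias_concepts(surface)
            if cuis:
                candidates.append((start, end, surface, cuis))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
    occupied: list[tuple[int, int]] = []
    mentions: list[Mention] = []
    for start, end, surface, cuis in candidates:
        if any(start < e and s < end for s, e in occupied):
            continue
        occupied.append((start, end))
        types = sorted({vocabulary.concepts[c].entity_type for c in cuis}, key=lambda t: t.value)
        for etype in types:
            mentions.append(Mention(start=start, end=end, surface=surface, entity_type=etype))
    mentions.sort(key=lambda m: (m.start, m.end, m.entity_type.value))
    return mentions


Tagger = Callable[[str], list[Mention]]


def annotate_corpus(
    documents: Iterable[Document],
    vocabulary: Vocabulary,
    threshold: float = DEFAULT_LINK_THRESHOLD,
    k: int = DEFAULT_LINK_K,
    tagger: Tagger | None = None,
) -> Iterator[SentenceRecord]:
    """Segment, tag, and link every document; yields sentences with linked mentions.

    Mentions that fail to link at *threshold* are dropped (they cannot be
    counted).  When an ambiguous surface passes the threshold for several
    entity types, one linked mention per passing type is kept.  The default
    tagger is the vocabulary dictionary matcher; pass *tagger* to substitute
    an external NER component.
    """
    tag = tagger if tagger is not None else (lambda text: match_mentions(text, vocabulary))
    cache: dict[tuple[str, EntityType], tuple[str, float] | None] = {}
    for doc in documents:
        for sent in segment_sentences(doc):
            linked: list[Mention] = []
            for mention in tag(sent.text):
                key = (mention.surface.casefold(), mention.entity_type)
                if key not in cache:
                    cache[key] = vocabulary.link(
                        mention.surface, threshold=threshold, k=k, entity_type=mention.entity_type
                    )
                hit = cache[key]
                if hit is not None:
                    linked.append(replace(mention, cui=hit[0], link_score=hit[1]))
            sent.mentions = sorted(linked, key=lambda m: (m.start, m.end, m.entity_type.value))
            yield sent


# --------------------------------------------------------------------------
# vocabulary I/O


def read_vocabulary_tsv(path: str | Path) -> Vocabulary:
    """Read a vocabulary TSV with columns cui, name, entity_type, aliases (pipe-separated)."""
    concepts = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["cui", "name", "entity_type", "aliases"]
        if header != expected:
            raise ValueError(f"vocabulary TSV header must be {expected}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            cui, name, etype, aliases = line.rstrip("\n").split("\t")
            concepts.append(
                Concept(
                    cui=cui,
                    name=name,
                    entity_type=EntityType(etype),
                    aliases=tuple(a for a in aliases.split("|") if a),
                )
            )
    return Vocabulary(concepts)


def write_vocabulary_tsv(vocabulary: Vocabulary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cui\tname\tentity_type\taliases\n")
        for cui in sorted(vocabulary.concepts):
            c = vocabulary.concepts[cui]
            fh.write(f"{c.cui}\t{c.name}\t{c.entity_type.value}\t{'|'.join(c.aliases)}\n")


def read_vocabulary_jsonl(path: str | Path) -> Vocabulary:
    """Read a vocabulary from JSONL (keys cui, name, entity_type, aliases)."""
    concepts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            concepts.append(
                Concept(
                    cui=obj["cui"],
                    name=obj["name"],
                    entity_type=EntityType(obj["entity_type"]),
                    aliases=tuple(obj.get("aliases", ())),
                )
            )
    return Vocabulary(concepts)
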