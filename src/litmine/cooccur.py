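"""Sentence-level co-occurrence counting for typed entity pairs.

The counting unit is the sentence, and counting is deduplicated per sentence:
a sentence contributes at most 1 to C_xy for a given concept pair (x, y), at
most 1 to each margin C_x* and C_*y, and at most 1 to the total C_**,
regardless of how many times either entity is mentioned in it.  Only sentences
containing at least one X-typed and one Y-typed linked mention contribute
anywhere.  Counting a sentence once per distinct pair (not per mention pair)
is an explicit modelling choice; see the methods note.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .corpus import SentenceRecord
from .vocab import EntityType

__all__ = [
    "MINED_TYPE_PAIRS",
    "PairKey",
    "CooccurrenceTable",
    "count_cooccurrences",
    "merge_counts",
    "build_evidence_index",
    "extract_evidence",
    "write_counts",
    "read_counts",
]

#: The four mined ordered type pairs.
MINED_TYPE_PAIRS: tuple[tuple[EntityType, EntityType], ...] = (
    (EntityType.GENE, EntityType.DISEASE),
    (EntityType.CELL_TYPE, EntityType.DISEASE),
    (EntityType.DRUG, EntityType.DISEASE),
    (EntityType.DRUG, EntityType.GENE),
)


class PairKey(NamedTuple):
    type_x: EntityType
    type_y: EntityType
    cui_x: str
    cui_y: str


@dataclass
class CooccurrenceTable:
    """Count statistics C_xy, C_x*, C_*y, C_** for one ordered type pair."""

    type_pair: tuple[EntityType, EntityType]
    c_xy: Counter = field(default_factory=Counter)  # (cui_x, cui_y) -> sentences
    c_x: Counter = field(default_factory=Counter)  # cui_x -> sentences with x and any Y
    c_y: Counter = field(default_factory=Counter)  # cui_y -> sentences with y and any X
    c_total: int = 0  # sentences with any X and any Y

    def validate(self) -> None:
        for (x, y), n in self.c_xy.items():
            if n < 0 or n > min(self.c_x[x], self.c_y[y]):
                raise ValueError(f"count invariant violated for pair {(x, y)}")
        for margin in (self.c_x, self.c_y):
            for cui, n in margin.items():
                if n < 0 or n > self.c_total:
                    raise ValueError(f"margin invariant violated for {cui}")

    def pair_key(self, cui_x: str, cui_y: str) -> PairKey:
        return PairKey(self.type_pair[0], self.type_pair[1], cui_x, cui_y)


def _check_type_pair(type_pair: tuple[EntityType, EntityType]) -> tuple[EntityType, EntityType]:
    type_pair = (EntityType(type_pair[0]), EntityType(type_pair[1]))
    if type_pair not in MINED_TYPE_PAIRS:
        raise ValueError(
            f"unknown type pair {type_pair}; mined pairs are "
            + ", ".join(f"{a.value}-{b.value}" for a, b in MINED_TYPE_PAIRS)
        )
    return type_pair


def _sentence_cui_sets(
    sent: SentenceRecord, type_pair: tuple[EntityType, EntityType]
) -> tuple[set[str], set[str]]:
    type_x, type_y = type_pair
    xs = {m.cui for m in sent.mentions if m.entity_type == type_x and m.cui}
    ys = {m.cui for m in sent.mentions if m.entity_type == type_y and m.cui}
    return xs, ys


def count_cooccurrences(
    sentences: Iterable[SentenceRecord], type_pair: tuple[EntityType, EntityType]
) -> CooccurrenceTable:
    """Build the co-occurrence table for one ordered type pair.

    Pairs where both members carry the same CUI (a rare alias collision across
    types) are excluded from C_xy but still feed the margins.
    """
    type_pair = _check_type_pair(type_pair)
    table = CooccurrenceTable(type_pair=type_pair)
    for sent in sentences:
        xs, ys = _sentence_cui_sets(sent, type_pair)
        if not xs or not ys:
            continue
        table.c_total += 1
        for x in xs:
            table.c_x[x] += 1
        for y in ys:
            table.c_y[y] += 1
        for x in xs:
            for y in ys:
                if x != y:
                    table.c_xy[(x, y)] += 1
    return table


def merge_counts(table_a: CooccurrenceTable, table_b: CooccurrenceTable) -> CooccurrenceTable:
    """Entrywise sum of two tables over the same type pair.

    For disjoint document sets this equals counting the union in one pass,
    which is what makes incremental (e.g. monthly) corpus updates possible.
    """
    if table_a.type_pair != table_b.type_pair:
        raise ValueError(
            f"type pair mismatch: {table_a.type_pair} vs {table_b.type_pair}"
        )
    return CooccurrenceTable(
        type_pair=table_a.type_pair,
        c_xy=table_a.c_xy + table_b.c_xy,
        c_x=table_a.c_x + table_b.c_x,
        c_y=table_a.c_y + table_b.c_y,
        c_total=table_a.c_total + table_b.c_total,
    )


def build_evidence_index(
    sentences: Iterable[SentenceRecord], type_pair: tuple[EntityType, EntityType]
) -> dict[PairKey, list[tuple[str, int]]]:
    """Map each co-occurring pair to its supporting (doc_id, sent_index) refs, in corpus order."""
    type_pair = _check_type_pair(type_pair)
    index: dict[PairKey, list[tuple[str, int]]] = {}
    for sent in sentences:
        xs, ys = _sentence_cui_sets(sent, type_pair)
        for x in sorted(xs):
            for y in sorted(ys):
                if x != y:
                    key = PairKey(type_pair[0], type_pair[1], x, y)
                    index.setdefault(key, []).append((sent.doc_id, sent.sent_index))
    return index


def extract_evidence(sentences: Iterable[SentenceRecord], pair: PairKey) -> list[SentenceRecord]:
    """Return the sentences supporting *pair* (text plus provenance), in corpus order."""
    out = []
    for sent in sentences:
        xs, ys = _sentence_cui_sets(sent, (pair.type_x, pair.type_y))
        if pair.cui_x in xs and pair.cui_y in ys and pair.cui_x != pair.cui_y:
            out.append(sent)
    return out


# --------------------------------------------------------------------------
# persistence: four TSV files in a directory


def write_counts(table: CooccurrenceTable, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tx, ty = table.type_pair
    with open(directory / "pairs.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("type_x\ttype_y\tcui_x\tcui_y\tcount\n")
        for (x, y) in sorted(table.c_xy):
            fh.write(f"{tx.value}\t{ty.value}\t{x}\t{y}\t{table.c_xy[(x, y)]}\n")
    for fname, margin in (("margins_x.tsv", table.c_x), ("margins_y.tsv", table.c_y)):
        with open(directory / fname, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("cui\tcount\n")
            for cui in sorted(margin):
                fh.write(f"{cui}\t{margin[cui]}\n")
    with open(directory / "totals.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("type_x\ttype_y\tc_total\n")
        fh.write(f"{tx.value}\t{ty.value}\t{table.c_total}\n")


def read_counts(directory: str | Path) -> CooccurrenceTable:
    directory = Path(directory)
    with open(directory / "totals.tsv", encoding="utf-8") as fh:
        fh.readline()
        tx, ty, total = fh.readline().rstrip("\n").split("\t")
    table = CooccurrenceTable(
        type_pair=_check_type_pair((EntityType(tx), EntityType(ty))), c_total=int(total)
    )
    with open(directory / "pairs.tsv", encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                _, _, x, y, n = line.rstrip("\n").split("\t")
                table.c_xy[(x, y)] = int(n)
    for fname, margin in (("margins_x.tsv", table.c_x), ("margins_y.tsv", table.c_y)):
        with open(directory / fname, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                if line.strip():
                    cui, n = line.rstrip("\n").split("\t")
                    margin[cui] = int(n)
    table.validate()
    return table
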