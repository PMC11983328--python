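"""Synthetic vocabularies and corpora with planted associations of known strength.

The generator emulates the sentence-level co-mention structure the pipeline
mines, with none of the linguistic noise: sentences are filled from fixed
templates so the dictionary tagger has exact recall, isolating the counting
and scoring statistics from NER errors.  Each candidate entity pair (x, y) is
co-mentioned in any given sentence with probability ``base_rate``; planted
pairs are boosted by a lift factor ``lambda >= 1``, so their expected
co-mention count is ``n_sentences * base_rate * lambda``.  Co-mention events
are placed in distinct sentence slots (at most one pair per sentence);
remaining sentences become single-entity or entity-free filler.

Entity surfaces default to the canonical name; a "typo mode"
(``typo_rate > 0``) substitutes the concept's misspelling-variant alias
(second and third characters transposed) to exercise the character-3gram
linker.  An optional Zipf popularity weight over entities produces the
heterogeneous margins seen in real literature, where common diseases dwarf
rare ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .corpus import Document
from .cooccur import MINED_TYPE_PAIRS, PairKey
from .vocab import Concept, EntityType, Vocabulary

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_vocabulary",
    "generate_corpus",
    "default_recovery_spec",
    "write_truth_tsv",
    "read_truth_tsv",
]

_TYPE_PREFIX = {
    EntityType.GENE: ("CG", "GENE"),
    EntityType.DISEASE: ("CD", "DISEASE"),
    EntityType.DRUG: ("CR", "DRUG"),
    EntityType.CELL_TYPE: ("CC", "CELL"),
}

#: Sentence templates per ordered type pair; slots {x} and {y}.
DEFAULT_TEMPLATES: dict[tuple[EntityType, EntityType], tuple[str, ...]] = {
    (EntityType.GENE, EntityType.DISEASE): (
        "{x} is associated with {y}.",
        "Variants of {x} increase the risk of {y}.",
        "Expression of {x} modulates {y} progression.",
    ),
    (EntityType.CELL_TYPE, EntityType.DISEASE): (
        "{x} infiltration is associated with {y}.",
        "Depletion of {x} alleviates {y}.",
    ),
    (EntityType.DRUG, EntityType.DISEASE): (
        "{x} is used to treat {y}.",
        "Treatment with {x} improved outcomes in {y}.",
    ),
    (EntityType.DRUG, EntityType.GENE): (
        "{x} inhibits {y}.",
        "{x} targets the product of {y}.",
    ),
}

_SINGLE_TEMPLATES = (
    "{x} was examined in detail.",
    "A cohort study measured {x} levels.",
)

_EMPTY_FILLERS = (
    "The measurements were repeated across laboratories.",
    "Samples were processed under standard conditions.",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    n_genes: int = 200
    n_diseases: int = 20
    n_drugs: int = 0
    n_celltypes: int = 0
    n_sentences: int = 5000
    base_rate: float = 0.0002
    #: (cui_x, cui_y, lift) triples; CUIs follow the deterministic scheme below.
    planted_pairs: tuple[tuple[str, str, float], ...] = ()
    sentences_per_doc: int = 5
    single_entity_rate: float = 0.5
    typo_rate: float = 0.0
    zipf_exponent: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("base_rate must be a probability")
        if not 0.0 <= self.typo_rate <= 1.0 or not 0.0 <= self.single_entity_rate <= 1.0:
            raise ValueError("rates must be probabilities")
        for x, y, lift in self.planted_pairs:
            if lift < 1.0:
                raise ValueError(f"lift for ({x}, {y}) must be >= 1")
            if lift * self.base_rate > 1.0:
                raise ValueError(f"lift*base_rate > 1 for ({x}, {y})")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a generated corpus: planted pairs, lifts, expected counts."""

    lifts: dict[PairKey, float] = field(default_factory=dict)
    expected_counts: dict[PairKey, float] = field(default_factory=dict)


def default_recovery_spec(seed: int = 1) -> SyntheticSpec:
    """The canonical planted-association recovery condition.

    200 genes x 20 diseases, 5,000 sentences, background rate 1/5,000 (so a
    background pair averages one co-mention), and 10 planted gene-disease
    pairs at lift 20 (pair i: gene i with disease i).
    """
    planted = tuple(
        (f"CG{i:04d}", f"CD{i:04d}", 20.0) for i in range(10)
    )
    return SyntheticSpec(planted_pairs=planted, seed=seed)


def _misspell(name: str) -> str:
    if len(name) < 3:
        return name[::-1]
    return name[0] + name[2] + name[1] + name[3:]


def _type_sizes(spec: SyntheticSpec) -> dict[EntityType, int]:
    return {
        EntityType.GENE: spec.n_genes,
        EntityType.DISEASE: spec.n_diseases,
        EntityType.DRUG: spec.n_drugs,
        EntityType.CELL_TYPE: spec.n_celltypes,
    }


def generate_vocabulary(spec: SyntheticSpec) -> Vocabulary:
    """Deterministic synthetic vocabulary; CUIs are zero-padded per type.

    Every concept gets its canonical name, a qualified variant, and a
    misspelling-variant alias.  Alias uniqueness holds by construction: the
    misspelling scheme transposes the fixed type prefix, which no canonical
    name shares, and the numeric suffix stays unique.
    """
    concepts: list[Concept] = []
    qualifier = {
        EntityType.GENE: "{name} protein",
        EntityType.DISEASE: "{name} syndrome",
        EntityType.DRUG: "{name} compound",
        EntityType.CELL_TYPE: "{name} cells",
    }
    for etype, size in _type_sizes(spec).items():
        prefix, stem = _TYPE_PREFIX[etype]
        for i in range(size):
            name = f"{stem}{i:04d}"
            concepts.append(
                Concept(
                    cui=f"{prefix}{i:04d}",
                    name=name,
                    entity_type=etype,
                    aliases=(qualifier[etype].format(name=name), _misspell(name)),
                )
            )
    if not concepts:
        raise ValueError("at least one entity type must have non-zero size")
    return Vocabulary(concepts)


def _pair_universe(
    spec: SyntheticSpec, vocabulary: Vocabulary
) -> list[tuple[tuple[EntityType, EntityType], str, str]]:
    by_type: dict[EntityType, list[str]] = {}
    for cui, concept in sorted(vocabulary.concepts.items()):
        by_type.setdefault(concept.entity_type, []).append(cui)
    universe = []
    for tx, ty in MINED_TYPE_PAIRS:
        for x in by_type.get(tx, ()):
            for y in by_type.get(ty, ()):
                universe.append(((tx, ty), x, y))
    return universe


def generate_corpus(
    spec: SyntheticSpec, vocabulary: Vocabulary | None = None
) -> tuple[list[Document], PlantedTruth]:
    """Generate documents plus the planted ground truth; byte-stable under seed."""
    if vocabulary is None:
        vocabulary = generate_vocabulary(spec)
    rng = np.random.default_rng(spec.seed)
    universe = _pair_universe(spec, vocabulary)
    if not universe and spec.base_rate > 0:
        raise ValueError("no mineable type pair has entities on both sides")
    planted_lookup = {(x, y): lift for x, y, lift in spec.planted_pairs}
    for (x, y) in planted_lookup:
        if x not in vocabulary.concepts or y not in vocabulary.concepts:
            raise ValueError(f"planted pair ({x}, {y}) not in vocabulary")

    rates = np.full(len(universe), spec.base_rate)
    if spec.zipf_exponent > 0:
        weight: dict[str, float] = {}
        by_type: dict[EntityType, int] = {}
        for cui in sorted(vocabulary.concepts):
            etype = vocabulary.concepts[cui].entity_type
            rank = by_type.get(etype, 0) + 1
            by_type[etype] = rank
            weight[cui] = rank ** (-spec.zipf_exponent)
        raw = np.array([weight[x] * weight[y] for _, x, y in universe])
        rates = spec.base_rate * raw / raw.mean()
    lifts = np.array(
        [planted_lookup.get((x, y), 1.0) for _, x, y in universe]
    )
    rates = rates * lifts
    if np.any(rates > 1.0):
        raise ValueError("lift*rate exceeds 1 for at least one pair")

    counts = rng.binomial(spec.n_sentences, rates) if len(universe) else np.array([], int)
    total_events = int(counts.sum())
    if total_events > spec.n_sentences:
        raise ValueError(
            f"{total_events} co-mention events exceed {spec.n_sentences} sentences; "
            "lower base_rate or lifts"
        )
    slots = rng.permutation(spec.n_sentences)[:total_events]
    assignment: dict[int, int] = {}  # sentence index -> pair index
    cursor = 0
    for pair_idx, count in enumerate(counts):
        for _ in range(int(count)):
            assignment[int(slots[cursor])] = pair_idx
            cursor += 1

    all_cuis = sorted(vocabulary.concepts)

    def surface(cui: str) -> str:
        concept = vocabulary.concepts[cui]
        if spec.typo_rate > 0 and rng.random() < spec.typo_rate:
            return _misspell(concept.name)
        return concept.name

    sentences: list[str] = []
    for i in range(spec.n_sentences):
        if i in assignment:
            type_pair, x, y = universe[assignment[i]]
            templates = DEFAULT_TEMPLATES[type_pair]
            template = templates[int(rng.integers(len(templates)))]
            sentences.append(template.format(x=surface(x), y=surface(y)))
        elif rng.random() < spec.single_entity_rate and all_cuis:
            cui = all_cuis[int(rng.integers(len(all_cuis)))]
            template = _SINGLE_TEMPLATES[int(rng.integers(len(_SINGLE_TEMPLATES)))]
            sentences.append(template.format(x=surface(cui)))
        else:
            sentences.append(_EMPTY_FILLERS[int(rng.integers(len(_EMPTY_FILLERS)))])

    per_doc = max(1, spec.sentences_per_doc)
    documents = [
        Document(
            doc_id=f"SYN{start // per_doc:05d}",
            text=" ".join(sentences[start : start + per_doc]),
        )
        for start in range(0, len(sentences), per_doc)
    ]

    truth = PlantedTruth(
        lifts={
            PairKey(tp[0], tp[1], x, y): planted_lookup[(x, y)]
            for tp, x, y in universe
            if (x, y) in planted_lookup
        },
        expected_counts={
            PairKey(tp[0], tp[1], x, y): spec.n_sentences
            * spec.base_rate
            * planted_lookup[(x, y)]
            for tp, x, y in universe
            if (x, y) in planted_lookup
        },
    )
    return documents, truth


def write_truth_tsv(truth: PlantedTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("type_x\ttype_y\tcui_x\tcui_y\tlift\texpected_count\n")
        for key in sorted(truth.lifts):
            fh.write(
                f"{key.type_x.value}\t{key.type_y.value}\t{key.cui_x}\t{key.cui_y}\t"
                f"{truth.lifts[key]:g}\t{truth.expected_counts[key]:g}\n"
            )


def read_truth_tsv(path: str | Path) -> PlantedTruth:
    lifts: dict[PairKey, float] = {}
    expected: dict[PairKey, float] = {}
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            tx, ty, x, y, lift, exp = line.rstrip("\n").split("\t")
            key = PairKey(EntityType(tx), EntityType(ty), x, y)
            lifts[key] = float(lift)
            expected[key] = float(exp)
    return PlantedTruth(lifts=lifts, expected_counts=expected)
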