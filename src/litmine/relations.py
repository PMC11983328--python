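"""Gene-disease relation-extraction scaffolding.

A transformer classifier for gene-disease relation labels is a heavyweight,
externally trained component.  This module implements everything around it:
entity masking with dummy tokens (``$gene`` / ``$disease``), the closed
seven-label taxonomy, a pluggable classifier contract (any callable mapping
masked sentence text to a label), and per-gene aggregation of sentence-level
labels into percentage tables.

The bundled :class:`KeywordRuleClassifier` is a deliberately trivial keyword
baseline that exists solely to exercise the pipeline end to end.  It is NOT a
substitute for a trained relation classifier and its labels carry no
scientific weight; plug a real model in through the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, NamedTuple, Sequence

import pandas as pd

from .corpus import SentenceRecord
from .cooccur import PairKey
from .vocab import EntityType, Mention

__all__ = [
    "RelationLabel",
    "GENE_TOKEN",
    "DISEASE_TOKEN",
    "MaskedSpan",
    "MaskedSentence",
    "SentenceLabel",
    "mask_entities",
    "unmask",
    "classify_sentences",
    "KeywordRuleClassifier",
    "aggregate_label_percentages",
]

GENE_TOKEN = "$gene"
DISEASE_TOKEN = "$disease"


class RelationLabel(str, Enum):
    """The closed seven-label gene-disease relationship taxonomy."""

    NO_EXPLICIT_RELATIONSHIP = "NO_EXPLICIT_RELATIONSHIP"
    PLAYS_A_ROLE = "PLAYS_A_ROLE"
    TARGET_GENERAL = "TARGET_GENERAL"
    TARGET_CAUSATIVE = "TARGET_CAUSATIVE"
    TARGET_MODULATOR_DECREASE = "TARGET_MODULATOR_DECREASE"
    TARGET_MODULATOR_INCREASE = "TARGET_MODULATOR_INCREASE"
    BIOMARKER = "BIOMARKER"


class MaskedSpan(NamedTuple):
    orig_start: int
    orig_end: int
    masked_start: int
    masked_end: int
    surface: str
    placeholder: str


@dataclass(frozen=True)
class MaskedSentence:
    """Sentence text with entity surfaces replaced by dummy tokens."""

    text: str
    doc_id: str
    sent_index: int
    gene_cui: str
    disease_cui: str
    spans: tuple[MaskedSpan, ...]


class SentenceLabel(NamedTuple):
    doc_id: str
    sent_index: int
    pair: PairKey
    label: RelationLabel


def mask_entities(
    sentence: SentenceRecord, gene_mention: Mention, disease_mention: Mention
) -> MaskedSentence:
    """Replace the gene and disease surfaces of one pair with dummy tokens.

    Every mention in the sentence sharing the gene's CUI becomes ``$gene`` and
    every mention sharing the disease's CUI becomes ``$disease``, so repeated
    surfaces are masked exhaustively.  Overlapping spans or spans outside the
    sentence are errors.
    """
    text = sentence.text
    targets: list[tuple[int, int, str]] = []
    pool = list(sentence.mentions)
    for extra in (gene_mention, disease_mention):
        if extra not in pool:
            pool.append(extra)
    for m in pool:
        if m.cui == gene_mention.cui and m.entity_type == gene_mention.entity_type:
            targets.append((m.start, m.end, GENE_TOKEN))
        elif m.cui == disease_mention.cui and m.entity_type == disease_mention.entity_type:
            targets.append((m.start, m.end, DISEASE_TOKEN))
    targets = sorted(set(targets))
    for start, end, _ in targets:
        if not (0 <= start < end <= len(text)):
            raise ValueError(f"mention span ({start}, {end}) outside sentence bounds")
    for (s1, e1, _), (s2, e2, _) in zip(targets, targets[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping mention spans ({s1}, {e1}) and ({s2}, {e2})")

    pieces: list[str] = []
    spans: list[MaskedSpan] = []
    cursor = 0
    masked_len = 0
    for start, end, token in targets:
        pieces.append(text[cursor:start])
        masked_len += start - cursor
        spans.append(
            MaskedSpan(start, end, masked_len, masked_len + len(token), text[start:end], token)
        )
        pieces.append(token)
        masked_len += len(token)
        cursor = end
    pieces.append(text[cursor:])
    return MaskedSentence(
        text="".join(pieces),
        doc_id=sentence.doc_id,
        sent_index=sentence.sent_index,
        gene_cui=gene_mention.cui or "",
        disease_cui=disease_mention.cui or "",
        spans=tuple(spans),
    )


def unmask(masked: MaskedSentence) -> str:
    """Reconstruct the original sentence text from a masked sentence."""
    text = masked.text
    pieces = []
    cursor = 0
    for span in masked.spans:
        pieces.append(text[cursor : span.masked_start])
        pieces.append(span.surface)
        cursor = span.masked_end
    pieces.append(text[cursor:])
    return "".join(pieces)


Classifier = Callable[[str], RelationLabel]


def classify_sentences(
    masked_sentences: Iterable[MaskedSentence], classifier: Classifier
) -> list[SentenceLabel]:
    """Apply a classifier to masked sentences; one label per input.

    The classifier contract is a single callable from masked text to a
    :class:`RelationLabel`; anything outside the taxonomy is an error.
    """
    out: list[SentenceLabel] = []
    for ms in masked_sentences:
        label = classifier(ms.text)
        if not isinstance(label, RelationLabel):
            raise ValueError(f"classifier returned out-of-taxonomy label {label!r}")
        out.append(
            SentenceLabel(
                doc_id=ms.doc_id,
                sent_index=ms.sent_index,
                pair=PairKey(EntityType.GENE, EntityType.DISEASE, ms.gene_cui, ms.disease_cui),
                label=label,
            )
        )
    return out


class KeywordRuleClassifier:
    """Trivial keyword baseline exercising the classifier contract.

    Rules are checked in the order below against the lowercased masked text;
    the first hit wins, and a text matching no rule gets
    ``NO_EXPLICIT_RELATIONSHIP``.  Documented rule table:

    1. BIOMARKER              -- "biomarker", "marker for", "diagnostic marker"
    2. TARGET_CAUSATIVE       -- "causes", "cause of", "causative", "leads to"
    3. TARGET_MODULATOR_DECREASE -- "decreases", "alleviates", "reduces",
                                    "protects against", "suppresses"
    4. TARGET_MODULATOR_INCREASE -- "increases", "worsens", "exacerbates",
                                    "aggravates", "promotes"
    5. TARGET_GENERAL         -- "target", "therapeutic"
    6. PLAYS_A_ROLE           -- "plays a role", "involved in",
                                 "associated with", "implicated in",
                                 "linked to", "modulates", "related to"
    """

    RULES: tuple[tuple[tuple[str, ...], RelationLabel], ...] = (
        (("biomarker", "marker for", "diagnostic marker"), RelationLabel.BIOMARKER),
        (("causes", "cause of", "causative", "leads to"), RelationLabel.TARGET_CAUSATIVE),
        (
            ("decreases", "alleviates", "reduces", "protects against", "suppresses"),
            RelationLabel.TARGET_MODULATOR_DECREASE,
        ),
        (
            ("increases", "worsens", "exacerbates", "aggravates", "promotes"),
            RelationLabel.TARGET_MODULATOR_INCREASE,
        ),
        (("target", "therapeutic"), RelationLabel.TARGET_GENERAL),
        (
            (
                "plays a role",
                "involved in",
                "associated with",
                "implicated in",
                "linked to",
                "modulates",
                "related to",
            ),
            RelationLabel.PLAYS_A_ROLE,
        ),
    )

    def __call__(self, masked_text: str) -> RelationLabel:
        low = masked_text.casefold()
        for keywords, label in self.RULES:
            if any(kw in low for kw in keywords):
                return label
        return RelationLabel.NO_EXPLICIT_RELATIONSHIP


#: Column order of the aggregation table (taxonomy order, then the count).
AGGREGATE_COLUMNS = [label.value for label in RelationLabel] + ["sentence_count"]


def aggregate_label_percentages(
    labels: Sequence[SentenceLabel], min_sentences: int = 50
) -> pd.DataFrame:
    """Per-gene percentage of sentences in each relation category.

    *labels* must all refer to one disease.  Genes with fewer than
    *min_sentences* supporting sentences are dropped; percentages are rounded
    to one decimal; rows are sorted by sentence count descending, ties by gene
    CUI.  The index is the gene CUI.
    """
    if not labels:
        return pd.DataFrame(columns=AGGREGATE_COLUMNS)
    diseases = {lab.pair.cui_y for lab in labels}
    if len(diseases) > 1:
        raise ValueError(f"labels span several diseases: {sorted(diseases)}")
    frame = pd.DataFrame(
        {
            "gene": [lab.pair.cui_x for lab in labels],
            "label": [lab.label.value for lab in labels],
        }
    )
    counts = (
        frame.groupby(["gene", "label"]).size().unstack(fill_value=0)
        .reindex(columns=[label.value for label in RelationLabel], fill_value=0)
    )
    totals = counts.sum(axis=1)
    keep = totals[totals >= min_sentences].index
    counts = counts.loc[keep]
    totals = totals.loc[keep]
    pct = (100.0 * counts.div(totals, axis=0)).round(1)
    pct["sentence_count"] = totals
    pct = pct.sort_index(kind="mergesort")  # tie order: gene CUI ascending
    pct = pct.sort_values(by="sentence_count", ascending=False, kind="mergesort")
    pct.index.name = "gene"
    return pct[AGGREGATE_COLUMNS]
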