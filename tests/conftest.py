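import pytest

from litmine.corpus import SentenceRecord
from litmine.vocab import Concept, EntityType, Mention, Vocabulary


def make_mention(cui: str, etype: EntityType, start: int = 0, end: int = 1, surface: str = "x"):
    return Mention(
        start=start, end=end, surface=surface, entity_type=etype, cui=cui, link_score=1.0
    )


def make_sentence(doc_id: str, sent_index: int, cuis: list[tuple[str, EntityType]], text: str = ""):
    """Annotated sentence stub for counting tests: only mention cui/type matter."""
    text = text or " ".join(c for c, _ in cuis) or "filler"
    mentions = []
    pos = 0
    for cui, etype in cuis:
        mentions.append(make_mention(cui, etype, start=pos, end=pos + 1, surface=cui))
        pos += 2
    return SentenceRecord(
        doc_id=doc_id, sent_index=sent_index, start=0, end=len(text), text=text, mentions=mentions
    )


@pytest.fixture
def tiny_vocab() -> Vocabulary:
    return Vocabulary(
        [
            Concept("C0001", "TP53", EntityType.GENE, ("TP53 protein", "tumor protein p53")),
            Concept("C0002", "GBA", EntityType.GENE, ("glucocerebrosidase",)),
            Concept("C0003", "breast cancer", EntityType.DISEASE, ("breast carcinoma",)),
            Concept("C0004", "Gaucher disease", EntityType.DISEASE, ()),
            Concept("C0005", "osteoporosis", EntityType.DISEASE, ()),
            Concept("C0006", "denosumab", EntityType.DRUG, ()),
            Concept("C0007", "osteoclast", EntityType.CELL_TYPE, ("osteoclasts",)),
        ]
    )


@pytest.fixture
def three_sentence_fixture() -> list[SentenceRecord]:
    """s1{g1,d1}, s2{g1,d1,d2}, s3{g2}: the hand-enumerated counting example."""
    G, D = EntityType.GENE, EntityType.DISEASE
    return [
        make_sentence("doc1", 0, [("g1", G), ("d1", D)]),
        make_sentence("doc1", 1, [("g1", G), ("d1", D), ("d2", D)]),
        make_sentence("doc2", 0, [("g2", G)]),
    ]
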