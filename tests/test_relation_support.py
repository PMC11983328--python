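import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litmine.corpus import SentenceRecord
from litmine.relations import (
    DISEASE_TOKEN,
    GENE_TOKEN,
    KeywordRuleClassifier,
    RelationLabel,
    SentenceLabel,
    aggregate_label_percentages,
    classify_sentences,
    mask_entities,
    unmask,
)
from litmine.cooccur import PairKey
from litmine.vocab import EntityType, Mention

G, D = EntityType.GENE, EntityType.DISEASE


def sentence_with_mentions(text, spans):
    mentions = [
        Mention(start=s, end=e, surface=text[s:e], entity_type=t, cui=cui, link_score=1.0)
        for s, e, t, cui in spans
    ]
    return SentenceRecord(
        doc_id="d", sent_index=0, start=0, end=len(text), text=text, mentions=mentions
    )


class TestMasking:
    def test_dummy_token_convention(self):
        text = "BRCA1 increases risk of breast cancer."
        sent = sentence_with_mentions(
            text, [(0, 5, G, "Cg"), (24, 37, D, "Cd")]
        )
        masked = mask_entities(sent, sent.mentions[0], sent.mentions[1])
        assert masked.text == f"{GENE_TOKEN} increases risk of {DISEASE_TOKEN}."

    def test_repeated_surfaces_all_masked(self):
        text = "BRCA1 and BRCA1 both worsen lupus."
        sent = sentence_with_mentions(
            text, [(0, 5, G, "Cg"), (10, 15, G, "Cg"), (28, 33, D, "Cd")]
        )
        masked = mask_entities(sent, sent.mentions[0], sent.mentions[2])
        assert masked.text == f"{GENE_TOKEN} and {GENE_TOKEN} both worsen {DISEASE_TOKEN}."

    def test_round_trip_identity(self):
        text = "BRCA1 increases risk of breast cancer."
        sent = sentence_with_mentions(text, [(0, 5, G, "Cg"), (24, 37, D, "Cd")])
        masked = mask_entities(sent, sent.mentions[0], sent.mentions[1])
        assert unmask(masked) == text

    def test_overlapping_spans_rejected(self):
        text = "BRCA1-related cancer."
        sent = sentence_with_mentions(text, [(0, 5, G, "Cg"), (3, 20, D, "Cd")])
        with pytest.raises(ValueError, match="overlap"):
            mask_entities(sent, sent.mentions[0], sent.mentions[1])

    def test_out_of_bounds_span_rejected(self):
        text = "short."
        sent = sentence_with_mentions(text, [(0, 5, G, "Cg")])
        bad = Mention(start=10, end=20, surface="x", entity_type=D, cui="Cd", link_score=1.0)
        with pytest.raises(ValueError, match="bounds"):
            mask_entities(sent, sent.mentions[0], bad)

    @given(
        st.text(alphabet="abcdef ", min_size=1, max_size=10),
        st.text(alphabet="ghijkl ", min_size=1, max_size=10),
        st.text(alphabet="mnopqr ", min_size=1, max_size=10),
    )
    @settings(max_examples=60, deadline=None)
    def test_round_trip_on_random_contexts(self, left, mid, right):
        gene, disease = "XY1", "qfever"
        text = f"{left}{gene}{mid} {disease}{right}"
        gstart = len(left)
        dstart = len(left) + len(gene) + len(mid) + 1
        sent = sentence_with_mentions(
            text,
            [(gstart, gstart + len(gene), G, "Cg"), (dstart, dstart + len(disease), D, "Cd")],
        )
        masked = mask_entities(sent, sent.mentions[0], sent.mentions[1])
        assert unmask(masked) == text


class TestClassifierContract:
    def test_empty_input(self):
        assert classify_sentences([], KeywordRuleClassifier()) == []

    def test_constant_classifier(self):
        text = "BRCA1 causes cancer."
        sent = sentence_with_mentions(text, [(0, 5, G, "Cg"), (13, 19, D, "Cd")])
        masked = [mask_entities(sent, sent.mentions[0], sent.mentions[1])] * 3
        labels = classify_sentences(masked, lambda _: RelationLabel.PLAYS_A_ROLE)
        assert [l.label for l in labels] == [RelationLabel.PLAYS_A_ROLE] * 3

    def test_out_of_taxonomy_label_rejected(self):
        text = "BRCA1 causes cancer."
        sent = sentence_with_mentions(text, [(0, 5, G, "Cg"), (13, 19, D, "Cd")])
        masked = [mask_entities(sent, sent.mentions[0], sent.mentions[1])]
        with pytest.raises(ValueError, match="out-of-taxonomy"):
            classify_sentences(masked, lambda _: "WEIRD")

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("$gene is a biomarker for $disease", RelationLabel.BIOMARKER),
            ("$gene causes $disease when mutated", RelationLabel.TARGET_CAUSATIVE),
            ("$gene alleviates $disease", RelationLabel.TARGET_MODULATOR_DECREASE),
            ("$gene worsens $disease", RelationLabel.TARGET_MODULATOR_INCREASE),
            ("$gene is a target for $disease", RelationLabel.TARGET_GENERAL),
            ("$gene is associated with $disease", RelationLabel.PLAYS_A_ROLE),
            ("$gene and $disease appear here", RelationLabel.NO_EXPLICIT_RELATIONSHIP),
        ],
    )
    def test_baseline_rule_table(self, text, expected):
        assert KeywordRuleClassifier()(text) == expected

    def test_taxonomy_serialization_bijective(self):
        assert len(RelationLabel) == 7
        for label in RelationLabel:
            assert RelationLabel(label.value) is label


def _labels(gene, counts, disease="Cd"):
    out = []
    i = 0
    for label, n in counts.items():
        for _ in range(n):
            out.append(
                SentenceLabel("doc", i, PairKey(G, D, gene, disease), label)
            )
            i += 1
    return out


class TestAggregation:
    def test_percentage_row_pattern(self):
        # 26/4/35 of 65 sentences -> 40.0 / 6.2 / 53.8
        labels = _labels(
            "Cg1",
            {
                RelationLabel.PLAYS_A_ROLE: 26,
                RelationLabel.TARGET_GENERAL: 4,
                RelationLabel.TARGET_CAUSATIVE: 35,
            },
        )
        table = aggregate_label_percentages(labels, min_sentences=50)
        row = table.loc["Cg1"]
        assert row["PLAYS_A_ROLE"] == 40.0
        assert row["TARGET_GENERAL"] == 6.2
        assert row["TARGET_CAUSATIVE"] == 53.8
        assert row["sentence_count"] == 65

    def test_threshold_excludes_sparse_genes(self):
        labels = _labels("Cg1", {RelationLabel.PLAYS_A_ROLE: 49})
        assert aggregate_label_percentages(labels, min_sentences=50).empty

    def test_rows_sorted_by_count_and_sum_to_100(self):
        labels = (
            _labels("CgA", {RelationLabel.PLAYS_A_ROLE: 40, RelationLabel.BIOMARKER: 23})
            + _labels("CgB", {RelationLabel.TARGET_GENERAL: 33, RelationLabel.TARGET_CAUSATIVE: 19, RelationLabel.PLAYS_A_ROLE: 103})
        )
        table = aggregate_label_percentages(labels, min_sentences=50)
        assert list(table.index) == ["CgB", "CgA"]
        sums = table.drop(columns="sentence_count").sum(axis=1)
        assert ((sums - 100).abs() <= 0.4).all()

    def test_multiple_diseases_rejected(self):
        labels = _labels("Cg1", {RelationLabel.PLAYS_A_ROLE: 1}) + _labels(
            "Cg1", {RelationLabel.PLAYS_A_ROLE: 1}, disease="Cd2"
        )
        with pytest.raises(ValueError, match="several diseases"):
            aggregate_label_percentages(labels, min_sentences=1)
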