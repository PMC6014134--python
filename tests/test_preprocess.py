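"""Sentence splitting, candidate generation, anonymization, filtering,
vocabulary."""

import pytest

from chemrel.corpus import AbstractRecord, EntityMention, GoldRelation
from chemrel.preprocess import (
    RARE_TOKEN,
    anonymize_challenge,
    anonymize_postchallenge,
    build_vocab,
    filter_instances,
    generate_candidates,
    prepare_instances,
    split_sentences,
)


def _mk(title, body, entities):
    """Build (abstract, mentions) with offsets into title + tab + body."""
    record = AbstractRecord("1", title, body)
    text = record.text()
    mentions = []
    for i, (surface, etype) in enumerate(entities, start=1):
        start = text.index(surface)
        mentions.append(EntityMention("1", f"T{i}", etype, start,
                                      start + len(surface), surface))
    return record, mentions


class TestSplitSentences:
    def test_two_plain_sentences(self):
        record, _ = _mk("A title", "First one. Second one.", [])
        sents = [s for s in split_sentences(record, [])]
        assert [s.text for s in sents] == ["A title", "First one.", "Second one."]

    def test_spans_tile_document(self):
        record, _ = _mk("T", "Alpha beta. Gamma delta. Epsilon.", [])
        sents = split_sentences(record, [])
        text = record.text()
        for s in sents:
            assert text[s.start:s.end] == s.text

    def test_boundary_never_cuts_a_mention(self):
        # naive period splitting would cut inside "S. aureus gene"
        record, mentions = _mk("T", "Binding of the S. aureus gene was seen.",
                               [("S. aureus gene", "GENE")])
        sents = split_sentences(record, mentions)
        hosting = [s for s in sents if s.mentions]
        assert len(hosting) == 1
        assert "S. aureus gene" in hosting[0].text

    def test_empty_body_keeps_title_sentence(self):
        record = AbstractRecord("1", "Only a title", "")
        sents = split_sentences(record, [])
        assert sents[0].text == "Only a title"

    def test_all_generated_mentions_land_in_one_sentence(self, small_corpus):
        sc = small_corpus
        for abstract in sc.abstracts:
            sents = split_sentences(abstract, sc.entities)
            placed = sum(len(s.mentions) for s in sents)
            expected = sum(1 for m in sc.entities if m.pmid == abstract.pmid)
            assert placed == expected


class TestGenerateCandidates:
    def test_pair_enumeration_matches_product(self):
        record, mentions = _mk(
            "T", "aspirin and caffeine bind TrkA here.",
            [("aspirin", "CHEMICAL"), ("caffeine", "CHEMICAL"), ("TrkA", "GENE")])
        (sent,) = [s for s in split_sentences(record, mentions) if s.mentions]
        insts = generate_candidates(sent, [])
        assert len(insts) == 2  # 2 chemicals x 1 gene
        assert all(i.label == "False" for i in insts)

    def test_single_entity_yields_nothing(self):
        record, mentions = _mk("T", "aspirin was given.", [("aspirin", "CHEMICAL")])
        (sent,) = [s for s in split_sentences(record, mentions) if s.mentions]
        assert generate_candidates(sent, []) == []

    def test_gold_label_attached(self):
        record, mentions = _mk("T", "aspirin inhibits TrkA today.",
                               [("aspirin", "CHEMICAL"), ("TrkA", "GENE")])
        (sent,) = [s for s in split_sentences(record, mentions) if s.mentions]
        gold = [GoldRelation("1", "CPR:4", "T1", "T2")]
        (inst,) = generate_candidates(sent, gold)
        assert inst.label == "CPR:4"

    def test_candidate_count_equals_chem_times_gene(self, small_corpus):
        sc = small_corpus
        for abstract in sc.abstracts:
            for sent in split_sentences(abstract, sc.entities):
                n_chem = sum(1 for m, *_ in sent.mentions if m.etype == "CHEMICAL")
                n_gene = sum(1 for m, *_ in sent.mentions if m.etype == "GENE")
                assert len(generate_candidates(sent, sc.relations)) == n_chem * n_gene


class TestAnonymize:
    def _instance(self, body, entities, gold=()):
        record, mentions = _mk("T", body, entities)
        (sent,) = [s for s in split_sentences(record, mentions) if s.mentions]
        return generate_candidates(sent, list(gold))[0]

    def test_challenge_placeholders_by_appearance(self):
        inst = self._instance(
            "Amitriptyline promotes TrkA autophosphorylation.",
            [("Amitriptyline", "CHEMICAL"), ("TrkA", "GENE")])
        out = anonymize_challenge(inst)
        assert out.tokens[:4] == ["BC6ENT1", "promotes", "BC6ENT2",
                                  "autophosphorylation"]
        assert (out.e1_index, out.e2_index) == (0, 2)

    def test_multi_token_entity_collapses(self):
        inst = self._instance(
            "zinc chloride blocks histone deacetylase strongly.",
            [("zinc chloride", "CHEMICAL"), ("histone deacetylase", "GENE")])
        out = anonymize_challenge(inst)
        assert out.tokens.count("BC6ENT1") == 1
        assert out.tokens.count("BC6ENT2") == 1
        # 2-token and 2-token entities collapse: 3 fewer tokens than naive
        assert out.tokens == ["BC6ENT1", "blocks", "BC6ENT2", "strongly", "."]

    def test_chem_lexicon_substitution(self):
        inst = self._instance(
            "aspirin blocks TrkA unlike caffeine here.",
            [("aspirin", "CHEMICAL"), ("TrkA", "GENE")])
        out = anonymize_challenge(inst, chem_lexicon={"caffeine"})
        assert "CHEM" in out.tokens
        out2 = anonymize_challenge(inst)
        assert "CHEM" not in out2.tokens

    def test_postchallenge_marks_bystanders(self):
        inst = self._instance(
            "zinc blocks histone deacetylase and HDAC too.",
            [("zinc", "CHEMICAL"), ("histone deacetylase", "GENE"),
             ("HDAC", "GENE")])
        out = anonymize_postchallenge(inst)
        assert "BC6ENTC" in out.tokens
        assert "BC6ENTG" in out.tokens
        assert "BC6OTHER" in out.tokens

    def test_postchallenge_no_bystanders_two_substitutions(self):
        inst = self._instance("zinc blocks TrkA now.",
                              [("zinc", "CHEMICAL"), ("TrkA", "GENE")])
        out = anonymize_postchallenge(inst)
        placeholders = [t for t in out.tokens if t.startswith("BC6")]
        assert placeholders == ["BC6ENTC", "BC6ENTG"]

    def test_idempotent(self):
        inst = self._instance("zinc blocks TrkA now.",
                              [("zinc", "CHEMICAL"), ("TrkA", "GENE")])
        once = anonymize_postchallenge(inst)
        twice = anonymize_postchallenge(once)
        assert once.tokens == twice.tokens


class TestFilters:
    def test_confusing_pair_removed(self):
        record, mentions = _mk("T", "aspirin modulates TrkA today.",
                               [("aspirin", "CHEMICAL"), ("TrkA", "GENE")])
        (sent,) = [s for s in split_sentences(record, mentions) if s.mentions]
        gold = [GoldRelation("1", "CPR:3", "T1", "T2"),
                GoldRelation("1", "CPR:4", "T1", "T2")]
        insts = generate_candidates(sent, gold)
        kept, overlap, confusing = filter_instances(insts)
        assert kept == [] and overlap == []
        assert len(confusing) == 1

    def test_nested_spans_removed_as_overlap(self):
        # gene surface contains the chemical surface
        record, mentions = _mk("T", "the zinc finger protein binds it.",
                               [("zinc", "CHEMICAL"),
                                ("zinc finger protein", "GENE")])
        (sent,) = [s for s in split_sentences(record, mentions) if s.mentions]
        insts = generate_candidates(sent, [])
        kept, overlap, confusing = filter_instances(insts)
        assert len(overlap) == 1 and not kept and not confusing

    def test_counts_partition_input(self, small_corpus):
        sc = small_corpus
        insts, stats = prepare_instances(sc.abstracts, sc.entities, sc.relations)
        assert (stats["kept"] + stats["removed_overlap"]
                + stats["removed_confusing"]) == stats["total"]


class TestVocabulary:
    def test_below_min_count_maps_to_rare(self):
        vocab = build_vocab(["a", "a", "b", "b", "b"], min_count=3)
        assert vocab.canonical("a") == RARE_TOKEN
        assert vocab.canonical("b") == "b"

    def test_frequency_exactly_at_threshold_kept(self):
        vocab = build_vocab(["x"] * 3 + ["y"] * 2, min_count=3)
        assert vocab.canonical("x") == "x"
        assert vocab.canonical("y") == RARE_TOKEN

    def test_min_count_one_keeps_everything(self):
        tokens = ["q", "r", "s"]
        vocab = build_vocab(tokens, min_count=1)
        assert all(vocab.canonical(t) == t for t in tokens)

    def test_placeholders_always_kept(self):
        vocab = build_vocab(["BC6ENTC", "filler", "filler", "filler"],
                            min_count=3)
        assert vocab.canonical("BC6ENTC") == "BC6ENTC"

    def test_deterministic_lexicographic_indexing(self):
        v1 = build_vocab(["b", "a", "a", "b", "c", "c"], min_count=2)
        v2 = build_vocab(["c", "c", "b", "b", "a", "a"], min_count=2)
        assert v1.index == v2.index


def test_gold_relation_in_sentence_becomes_one_instance(small_corpus):
    """Every same-sentence gold relation surfaces as exactly one labeled
    instance before filtering; cross-sentence gold yields none."""
    sc = small_corpus
    insts, _ = prepare_instances(sc.abstracts, sc.entities, sc.relations,
                                 apply_filters=False)
    labeled = {(i.pmid, i.chem_id, i.gene_id) for i in insts if i.label != "False"}
    # find which gold relations are same-sentence
    same_sentence = set()
    for abstract in sc.abstracts:
        for sent in split_sentences(abstract, sc.entities):
            ids = {m.mention_id for m, *_ in sent.mentions}
            for r in sc.relations:
                if r.pmid == abstract.pmid and {r.chem_id, r.gene_id} <= ids:
                    same_sentence.add((r.pmid, r.chem_id, r.gene_id))
    assert labeled == same_sentence
    assert len(same_sentence) < len(sc.relations)  # some gold is cross-sentence
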