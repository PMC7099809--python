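"""Tag decoding, bidirectional confirmation, intra/inter split, scoring."""

import numpy as np
import pytest

from docrel.corpus_io import CHEMICAL, DISEASE
from docrel.decoder_eval import (DirectedFinding, RelationPrediction,
                                 confirm_pairs, decode_document,
                                 decode_targets, evaluate, prf,
                                 read_predictions, split_intra_inter,
                                 write_predictions)
from docrel.instance_builder import build_instances
from docrel.synthetic_corpus import GenConfig, generate
from tests.conftest import make_doc


@pytest.fixture(scope="module")
def coord_instances(coordination_doc):
    return {i.source_concept_id: i
            for i in build_instances(coordination_doc)}


class TestDecodeTargets:
    def test_coordinated_prediction(self, coord_instances):
        inst = coord_instances["D007333"]  # source: the disease
        # predict the gold tags themselves
        findings = decode_targets(inst, inst.gold_tags)
        assert {(f.source_concept_id, f.target_concept_id)
                for f in findings} == \
            {("D007333", "D003024"), ("D007333", "C076029")}

    def test_no_target_tags_empty(self, coord_instances):
        inst = coord_instances["D007333"]
        assert decode_targets(inst, inst.types) == set()

    def test_concept_level_dedup(self):
        doc = make_doc(
            "1", "T.",
            "Aspirin helped. Aspirin hurt. Aspirin was stopped. "
            "Headache occurred.",
            entities=[("Aspirin", "C1", CHEMICAL),
                      ("Headache", "D1", DISEASE)],
            relations=[("C1", "D1")])
        inst = {i.source_concept_id: i for i in build_instances(doc)}["D1"]
        tags = list(inst.types)
        hit = [i for i, cids in enumerate(inst.token_concept_ids)
               if "C1" in cids]
        assert len(hit) == 3
        tags[hit[0]] = "T-Che"  # only ONE of the three mentions tagged
        findings = decode_targets(inst, tags)
        assert len(findings) == 1

    def test_length_mismatch_raises(self, coord_instances):
        inst = coord_instances["D007333"]
        with pytest.raises(ValueError):
            decode_targets(inst, inst.gold_tags[:-1])


class TestConfirmPairs:
    TYPES = {"C1": CHEMICAL, "D1": DISEASE}

    def f(self, src, tgt, ttype):
        return DirectedFinding("doc", src, tgt, ttype)

    def test_both_directions_confirm(self):
        findings = {self.f("C1", "D1", DISEASE), self.f("D1", "C1", CHEMICAL)}
        assert confirm_pairs(findings, self.TYPES) == \
            {RelationPrediction("doc", "C1", "D1")}

    def test_single_direction_not_emitted(self):
        findings = {self.f("C1", "D1", DISEASE)}
        assert confirm_pairs(findings, self.TYPES) == set()
        assert confirm_pairs(findings, self.TYPES, mode="union") == \
            {RelationPrediction("doc", "C1", "D1")}

    def test_random_sets_match_intersection_oracle(self, rng):
        chems = [f"C{i}" for i in range(5)]
        diss = [f"D{i}" for i in range(5)]
        types = {c: CHEMICAL for c in chems} | {d: DISEASE for d in diss}
        for _ in range(20):
            fwd = {(c, d) for c in chems for d in diss if rng.random() < 0.3}
            bwd = {(c, d) for c in chems for d in diss if rng.random() < 0.3}
            findings = {self.f(c, d, DISEASE) for c, d in fwd} | \
                       {self.f(d, c, CHEMICAL) for c, d in bwd}
            got = confirm_pairs(findings, types)
            expect = {RelationPrediction("doc", c, d) for c, d in fwd & bwd}
            assert got == expect

    def test_order_invariance(self, coordination_doc):
        insts = build_instances(coordination_doc)
        tags = [i.gold_tags for i in insts]
        a = decode_document(insts, tags)
        b = decode_document(list(reversed(insts)), list(reversed(tags)))
        assert a == b


class TestIntraInterSplit:
    def test_same_sentence_intra(self):
        doc = make_doc("1", "T.", "Aspirin caused headache.",
                       entities=[("Aspirin", "C1", CHEMICAL),
                                 ("headache", "D1", DISEASE)])
        intra, inter = split_intra_inter(doc, {("C1", "D1")})
        assert intra == {("C1", "D1")} and inter == set()

    def test_different_sentences_inter(self):
        doc = make_doc("1", "T.", "Aspirin was given. Headache followed.",
                       entities=[("Aspirin", "C1", CHEMICAL),
                                 ("Headache", "D1", DISEASE)])
        intra, inter = split_intra_inter(doc, {("C1", "D1")})
        assert inter == {("C1", "D1")} and intra == set()

    def test_unknown_concept_raises(self):
        doc = make_doc("1", "T.", "Nothing here.", [])
        with pytest.raises(KeyError):
            split_intra_inter(doc, {("C9", "D9")})

    def test_zero_inter_fraction_generator(self):
        docs = generate(GenConfig(n_docs=100, seed=7,
                                  inter_sentential_fraction=0.0))
        for doc in docs:
            pairs = {(r.chemical_id, r.disease_id) for r in doc.relations}
            intra, inter = split_intra_inter(doc, pairs)
            assert inter == set()
            assert intra == pairs

    def test_partition_property(self, small_corpus):
        for doc in small_corpus:
            pairs = {(r.chemical_id, r.disease_id) for r in doc.relations}
            intra, inter = split_intra_inter(doc, pairs)
            assert intra | inter == pairs
            assert intra & inter == set()


class TestEvaluate:
    def test_perfect_predictions(self, small_corpus):
        preds = {RelationPrediction(d.doc_id, r.chemical_id, r.disease_id)
                 for d in small_corpus for r in d.relations}
        report = evaluate(preds, small_corpus)
        assert report.precision == report.recall == report.f1 == 1.0
        assert report.intra.f1 == 1.0 and report.inter.f1 == 1.0

    def test_no_predictions(self, small_corpus):
        report = evaluate(set(), small_corpus)
        assert report.precision == 0.0
        assert report.recall == 0.0
        assert report.f1 == 0.0

    def test_printed_arithmetic_f1(self):
        # counts engineered so P = 0.600 and R = 0.675 exactly
        p, r, f1 = prf(tp=27, fp=18, fn=13)
        assert p == pytest.approx(0.600, abs=1e-12)
        assert r == pytest.approx(0.675, abs=1e-12)
        assert round(f1, 3) == 0.635

    def test_counts_route_through_pair_sets(self):
        """The same P/R/F1 arises from explicit prediction/gold pair sets."""
        docs, preds = [], set()
        for i in range(40):
            did = str(i)
            gold = [("C1", "D1")]
            pred = []
            if i < 27:
                pred = [("C1", "D1")]          # TP
            if i < 13:
                pred.append(("C2", "D2"))       # FP (13 of them)
            if 27 <= i < 32:
                pred = [("C2", "D2")]           # 5 more FPs; gold missed
            doc = make_doc(
                did, "T.",
                "alphaxin caused betaosis. gammaxin was seen near deltaoma.",
                entities=[("alphaxin", "C1", CHEMICAL),
                          ("betaosis", "D1", DISEASE),
                          ("gammaxin", "C2", CHEMICAL),
                          ("deltaoma", "D2", DISEASE)],
                relations=gold)
            docs.append(doc)
            preds |= {RelationPrediction(did, c, d) for c, d in pred}
        report = evaluate(preds, docs)
        assert report.overall.tp == 27
        assert report.overall.fp == 18
        assert report.overall.fn == 13
        assert report.precision == pytest.approx(0.600, abs=1e-12)
        assert report.recall == pytest.approx(0.675, abs=1e-12)
        assert round(report.f1, 3) == 0.635

    def test_false_positive_level_assignment(self):
        doc = make_doc(
            "1", "T.", "alphaxin was given. betaosis followed later.",
            entities=[("alphaxin", "C1", CHEMICAL),
                      ("betaosis", "D1", DISEASE)],
            relations=[])
        preds = {RelationPrediction("1", "C1", "D1")}
        report = evaluate(preds, [doc])
        # the unmatched prediction is inter-sentential by co-occurrence
        assert report.inter.fp == 1 and report.intra.fp == 0

    def test_unknown_document_raises(self):
        with pytest.raises(KeyError):
            evaluate({RelationPrediction("zzz", "C", "D")}, [])


def test_predictions_tsv_round_trip(tmp_path):
    preds = {RelationPrediction("10", "C1", "D1"),
             RelationPrediction("11", "C2", "D9")}
    p = tmp_path / "preds.tsv"
    write_predictions(preds, p)
    assert read_predictions(p) == preds
    lines = p.read_text().splitlines()
    assert all(len(l.split("\t")) == 4 and l.split("\t")[1] == "CID"
               for l in lines)
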