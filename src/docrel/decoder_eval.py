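"""From tag sequences to confirmed relation pairs, and their evaluation.

Decoding is concept-level: in the instance for source concept *c*, any
concept one of whose mention tokens is tagged ``T-Che``/``T-Dis`` (matching
its entity type) is a *directed finding* ``c -> target``.  A
chemical-disease pair is emitted only when confirmed **bidirectionally**:
the disease must be found a target when the chemical is the source, and the
chemical a target when the disease is the source.

Evaluation is micro-averaged precision / recall / F1 over all documents,
with F1 = 2PR/(P+R).  Pairs are additionally split by sentential status: a
pair is *intra-sentential* iff at least one sentence contains a mention of
each of its concepts, otherwise *inter-sentential*; both gold and predicted
pairs are assigned a level by that same co-occurrence rule, so level-wise
precision is defined for unmatched predictions too.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .corpus_io import CHEMICAL, DISEASE, DocumentRecord, Sentence, split_sentences
from .instance_builder import LabeledInstance

_TYPE_OF_T_TAG = {"T-Che": CHEMICAL, "T-Dis": DISEASE}


@dataclass(frozen=True)
class DirectedFinding:
    doc_id: str
    source_concept_id: str
    target_concept_id: str
    target_entity_type: str


@dataclass(frozen=True)
class RelationPrediction:
    doc_id: str
    chemical_id: str
    disease_id: str


def decode_targets(instance: LabeledInstance,
                   predicted_tags: list[str]) -> set[DirectedFinding]:
    """Directed findings for one instance from its predicted tag sequence.

    A concept is a target iff ANY of its mention tokens carries a ``T-*``
    tag matching the concept's entity type; multiple tagged mentions of the
    same concept collapse to a single finding.  Self-findings are never
    produced.
    """
    if len(predicted_tags) != len(instance.tokens):
        raise ValueError("tag sequence length does not match instance")
    findings = set()
    for tag, cids, etype in zip(predicted_tags, instance.token_concept_ids,
                                instance.token_entity_types):
        want = _TYPE_OF_T_TAG.get(tag)
        if want is None or not cids or etype != want:
            continue
        for cid in cids:
            if cid != instance.source_concept_id:
                findings.add(DirectedFinding(
                    doc_id=instance.doc_id,
                    source_concept_id=instance.source_concept_id,
                    target_concept_id=cid, target_entity_type=want))
    return findings


def confirm_pairs(findings: set[DirectedFinding] | list[DirectedFinding],
                  source_types: dict[str, str],
                  mode: str = "intersection") -> set[RelationPrediction]:
    """Merge directed findings of one document into undirected CD pairs.

    ``source_types`` maps each source concept to its entity type.  In the
    default ``intersection`` mode a (chemical, disease) pair is emitted iff
    both directions were found; ``union`` (an ablation) emits a pair when
    either direction was found.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown confirmation mode {mode!r}")
    chem_to_dis = set()   # found with a chemical source
    dis_to_chem = set()   # found with a disease source
    for f in findings:
        stype = source_types[f.source_concept_id]
        if stype == CHEMICAL and f.target_entity_type == DISEASE:
            chem_to_dis.add((f.doc_id, f.source_concept_id,
                             f.target_concept_id))
        elif stype == DISEASE and f.target_entity_type == CHEMICAL:
            dis_to_chem.add((f.doc_id, f.target_concept_id,
                             f.source_concept_id))
    merged = (chem_to_dis & dis_to_chem if mode == "intersection"
              else chem_to_dis | dis_to_chem)
    return {RelationPrediction(doc_id=d, chemical_id=c, disease_id=s)
            for d, c, s in merged}


def decode_document(instances: list[LabeledInstance],
                    tag_sequences: list[list[str]],
                    mode: str = "intersection") -> set[RelationPrediction]:
    """Decode + confirm over all instances of one document."""
    findings: set[DirectedFinding] = set()
    source_types: dict[str, str] = {}
    for inst, tags in zip(instances, tag_sequences):
        source_types[inst.source_concept_id] = inst.source_entity_type
        findings |= decode_targets(inst, tags)
    return confirm_pairs(findings, source_types, mode=mode)


# ---------------------------------------------------------------------------
# Intra / inter split and scoring
# ---------------------------------------------------------------------------

def split_intra_inter(doc: DocumentRecord,
                      pairs: set[tuple[str, str]],
                      sentences: list[Sentence] | None = None):
    """Partition (chemical, disease) pairs by sentence co-occurrence.

    A pair is intra-sentential iff some sentence contains at least one
    mention of each concept.  Raises ``KeyError`` if a pair names a concept
    with no mention in the document.
    """
    if sentences is None:
        sentences = split_sentences(doc)
    present = doc.concept_ids()
    per_sentence: list[set[str]] = []
    for sent in sentences:
        per_sentence.append({m.concept_id for m in doc.mentions
                             if sent.start <= m.start and m.end <= sent.end})
    intra, inter = set(), set()
    for chem, dis in pairs:
        if chem not in present or dis not in present:
            raise KeyError(f"document {doc.doc_id}: pair ({chem}, {dis}) "
                           f"references an unmentioned concept")
        if any(chem in s and dis in s for s in per_sentence):
            intra.add((chem, dis))
        else:
            inter.add((chem, dis))
    return intra, inter


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Micro precision, recall and F1 = 2PR/(P+R) from raw counts."""
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


@dataclass
class LevelScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return prf(self.tp, self.fp, self.fn)[0]

    @property
    def recall(self) -> float:
        return prf(self.tp, self.fp, self.fn)[1]

    @property
    def f1(self) -> float:
        return prf(self.tp, self.fp, self.fn)[2]

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


@dataclass
class EvalReport:
    overall: LevelScores = field(default_factory=LevelScores)
    intra: LevelScores = field(default_factory=LevelScores)
    inter: LevelScores = field(default_factory=LevelScores)

    @property
    def precision(self) -> float:
        return self.overall.precision

    @property
    def recall(self) -> float:
        return self.overall.recall

    @property
    def f1(self) -> float:
        return self.overall.f1

    def as_dict(self) -> dict:
        return {"overall": self.overall.as_dict(),
                "intra": self.intra.as_dict(),
                "inter": self.inter.as_dict()}

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def pretty(self) -> str:
        rows = [("overall", self.overall), ("intra", self.intra),
                ("inter", self.inter)]
        lines = [f"{'level':8s} {'P':>7s} {'R':>7s} {'F1':>7s} "
                 f"{'TP':>5s} {'FP':>5s} {'FN':>5s}"]
        for name, s in rows:
            lines.append(f"{name:8s} {s.precision:7.3f} {s.recall:7.3f} "
                         f"{s.f1:7.3f} {s.tp:5d} {s.fp:5d} {s.fn:5d}")
        return "\n".join(lines)


def evaluate(predictions: set[RelationPrediction] | list[RelationPrediction],
             docs: list[DocumentRecord],
             macro: bool = False) -> EvalReport:
    """Score predictions against the documents' gold relation annotations.

    Micro-averaged by default (counts pooled over the corpus); ``macro``
    averages per-document P/R/F1 instead (reported in the overall level
    only).  Every pair — predicted or gold — is assigned intra/inter status
    by the sentence co-occurrence rule on its document.

    Raises ``KeyError`` when a prediction names an unknown document.
    """
    by_doc: dict[str, DocumentRecord] = {d.doc_id: d for d in docs}
    pred_by_doc: dict[str, set[tuple[str, str]]] = {d.doc_id: set()
                                                    for d in docs}
    for p in predictions:
        if p.doc_id not in by_doc:
            raise KeyError(f"prediction for unknown document {p.doc_id}")
        pred_by_doc[p.doc_id].add((p.chemical_id, p.disease_id))

    report = EvalReport()
    per_doc_f1: list[tuple[float, float, float]] = []
    for doc in docs:
        gold = {(r.chemical_id, r.disease_id) for r in doc.relations}
        pred = pred_by_doc[doc.doc_id]
        sentences = split_sentences(doc)
        intra_all, _ = split_intra_inter(doc, gold | pred, sentences)

        tp_pairs = gold & pred
        fp_pairs = pred - gold
        fn_pairs = gold - pred
        report.overall.tp += len(tp_pairs)
        report.overall.fp += len(fp_pairs)
        report.overall.fn += len(fn_pairs)
        for pairset, attr in ((tp_pairs, "tp"), (fp_pairs, "fp"),
                              (fn_pairs, "fn")):
            for pair in pairset:
                level = report.intra if pair in intra_all else report.inter
                setattr(level, attr, getattr(level, attr) + 1)
        if macro:
            per_doc_f1.append(prf(len(tp_pairs), len(fp_pairs), len(fn_pairs)))
    if macro:
        n = len(per_doc_f1) or 1
        p = sum(x[0] for x in per_doc_f1) / n
        r = sum(x[1] for x in per_doc_f1) / n
        f = sum(x[2] for x in per_doc_f1) / n
        report.macro = {"precision": p, "recall": r, "f1": f}  # type: ignore
    return report


def write_predictions(predictions, path) -> None:
    """Write predictions as TSV lines ``doc_id  CID  chem_id  dis_id``."""
    rows = sorted((p.doc_id, p.chemical_id, p.disease_id)
                  for p in predictions)
    with open(path, "w", encoding="utf-8") as fh:
        for d, c, s in rows:
            fh.write(f"{d}\tCID\t{c}\t{s}\n")


def read_predictions(path) -> set[RelationPrediction]:
    out = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4 or parts[1] != "CID":
                raise ValueError(f"line {lineno}: malformed prediction line")
            out.add(RelationPrediction(doc_id=parts[0], chemical_id=parts[2],
                                       disease_id=parts[3]))
    return out
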