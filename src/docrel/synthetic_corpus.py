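"""Seeded generator of PubTator-format corpora with controllable structure.

The generator emits title+abstract documents with chemical and disease
mentions (MeSH-style concept IDs, exact character offsets) and
document-level relation annotations, built from natural-ish cue templates
so that a small tagger can actually learn them:

* intra-sentential relations: ``"<chem> induced <dis> in 12 patients."``;
* coordination: ``"<chem1> and <chem2> induced <dis>."`` — two relations
  expressed jointly, exercising interactions between relations;
* inter-sentential relations: the chemical and the disease are placed in
  *different, adjacent* sentences bridged by a coreference-like phrase
  (``"Patients received <chem> ..." / "<dis> developed after this
  treatment."``), and the two concepts never co-occur in any sentence;
* distractor entities in neutral sentences, including negative
  co-occurrence sentences pairing two unrelated concepts.

Each relation is inter-sentential independently with probability
``inter_sentential_fraction`` (default 1/3, the proportion typical of
document-level chemical-disease corpora).  Output is fully deterministic
given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import (CHEMICAL, DISEASE, DocumentRecord, EntityMention,
                        RelationAnnotation)


@dataclass
class GenConfig:
    n_docs: int = 100
    #: inclusive range of entity concepts per document (chems + diseases)
    entities_per_doc: tuple[int, int] = (4, 6)
    #: inclusive range of relations per document
    relations_per_doc: tuple[int, int] = (1, 3)
    #: per-relation probability of being realized inter-sententially
    inter_sentential_fraction: float = 0.33
    #: probability that an intra relation is coordinated with a second
    #: chemical in the same sentence ("X and Y induced Z")
    coordination_prob: float = 0.3
    #: probability of adding a negative co-occurrence sentence (two
    #: unrelated distractor concepts in one sentence)
    distractor_cooccur_prob: float = 0.3
    #: probability of re-mentioning a related concept in a neutral sentence
    repeat_mention_prob: float = 0.2
    #: number of distinct chemical and disease concepts in the shared pool
    vocab_size: int = 40
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.entities_per_doc
        rlo, rhi = self.relations_per_doc
        if not (1 <= lo <= hi):
            raise ValueError("entities_per_doc must be a positive range")
        if not (0 <= rlo <= rhi):
            raise ValueError("relations_per_doc must be a valid range")
        for name in ("inter_sentential_fraction", "coordination_prob",
                     "distractor_cooccur_prob", "repeat_mention_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.vocab_size < hi:
            raise ValueError("vocab_size smaller than entities_per_doc")
        # every relation consumes a distinct chemical, and distractors draw
        # from the same per-document sample of the pool
        if self.vocab_size < rhi + hi:
            raise ValueError(
                "vocab_size too small for relations_per_doc plus "
                "entities_per_doc (infeasible configuration)")


_SYLLABLES = ["ba", "do", "fe", "ni", "lo", "ra", "mi", "ta", "zo", "ve",
              "cu", "pa", "ke", "su", "ga", "tri"]
_CHEM_SUFFIX = ["ine", "ol", "ide", "ate", "il", "ax"]
_DIS_SUFFIX = ["itis", "osis", "pathy", "emia", "oma", "algia"]
_DIS_PREFIX = ["chronic", "acute", "recurrent"]

_TITLES = [
    "Adverse outcomes of experimental pharmacotherapy in a cohort study.",
    "Safety profile of candidate compounds in hospitalized patients.",
    "Drug related complications observed during a clinical trial.",
]


def _make_name(rng: np.random.Generator, suffixes: list[str],
               used: set[str]) -> str:
    for _ in range(100):
        n = int(rng.integers(2, 4))
        stem = "".join(rng.choice(_SYLLABLES) for _ in range(n))
        name = stem + str(rng.choice(suffixes))
        if name not in used:
            used.add(name)
            return name
    raise RuntimeError("could not generate a unique surface")  # pragma: no cover


@dataclass
class _Concept:
    concept_id: str
    entity_type: str
    surface: str


def _build_pools(cfg: GenConfig, rng: np.random.Generator):
    used: set[str] = set()
    chems, diss = [], []
    for i in range(cfg.vocab_size):
        chems.append(_Concept(f"C{i + 1:06d}", CHEMICAL,
                              _make_name(rng, _CHEM_SUFFIX, used)))
    for i in range(cfg.vocab_size):
        surface = _make_name(rng, _DIS_SUFFIX, used)
        if rng.random() < 0.3:
            surface = f"{rng.choice(_DIS_PREFIX)} {surface}"
        diss.append(_Concept(f"D{i + 1:06d}", DISEASE, surface))
    return chems, diss


# A sentence template is a list of parts: plain strings or _Concept refs.
_Sentence = list


def _assemble(doc_id: str, title: str, sentence_parts: list[_Sentence],
              relations: list[tuple[str, str]]) -> DocumentRecord:
    mentions: list[EntityMention] = []
    abstract_chunks: list[str] = []
    pos = len(title) + 1  # offsets index into title + " " + abstract
    for parts in sentence_parts:
        sent = ""
        for part in parts:
            if isinstance(part, _Concept):
                start = pos + len(sent)
                mentions.append(EntityMention(
                    concept_id=part.concept_id, entity_type=part.entity_type,
                    start=start, end=start + len(part.surface),
                    surface=part.surface))
                sent += part.surface
            else:
                sent += part
        abstract_chunks.append(sent)
        pos += len(sent) + 1  # the joining space
    return DocumentRecord(
        doc_id=doc_id, title=title, abstract=" ".join(abstract_chunks),
        mentions=mentions,
        relations=[RelationAnnotation(chemical_id=c, disease_id=d)
                   for c, d in relations])


def generate(config: GenConfig) -> list[DocumentRecord]:
    """Generate a corpus of annotated documents (deterministic in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chem_pool, dis_pool = _build_pools(config, rng)
    docs = []
    for d in range(config.n_docs):
        docs.append(_generate_doc(config, rng, f"{10000 + d}",
                                  chem_pool, dis_pool))
    return docs


def _generate_doc(cfg: GenConfig, rng: np.random.Generator, doc_id: str,
                  chem_pool: list[_Concept],
                  dis_pool: list[_Concept]) -> DocumentRecord:
    lo, hi = cfg.entities_per_doc
    rlo, rhi = cfg.relations_per_doc
    n_entities = int(rng.integers(lo, hi + 1))
    n_rel = int(rng.integers(rlo, rhi + 1))

    chems = [chem_pool[i] for i in
             rng.choice(len(chem_pool), size=cfg.vocab_size, replace=False)]
    diss = [dis_pool[i] for i in
            rng.choice(len(dis_pool), size=cfg.vocab_size, replace=False)]
    by_id = {c.concept_id: c for c in chems + diss}

    # --- sample relations; coordination reuses a previous disease ---------
    relations: list[tuple[str, str]] = []   # (chem_id, dis_id)
    rel_chems: list[_Concept] = []
    rel_diss: list[_Concept] = []
    ci = di = 0
    for r in range(n_rel):
        chem = chems[ci]
        ci += 1
        if r > 0 and rng.random() < cfg.coordination_prob:
            dis = rel_diss[int(rng.integers(len(rel_diss)))]
        else:
            dis = diss[di]
            di += 1
        relations.append((chem.concept_id, dis.concept_id))
        rel_chems.append(chem)
        if dis not in rel_diss:
            rel_diss.append(dis)
    inter_flags = [bool(rng.random() < cfg.inter_sentential_fraction)
                   for _ in relations]

    # --- distractor entities ----------------------------------------------
    n_used = len({c.concept_id for c in rel_chems}) + len(rel_diss)
    distract_chems: list[_Concept] = []
    distract_diss: list[_Concept] = []
    while n_used + len(distract_chems) + len(distract_diss) < n_entities:
        if rng.random() < 0.5:
            distract_chems.append(chems[ci])
            ci += 1
        else:
            distract_diss.append(diss[di])
            di += 1

    # --- realize text units -------------------------------------------------
    units: list[list[_Sentence]] = []

    # group intra relations by disease for coordination sentences
    intra_by_dis: dict[str, list[str]] = {}
    for (c, dis), inter in zip(relations, inter_flags):
        if not inter:
            intra_by_dis.setdefault(dis, []).append(c)
    for dis_id, chem_ids in intra_by_dis.items():
        dis = by_id[dis_id]
        i = 0
        while i < len(chem_ids):
            if len(chem_ids) - i >= 2:
                c1, c2 = by_id[chem_ids[i]], by_id[chem_ids[i + 1]]
                units.append([[c1, " and ", c2, " induced ", dis,
                               " in several cases."]])
                i += 2
            else:
                c1 = by_id[chem_ids[i]]
                n_pat = int(rng.integers(5, 40))
                tpl = int(rng.integers(2))
                if tpl == 0:
                    units.append([[c1, f" induced ", dis,
                                   f" in {n_pat} patients."]])
                else:
                    units.append([["Treatment with ", c1, " induced ",
                                   dis, "."]])
                i += 1
    for (c, dis_id), inter in zip(relations, inter_flags):
        if inter:
            chem, dis = by_id[c], by_id[dis_id]
            tpl = int(rng.integers(2))
            if tpl == 0:
                units.append([
                    ["Patients received ", chem,
                     " during the study period."],
                    ["Subsequently, ", dis,
                     " developed after this treatment."]])
            else:
                units.append([
                    [chem, " was administered daily for two weeks."],
                    [dis, " developed after the therapy."]])

    for c in distract_chems:
        units.append([["Serum ", c, " levels were monitored throughout."]])
    for dis in distract_diss:
        units.append([["No evidence of ", dis, " was observed."]])
    if (distract_chems and distract_diss
            and rng.random() < cfg.distractor_cooccur_prob):
        units.append([[distract_chems[0], " did not alter the course of ",
                       distract_diss[0], "."]])
    if rel_chems and rng.random() < cfg.repeat_mention_prob:
        units.append([["The effects of ", rel_chems[0],
                       " remained under review."]])
    if rel_diss and rng.random() < cfg.repeat_mention_prob:
        units.append([[rel_diss[0], " resolved within weeks."]])
    if not units:
        units.append([["No drug related events were recorded."]])

    order = rng.permutation(len(units))
    sentence_parts: list[_Sentence] = []
    for i in order:
        sentence_parts.extend(units[i])

    title = str(rng.choice(_TITLES))
    return _assemble(doc_id, title, sentence_parts, relations)
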