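"""Building sequence-labeling instances from annotated documents.

Document-level relation annotations carry no offsets, so the extraction
problem is cast as tagging: for every entity concept in a document (the
*source*), one labeled instance is built over the whole token sequence, and
the model must tag every mention of every concept related to that source as
a *target*.

Input type tags (6): ``Che``, ``Dis`` (regular chemical / disease mention),
``S-Che``, ``S-Dis`` (mention of the source concept), ``<eos>`` (sentence
boundary marker) and ``O`` (ordinary word).

Output tags (8): the six above plus ``T-Che`` and ``T-Dis``, marking
mentions of concepts that hold a relation with the source concept.

Because annotations are concept-level, *all* mentions of a target concept
receive T-* tags, and all mentions of the source receive S-* type and tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import (CHEMICAL, DISEASE, DocumentRecord, Sentence,
                        split_sentences, tokenize)

EOS = "<eos>"

#: input type tag set, closed
TYPE_TAGS = ("Che", "Dis", "S-Che", "S-Dis", EOS, "O")
#: output tag set, closed; order fixes the CRF tag indices
OUTPUT_TAGS = ("Che", "Dis", "S-Che", "S-Dis", "T-Che", "T-Dis", "O", EOS)

TYPE_INDEX = {t: i for i, t in enumerate(TYPE_TAGS)}
TAG_INDEX = {t: i for i, t in enumerate(OUTPUT_TAGS)}

_S_OF = {CHEMICAL: "S-Che", DISEASE: "S-Dis"}
_T_OF = {CHEMICAL: "T-Che", DISEASE: "T-Dis"}
_R_OF = {CHEMICAL: "Che", DISEASE: "Dis"}


@dataclass
class LabeledInstance:
    """One tagging instance: a document viewed from one source concept."""

    doc_id: str
    source_concept_id: str
    source_entity_type: str
    #: normalized words; mention tokens replaced by their concept ID(s),
    #: one ``<eos>`` after each sentence
    tokens: list[str]
    #: per-token input type tag (subset of TYPE_TAGS)
    types: list[str]
    #: per-token gold output tag (subset of OUTPUT_TAGS); [] at predict time
    gold_tags: list[str]
    #: [start, end) token-index range of each sentence (``<eos>`` included)
    sentence_spans: list[tuple[int, int]]
    #: per-sentence entity-detector class in {1, 2, 3}; [] at predict time
    endet_labels: list[int]
    #: per-token tuple of concept IDs ('' tuple for non-mention tokens)
    token_concept_ids: list[tuple[str, ...]]
    token_entity_types: list[str | None] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tokens)


def normalize_words(doc: DocumentRecord,
                    sentences: list[Sentence] | None = None):
    """Normalized token sequence for a document.

    Every mention token's surface is replaced by its concept ID (co-located
    composite mentions joined with ``|``), other tokens are lowercased, and
    one ``<eos>`` token is appended per sentence.

    Returns ``(words, concept_ids, entity_types, sentence_spans)`` with one
    entry per token.
    """
    if sentences is None:
        sentences = split_sentences(doc)
    words: list[str] = []
    cids: list[tuple[str, ...]] = []
    etypes: list[str | None] = []
    spans: list[tuple[int, int]] = []
    for sent in sentences:
        start = len(words)
        for tok in tokenize(sent, doc):
            if tok.concept_ids:
                words.append("|".join(tok.concept_ids))
                cids.append(tok.concept_ids)
                etypes.append(tok.entity_type)
            else:
                words.append(tok.surface.lower())
                cids.append(())
                etypes.append(None)
        words.append(EOS)
        cids.append(())
        etypes.append(None)
        spans.append((start, len(words)))
    return words, cids, etypes, spans


def assign_endet_labels(instance: LabeledInstance) -> list[int]:
    """Per-sentence entity-detector class from the instance's gold tags.

    Class 3: the sentence has a source (S-*) and at least one target (T-*)
    mention; class 2: a source mention but no target; class 1: otherwise
    (including the case of targets without the source).
    """
    labels = []
    for (s, e) in instance.sentence_spans:
        tags = instance.gold_tags[s:e]
        has_s = any(t in ("S-Che", "S-Dis") for t in tags)
        has_t = any(t in ("T-Che", "T-Dis") for t in tags)
        labels.append(3 if (has_s and has_t) else 2 if has_s else 1)
    return labels


def build_instances(doc: DocumentRecord,
                    sentences: list[Sentence] | None = None,
                    with_gold: bool = True) -> list[LabeledInstance]:
    """One :class:`LabeledInstance` per distinct concept in the document.

    In the instance for source concept *c*: tokens of *c*'s mentions are
    typed (and gold-tagged) ``S-Che``/``S-Dis``; tokens of concepts that
    hold an annotated relation with *c* are gold-tagged ``T-Che``/``T-Dis``;
    all other entity tokens are typed and tagged ``Che``/``Dis``; ordinary
    words are ``O``. A document with no entities yields no instances.
    """
    if sentences is None:
        sentences = split_sentences(doc)
    words, cids, etypes, spans = normalize_words(doc, sentences)

    # concepts in order of first mention
    order: dict[str, str] = {}
    for m in sorted(doc.mentions, key=lambda m: (m.start, m.end, m.concept_id)):
        order.setdefault(m.concept_id, m.entity_type)

    related: dict[str, set[str]] = {c: set() for c in order}
    for rel in doc.relations:
        if rel.chemical_id in related and rel.disease_id in related:
            related[rel.chemical_id].add(rel.disease_id)
            related[rel.disease_id].add(rel.chemical_id)

    instances = []
    for source, source_type in order.items():
        types: list[str] = []
        tags: list[str] = []
        for word, concept_ids, etype in zip(words, cids, etypes):
            if word == EOS and not concept_ids:
                types.append(EOS)
                tags.append(EOS)
            elif not concept_ids:
                types.append("O")
                tags.append("O")
            elif source in concept_ids:
                types.append(_S_OF[source_type])
                tags.append(_S_OF[source_type])
            else:
                types.append(_R_OF[etype])
                if with_gold and any(c in related[source] for c in concept_ids):
                    tags.append(_T_OF[etype])
                else:
                    tags.append(_R_OF[etype])
        inst = LabeledInstance(
            doc_id=doc.doc_id, source_concept_id=source,
            source_entity_type=source_type, tokens=list(words),
            types=types, gold_tags=tags if with_gold else [],
            sentence_spans=list(spans), endet_labels=[],
            token_concept_ids=list(cids), token_entity_types=list(etypes))
        if with_gold:
            inst.endet_labels = assign_endet_labels(inst)
        else:
            inst.gold_tags = []
        instances.append(inst)
    return instances


def format_instance(instance: LabeledInstance) -> str:
    """Two/three-column per-token text rendering, blank line per sentence."""
    out = []
    for s, e in instance.sentence_spans:
        for i in range(s, e):
            cols = [instance.tokens[i], instance.types[i]]
            if instance.gold_tags:
                cols.append(instance.gold_tags[i])
            out.append("\t".join(cols))
        out.append("")
    return "\n".join(out)
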