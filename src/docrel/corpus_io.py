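"""Reading, writing and segmenting PubTator-format annotated abstracts.

The PubTator dialect handled here is the one used to distribute
document-level chemical-disease relation corpora::

    PMID|t|Title text
    PMID|a|Abstract text
    PMID<TAB>start<TAB>end<TAB>mention text<TAB>Chemical|Disease<TAB>conceptID
    PMID<TAB>CID<TAB>chemicalID<TAB>diseaseID
    <blank line>

Character offsets are 0-based half-open indices into ``title + " " +
abstract``.  Concept identifiers are MeSH-style IDs; relations are annotated
at the document level, i.e. as unordered (chemical concept, disease concept)
pairs without offsets.

Load-time normalization (lossy by design):

* mentions whose concept ID is ``-1`` (un-normalized) are dropped;
* composite concept IDs (``D001|D002``) are expanded into one co-located
  mention per ID sharing the span;
* partially overlapping mentions with distinct spans are resolved by keeping
  the longest span (ties: earliest start);
* relations whose chemical or disease concept has no surviving mention are
  dropped with a logged warning (they cannot be encoded as tags).

``write_pubtator(read_pubtator(f))`` is the byte-for-byte identity on files
that need none of the above and whose mention lines are sorted by
``(start, end)``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

CHEMICAL = "chemical"
DISEASE = "disease"

_TYPE_FROM_FILE = {"Chemical": CHEMICAL, "Disease": DISEASE}
_TYPE_TO_FILE = {CHEMICAL: "Chemical", DISEASE: "Disease"}


class PubTatorParseError(ValueError):
    """Malformed PubTator input; message names the offending line number."""


class ValidationError(ValueError):
    """A record violates the format's offset/surface contract."""


@dataclass(frozen=True)
class EntityMention:
    """A single entity mention with its normalized concept identifier."""

    concept_id: str
    entity_type: str  # CHEMICAL or DISEASE
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class RelationAnnotation:
    """A document-level chemical-disease pair, stored as (chemical, disease)."""

    chemical_id: str
    disease_id: str


@dataclass
class DocumentRecord:
    doc_id: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationAnnotation] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Title and abstract joined by a single space (offset basis)."""
        return self.title + " " + self.abstract

    def concept_ids(self) -> set[str]:
        return {m.concept_id for m in self.mentions}

    def concept_type(self, concept_id: str) -> str:
        for m in self.mentions:
            if m.concept_id == concept_id:
                return m.entity_type
        raise KeyError(concept_id)


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    #: concept IDs co-located on this token (composite expansion), or ()
    concept_ids: tuple[str, ...] = ()
    entity_type: str | None = None


@dataclass
class Sentence:
    """A contiguous character span of the document; index 0 is the title."""

    index: int
    start: int
    end: int

    def text_in(self, doc: DocumentRecord) -> str:
        return doc.text[self.start : self.end]


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------

def _validate_mention(doc_id: str, text: str, start: int, end: int,
                      surface: str, lineno: int) -> None:
    if not (0 <= start < end <= len(text)):
        raise ValidationError(
            f"line {lineno}: mention [{start},{end}) out of bounds for "
            f"document {doc_id} (text length {len(text)})")
    if text[start:end] != surface:
        raise ValidationError(
            f"line {lineno}: mention text {surface!r} does not match document "
            f"{doc_id} slice {text[start:end]!r} at [{start},{end})")


def _resolve_overlaps(mentions: list[EntityMention]) -> list[EntityMention]:
    """Keep the longest span among partially overlapping distinct spans.

    Co-located mentions (identical spans, from composite-ID expansion) are
    all kept: they collapse into a single token downstream.
    """
    spans = sorted({(m.start, m.end) for m in mentions},
                   key=lambda s: (-(s[1] - s[0]), s[0]))
    kept_spans: list[tuple[int, int]] = []
    for s in spans:
        if all(s[1] <= k[0] or s[0] >= k[1] for k in kept_spans):
            kept_spans.append(s)
    kept = set(kept_spans)
    out = [m for m in mentions if (m.start, m.end) in kept]
    out.sort(key=lambda m: (m.start, m.end, m.concept_id))
    return out


def _finish_document(doc: DocumentRecord) -> DocumentRecord:
    doc.mentions = _resolve_overlaps(doc.mentions)
    present = doc.concept_ids()
    kept_rel = []
    for rel in doc.relations:
        if rel.chemical_id in present and rel.disease_id in present:
            kept_rel.append(rel)
        else:
            logger.warning(
                "document %s: dropping relation (%s, %s); a concept has no "
                "mention", doc.doc_id, rel.chemical_id, rel.disease_id)
    doc.relations = kept_rel
    return doc


def read_pubtator(path: str | Path) -> list[DocumentRecord]:
    """Parse a PubTator file into :class:`DocumentRecord` objects.

    Raises :class:`PubTatorParseError` on malformed lines and
    :class:`ValidationError` when a mention's text does not match its span.
    """
    docs: list[DocumentRecord] = []
    cur: DocumentRecord | None = None
    pending: list[tuple[int, str, str, str, str, str]] = []

    def flush() -> None:
        nonlocal cur, pending
        if cur is None:
            return
        for lineno, start_s, end_s, surface, etype, cid in pending:
            start, end = int(start_s), int(end_s)
            _validate_mention(cur.doc_id, cur.text, start, end, surface, lineno)
            if etype not in _TYPE_FROM_FILE:
                raise PubTatorParseError(
                    f"line {lineno}: unknown entity type {etype!r}")
            for one_id in cid.split("|"):
                if one_id == "-1" or not one_id:
                    continue
                cur.mentions.append(EntityMention(
                    concept_id=one_id, entity_type=_TYPE_FROM_FILE[etype],
                    start=start, end=end, surface=surface))
        docs.append(_finish_document(cur))
        cur, pending = None, []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if "|t|" in line or "|a|" in line:
                pmid, kind, text = line.split("|", 2)
                if kind == "t":
                    if cur is not None:
                        flush()
                    cur = DocumentRecord(doc_id=pmid, title=text, abstract="")
                elif kind == "a":
                    if cur is None or cur.doc_id != pmid:
                        raise PubTatorParseError(
                            f"line {lineno}: abstract line for {pmid} without "
                            f"matching title")
                    cur.abstract = text
                else:  # pragma: no cover - guarded by the `in` checks
                    raise PubTatorParseError(f"line {lineno}: bad section {kind!r}")
                continue
            fields = line.split("\t")
            if cur is None:
                raise PubTatorParseError(
                    f"line {lineno}: annotation line outside a document block")
            if len(fields) == 4 and fields[1] == "CID":
                cur.relations.append(
                    RelationAnnotation(chemical_id=fields[2], disease_id=fields[3]))
            elif len(fields) in (6, 7):
                pending.append((lineno, fields[1], fields[2], fields[3],
                                fields[4], fields[5]))
            else:
                raise PubTatorParseError(
                    f"line {lineno}: malformed annotation line: {line!r}")
        flush()
    return docs


def validate_document(doc: DocumentRecord) -> None:
    """Raise :class:`ValidationError` if offsets/surfaces are inconsistent."""
    for m in doc.mentions:
        _validate_mention(doc.doc_id, doc.text, m.start, m.end, m.surface, 0)
    present = doc.concept_ids()
    for rel in doc.relations:
        if rel.chemical_id not in present or rel.disease_id not in present:
            raise ValidationError(
                f"document {doc.doc_id}: relation ({rel.chemical_id}, "
                f"{rel.disease_id}) references a concept with no mention")


def write_pubtator(docs: Sequence[DocumentRecord], path: str | Path) -> None:
    """Write records in the PubTator dialect (validating each first)."""
    lines: list[str] = []
    for doc in docs:
        validate_document(doc)
        lines.append(f"{doc.doc_id}|t|{doc.title}")
        lines.append(f"{doc.doc_id}|a|{doc.abstract}")
        for m in sorted(doc.mentions, key=lambda m: (m.start, m.end, m.concept_id)):
            lines.append("\t".join([
                doc.doc_id, str(m.start), str(m.end), m.surface,
                _TYPE_TO_FILE[m.entity_type], m.concept_id]))
        for rel in doc.relations:
            lines.append("\t".join([doc.doc_id, "CID",
                                    rel.chemical_id, rel.disease_id]))
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


# ---------------------------------------------------------------------------
# Sentence splitting and tokenization
# ---------------------------------------------------------------------------

#: tokens that commonly precede a period without ending a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "al", "fig", "figs", "dr", "no", "st", "approx",
    "etc", "ref", "refs", "resp",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def _is_abbreviation(text: str, punct_pos: int) -> bool:
    """True if the word ending at ``punct_pos`` is an abbreviation."""
    j = punct_pos
    i = j
    while i > 0 and not text[i - 1].isspace():
        i -= 1
    word = text[i:j].rstrip(".").lower()
    if word in _ABBREVIATIONS:
        return True
    # single capital letter, as in initials or "E. coli"
    if len(word) == 1 and text[i].isupper():
        return True
    return False


def split_sentences(doc: DocumentRecord) -> list[Sentence]:
    """Deterministically split a document into sentences.

    The title is always its own sentence (index 0).  Abstract boundaries are
    placed after sentence-final ``.!?`` followed by whitespace, with an
    abbreviation guard, and never inside an entity-mention span.
    """
    sentences = [Sentence(index=0, start=0, end=len(doc.title))]
    offset = len(doc.title) + 1  # abstract start within doc.text
    text = doc.text
    spans = [(m.start, m.end) for m in doc.mentions]

    boundaries: list[int] = []
    for match in _BOUNDARY.finditer(text, offset):
        cut = match.end()  # position just after the punctuation run
        if _is_abbreviation(text, match.start()):
            continue
        if any(s < cut < e for s, e in spans):
            continue
        boundaries.append(cut)

    start = offset
    for cut in boundaries:
        if cut <= start:
            continue
        sentences.append(Sentence(index=len(sentences), start=start, end=cut))
        # skip inter-sentence whitespace
        nxt = cut
        while nxt < len(text) and text[nxt].isspace():
            nxt += 1
        start = nxt
    if start < len(text):
        sentences.append(Sentence(index=len(sentences), start=start, end=len(text)))
    return sentences


_WORD = re.compile(r"\w+|[^\w\s]")


def tokenize(sentence: Sentence, doc: DocumentRecord) -> list[Token]:
    """Tokenize a sentence, emitting each entity-mention span as ONE token.

    Non-mention text is split on word characters and single punctuation
    marks.  Tokens carry character spans; mention tokens carry the tuple of
    co-located concept IDs and the entity type.
    """
    by_span: dict[tuple[int, int], list[EntityMention]] = {}
    for m in doc.mentions:
        if sentence.start <= m.start and m.end <= sentence.end:
            by_span.setdefault((m.start, m.end), []).append(m)

    tokens: list[Token] = []
    pos = sentence.start
    for (s, e) in sorted(by_span):
        if s > pos:
            for w in _WORD.finditer(doc.text, pos, s):
                tokens.append(Token(w.group(), w.start(), w.end()))
        group = by_span[(s, e)]
        tokens.append(Token(
            surface=doc.text[s:e], start=s, end=e,
            concept_ids=tuple(m.concept_id for m in group),
            entity_type=group[0].entity_type))
        pos = e
    for w in _WORD.finditer(doc.text, pos, sentence.end):
        tokens.append(Token(w.group(), w.start(), w.end()))
    return tokens


def corpus_stats(docs: Iterable[DocumentRecord]) -> dict[str, int]:
    """Document / relation counts, with the intra-/inter-sentential split.

    A pair is intra-sentential iff some sentence contains at least one
    mention of each concept; otherwise inter-sentential.
    """
    from .decoder_eval import split_intra_inter  # local import: avoid cycle

    n_docs = n_rel = n_intra = n_inter = 0
    for doc in docs:
        n_docs += 1
        pairs = {(r.chemical_id, r.disease_id) for r in doc.relations}
        intra, inter = split_intra_inter(doc, pairs)
        n_rel += len(pairs)
        n_intra += len(intra)
        n_inter += len(inter)
    return {"documents": n_docs, "relations": n_rel,
            "intra_sentential": n_intra, "inter_sentential": n_inter}
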