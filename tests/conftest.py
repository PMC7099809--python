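import numpy as np
import pytest

from docrel.corpus_io import (CHEMICAL, DISEASE, DocumentRecord, EntityMention,
                              RelationAnnotation)
from docrel.synthetic_corpus import GenConfig, generate


def make_doc(doc_id, title, abstract, entities, relations=()):
    """Build a DocumentRecord by locating entity surfaces in the text.

    ``entities``: iterable of (surface, concept_id, entity_type); every
    occurrence of each surface becomes a mention.
    """
    text = title + " " + abstract
    mentions = []
    for surface, cid, etype in entities:
        start = 0
        while True:
            i = text.find(surface, start)
            if i < 0:
                break
            mentions.append(EntityMention(concept_id=cid, entity_type=etype,
                                          start=i, end=i + len(surface),
                                          surface=surface))
            start = i + len(surface)
    return DocumentRecord(
        doc_id=doc_id, title=title, abstract=abstract, mentions=mentions,
        relations=[RelationAnnotation(chemical_id=c, disease_id=d)
                   for c, d in relations])


@pytest.fixture(scope="session")
def coordination_doc():
    """A document mirroring the coordinated-relation running example:
    two chemicals jointly induce the source disease, two do not."""
    return make_doc(
        "90001",
        "Glucose metabolism in treated patients.",
        "Both clozapine and olanzapine induced insulin resistance with "
        "elevation of glucose levels. No effect of risperidone on insulin "
        "resistance was observed.",
        entities=[
            ("clozapine", "D003024", CHEMICAL),
            ("olanzapine", "C076029", CHEMICAL),
            ("glucose", "D005947", CHEMICAL),
            ("risperidone", "D018967", CHEMICAL),
            ("insulin resistance", "D007333", DISEASE),
        ],
        relations=[("D003024", "D007333"), ("C076029", "D007333")])


@pytest.fixture(scope="session")
def small_corpus():
    return generate(GenConfig(n_docs=50, seed=123))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
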