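"""Show how a document becomes per-source sequence-labeling instances.

For each entity concept, one instance marks that concept as the source
(type S-Che/S-Dis) and gold-tags every mention of its related concepts as
a target (T-Che/T-Dis).  Coordinated chemicals ("X and Y induced Z") end
up as two targets in the same instance, which is exactly the relation
interaction a per-pair classifier cannot see.
"""

from docrel import build_instances
from docrel.corpus_io import CHEMICAL, DISEASE, DocumentRecord, EntityMention, RelationAnnotation

title = "Metabolic effects of antipsychotics."
abstract = ("Both clozapine and olanzapine induced insulin resistance. "
            "No effect of risperidone on insulin resistance was observed.")
text = title + " " + abstract

mentions = []
for surface, cid, etype in [("clozapine", "D003024", CHEMICAL),
                            ("olanzapine", "C076029", CHEMICAL),
                            ("risperidone", "D018967", CHEMICAL),
                            ("insulin resistance", "D007333", DISEASE)]:
    start = 0
    while (i := text.find(surface, start)) >= 0:
        mentions.append(EntityMention(cid, etype, i, i + len(surface), surface))
        start = i + len(surface)

doc = DocumentRecord(
    doc_id="90001", title=title, abstract=abstract, mentions=mentions,
    relations=[RelationAnnotation("D003024", "D007333"),
               RelationAnnotation("C076029", "D007333")])

instances = build_instances(doc)
print(f"{len(instances)} instances (one per concept)\n")
inst = next(i for i in instances if i.source_concept_id == "D007333")
print(f"source = {inst.source_concept_id} ({inst.source_entity_type})")
print(f"{'token':22s} {'type':7s} gold")
for tok, ty, tag in zip(inst.tokens, inst.types, inst.gold_tags):
    marker = "  <--" if tag.startswith(("S-", "T-")) else ""
    print(f"{tok:22s} {ty:7s} {tag}{marker}")
print("\nEnDet sentence classes (1 none / 2 source / 3 source+target):",
      inst.endet_labels)
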