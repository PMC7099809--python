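# Methods

## Problem and model

`docrel` extracts document-level binary relations between biomedical
entities — the motivating case is chemical-induced disease (CID) pairs in
PubMed abstracts, where annotations name concept pairs per document without
offsets, and roughly a third of the pairs never co-occur in a sentence.
Classification approaches score one candidate pair at a time and so ignore
both cross-sentence evidence and the interactions between relations (e.g.
coordination: "X and Y induced Z" supports both pairs jointly).

The package instead casts the task as sequence labeling. For every entity
concept *c* in a document, one instance is built over the full token
sequence of title + abstract:

* mentions are replaced by their concept IDs (so all surface variants of a
  concept share one vocabulary item) and `<eos>` markers close sentences;
* the input **type sequence** over {`Che`, `Dis`, `S-Che`, `S-Dis`,
  `<eos>`, `O`} marks entity tokens and distinguishes the source concept;
* the gold **output tags** over {`Che`, `Dis`, `S-Che`, `S-Dis`, `T-Che`,
  `T-Dis`, `O`, `<eos>`} additionally mark every mention of every concept
  that holds an annotated relation with *c* as a target (`T-*`). Because
  annotations are concept-level, *all* mentions of a target concept are
  tagged `T-*` — there is no offset information to do otherwise.

Each token *i* is embedded as `x_i = [w_i_emb ; t_i_emb]` (word 100-d, type
30-d by default). Two feature extractors encode the document:

* **DE** — a document-level Bi-LSTM over the whole token sequence,
  `h_do_i = [h_f_i ; h_b_i]` (per-direction hidden 150);
* **HE** — a *bottom* Bi-LSTM applied one sentence at a time (hidden 100;
  state never crosses sentence boundaries), whose outputs are concatenated
  in document order and fed to a *top* Bi-LSTM (hidden 150) that restores
  cross-sentence connections.

The LSTM cell is the standard gated unit: `i, f, o = σ(W_i* x + b_i* +
W_h* h + b_h*)`, `g = tanh(·)`, `c_t = f⊙c_{t-1} + i⊙g`, `h_t = o⊙tanh(c_t)`.

An auxiliary **entity detector (EnDet)** classifies every sentence into
three classes — no source/target mention, source only, source plus at
least one target — from the bottom Bi-LSTM's sentence representation
`s = [h_f_last ; h_b_first]` through a softmax layer. It exists only to
shape the shared bottom weights toward entity-location features.

Per token, DE and HE(top) outputs are concatenated (600-d at default
sizes) and an affine layer produces emission scores over the 8 tags,
decoded by a linear-chain CRF (start/stop scores plus an 8×8 transition
matrix; no hard transition constraints by default, an optional `allowed`
mask exists for experiments). Training is two-stage: (1) bottom Bi-LSTM +
EnDet on per-sentence cross-entropy; (2) the full network on sequence
negative log-likelihood (forward algorithm), with Adam (lr 0.001), batch
32, dropout 0.2 after the embeddings and 0.5 on the bottom Bi-LSTM output,
gradient-norm clipping at 5, and best-on-dev model selection by
document-level F1. The EnDet loss is not continued in stage 2; it
influences the final model only through the shared bottom weights (a
`joint_endet_weight` option adds it back).

At prediction time Viterbi decoding yields one tag path per instance; a
concept is a directed target of the source iff any of its mention tokens
is tagged `T-*` of the matching type; and a chemical-disease pair is
emitted only under **bidirectional confirmation** — each concept must be
found a target when the other is the source (an ablation `union` mode
exists). This intersection is what lets a tagging formulation, which
over-generates directed findings independently, keep precision.

## Implementation

The whole network — LSTM cells, masked bidirectional sequence application,
the CRF forward recursion and Viterbi, softmax heads, dropout, Adam, and
every backward pass — is implemented directly in NumPy. Gradients are
analytic (the CRF gradient is expected-minus-gold counts obtained by
back-propagating through the log-space forward recursion) and are verified
against central finite differences in the test suite. Batches are padded
time-major with validity masks; padded positions carry recurrent state
through unchanged, so padding never alters per-sequence results, and the
per-sentence bottom Bi-LSTM is realized by re-batching all sentences of a
batch. Eval-mode forward passes are deterministic; all randomness
(initialization, shuffling, dropout) flows from explicit seeds, so
identical seeds reproduce identical logs, parameters and predictions.

## Corpus handling

PubTator files are parsed with strict validation (offsets into
`title + " " + abstract`, 0-based half-open; mention text must equal the
span slice). Mentions with concept ID `-1` are dropped, composite IDs
(`A|B`) are expanded into co-located mentions, partially overlapping spans
are resolved by keeping the longest (ties: earliest start), and relations
whose concepts have no surviving mention are dropped with a warning —
they cannot be encoded as tags. Sentence splitting is a deterministic
regex rule (sentence-final `.!?` + whitespace) with an abbreviation guard
and a hard rule against splitting inside a mention span; the title is
always its own sentence. Tokenization splits words and punctuation except
that each mention span is exactly one token. These components are declared
choices: reproducibility is prioritized over matching any particular NLP
toolkit's segmentation.

## Evaluation

Micro-averaged precision, recall and F1 = 2PR/(P+R) over all documents
(macro per-document averaging available). A pair is **intra-sentential**
iff at least one sentence contains a mention of each of its concepts, else
**inter-sentential**; the same co-occurrence rule assigns a level to
unmatched (false-positive) predictions, making level-wise precision
well-defined — the choice is declared, since published level-wise
precision figures leave the FP assignment rule unstated.

## Synthetic corpora

The generator emits PubTator documents from cue templates: intra-sentential
relations ("X induced Y in 12 patients"), coordination ("X and Y induced
Z"), and inter-sentential relations realized as adjacent sentence pairs
("Patients received X …" / "Y developed after this treatment") whose two
concepts never co-occur in a sentence. Distractor entities appear in
neutral sentences, including negative co-occurrence sentences ("X did not
alter the course of Y"). Each relation is inter-sentential independently
with probability `inter_sentential_fraction` (default 0.33, the proportion
reported for document-level CID corpora). Concept IDs are MeSH-formatted
(`C######`/`D######`) and drawn from a finite pool shared across documents,
so held-out documents reuse trained concept embeddings while the cue words
and type features carry the generalizable signal.

What this does *not* emulate: real lexical diversity, hedged or negated
relation language, coreference chains longer than one sentence, nested or
discontinuous mentions, or annotation noise. Tests passing on these
corpora therefore demonstrate that the machinery — instance construction,
learning, decoding, confirmation, evaluation — is correct and learnable,
not that the model reaches any particular accuracy on real corpora.

## Problem sizes and numerical choices

Unit and acceptance runs use desk-scale settings chosen so the whole suite
trains on one CPU core in minutes: hidden sizes 16–32, 10-document corpora
for the overfit check (F1 ≥ 0.99 on the training documents, ≤ 200 epochs)
and 200-document corpora for the held-out recovery check (F1 ≥ 0.90,
80/20 split, ~12 epochs, lr 0.005–0.01). The full-scale defaults
(100/30-d embeddings, 150/100/150 hidden, lr 0.001, batch 32) remain the
configuration defaults for full-corpus use.

Numerical details: log-sum-exp is max-shifted; Viterbi ties break toward
the lowest tag index (deterministic decoding); the `<pad>` embedding row
is pinned to zero; empty sequences and empty lattices are rejected;
degenerate evaluation cases define P = R = F1 = 0 when denominators
vanish; self-relations are never emitted.

## Limitations

* Word-embedding pre-training is out of scope; embeddings are randomly
  initialized or loaded from a `token v1 … vD` text file.
* Clinical-note (mention-level) corpora are out of scope beyond the
  document-level machinery; no BioC XML support.
* Full-scale corpus results require the external corpora and long training
  runs; this package validates the method's mechanics and provides the
  evaluator that reproduces published arithmetic exactly.
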