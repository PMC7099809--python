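"""The document-level relation tagger network.

Architecture, per instance (a document viewed from one source concept):

* **Input representation** — each token is the concatenation of a word
  embedding (mentions having been replaced by concept IDs) and a type-tag
  embedding: ``x_i = [w_i_emb ; t_i_emb]``.
* **DE, document-level extractor** — a Bi-LSTM over the full token sequence
  (title + abstract, ``<eos>`` markers included); per-token output
  ``h_do = [h_f ; h_b]``.
* **HE, hierarchical extractor** — a *bottom* Bi-LSTM run one sentence at a
  time (state never crosses sentence boundaries), whose per-token outputs
  are re-concatenated in document order and fed to a *top* Bi-LSTM that
  restores cross-sentence connections.
* **EnDet, entity detector** — an auxiliary 3-class sentence classifier on
  the bottom Bi-LSTM's sentence representation ``s = [h_last_f ; h_first_b]``
  (no source/target mention, source only, source + target); trained first
  so that entity-location features are baked into the shared bottom weights.
* **Projection + CRF** — DE and HE outputs are concatenated and an affine
  layer produces per-token emission scores over the 8 output tags, decoded
  by a linear-chain CRF.

Everything is NumPy with handwritten backprop (see :mod:`docrel.layers`);
eval-mode forward passes are fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import crf as crf_mod
from .instance_builder import (EOS, LabeledInstance, OUTPUT_TAGS, TAG_INDEX,
                               TYPE_INDEX, TYPE_TAGS)
from .layers import (Adam, LSTMParams, affine_backward, affine_forward,
                     bilstm_backward, bilstm_forward, dropout_mask,
                     lstm_backward, lstm_forward, lstm_step, softmax,
                     softmax_xent)

PAD, UNK = "<pad>", "<unk>"


@dataclass
class ModelConfig:
    """Network dimensions and regularization.

    Defaults follow the reference configuration: 100-d word embeddings, 30-d
    type embeddings, per-direction hidden sizes 150 (DE), 100 (HE bottom)
    and 150 (HE top), dropout 0.2 after the embedding layer and 0.5 on the
    bottom Bi-LSTM output.  The ablation flags ``use_de`` / ``use_he`` /
    ``use_endet`` remove a component while keeping the rest intact.
    """

    word_emb_dim: int = 100
    type_emb_dim: int = 30
    de_hidden: int = 150
    he_bottom_hidden: int = 100
    he_top_hidden: int = 150
    dropout_emb: float = 0.2
    dropout_bottom: float = 0.5
    use_de: bool = True
    use_he: bool = True
    use_endet: bool = True
    n_tags: int = len(OUTPUT_TAGS)

    def __post_init__(self) -> None:
        if not (self.use_de or self.use_he):
            raise ValueError("at least one of DE and HE must be enabled")

    @property
    def input_dim(self) -> int:
        return self.word_emb_dim + self.type_emb_dim

    @property
    def feature_dim(self) -> int:
        d = 0
        if self.use_de:
            d += 2 * self.de_hidden
        if self.use_he:
            d += 2 * self.he_top_hidden
        return d


class Vocabulary:
    """Token -> id map with reserved <pad>/<unk> rows."""

    def __init__(self, tokens: list[str]):
        self.itos = [PAD, UNK] + [t for t in tokens if t not in (PAD, UNK)]
        self.stoi = {t: i for i, t in enumerate(self.itos)}

    def __len__(self) -> int:
        return len(self.itos)

    def __getitem__(self, token: str) -> int:
        return self.stoi.get(token, 1)

    @classmethod
    def build(cls, instances: list[LabeledInstance]) -> "Vocabulary":
        seen: dict[str, None] = {}
        for inst in instances:
            for tok in inst.tokens:
                seen.setdefault(tok, None)
        return cls(list(seen))


def load_embeddings(path, vocab: Vocabulary, matrix: np.ndarray) -> int:
    """Overwrite rows of ``matrix`` from a ``token v1 .. vD`` text file.

    Returns the number of vocabulary tokens that received a pre-trained
    vector; unknown-file tokens are skipped, absent vocabulary tokens keep
    their random initialization.
    """
    hit = 0
    dim = matrix.shape[1]
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip().split()
            if len(parts) != dim + 1:
                continue
            idx = vocab.stoi.get(parts[0])
            if idx is not None:
                matrix[idx] = np.array(parts[1:], dtype=float)
                hit += 1
    return hit


# ---------------------------------------------------------------------------
# Batching
# ---------------------------------------------------------------------------

@dataclass
class Batch:
    """Padded time-major arrays plus sentence bookkeeping for HE/EnDet."""

    instances: list[LabeledInstance]
    word_ids: np.ndarray      # [T, B]
    type_ids: np.ndarray      # [T, B]
    mask: np.ndarray          # [T, B] float
    gold: np.ndarray          # [T, B] int (0 where absent)
    lengths: np.ndarray       # [B]
    has_gold: bool
    # sentence re-batching (NS sentences, padded to S positions)
    n_sent: int
    sent_len: int
    sent_lengths: np.ndarray  # [NS]
    sent_mask: np.ndarray     # [S, NS]
    sent_owner_b: np.ndarray  # [NS] instance index of each sentence
    endet_labels: np.ndarray  # [NS] in {0,1,2}; -1 when unlabeled
    # flat gather/scatter indices between [T, B] and [S, NS]
    flat_doc_t: np.ndarray
    flat_doc_b: np.ndarray
    flat_sent_j: np.ndarray
    flat_sent_n: np.ndarray

    @property
    def size(self) -> int:
        return len(self.instances)


def make_batch(instances: list[LabeledInstance], vocab: Vocabulary) -> Batch:
    B = len(instances)
    if B == 0:
        raise ValueError("empty batch")
    lengths = np.array([len(inst) for inst in instances])
    T = int(lengths.max())
    word_ids = np.zeros((T, B), dtype=int)
    type_ids = np.zeros((T, B), dtype=int)
    mask = np.zeros((T, B))
    gold = np.zeros((T, B), dtype=int)
    has_gold = all(inst.gold_tags for inst in instances)
    sent_records = []  # (b, t0, t1, endet_label)
    for b, inst in enumerate(instances):
        for t, (w, ty) in enumerate(zip(inst.tokens, inst.types)):
            word_ids[t, b] = vocab[w]
            type_ids[t, b] = TYPE_INDEX[ty]
            mask[t, b] = 1.0
        if has_gold:
            for t, tag in enumerate(inst.gold_tags):
                gold[t, b] = TAG_INDEX[tag]
        for si, (s, e) in enumerate(inst.sentence_spans):
            lab = inst.endet_labels[si] - 1 if inst.endet_labels else -1
            sent_records.append((b, s, e, lab))
    NS = len(sent_records)
    S = max(e - s for _, s, e, _ in sent_records)
    sent_lengths = np.array([e - s for _, s, e, _ in sent_records])
    sent_mask = np.zeros((S, NS))
    sent_owner_b = np.array([b for b, _, _, _ in sent_records])
    endet_labels = np.array([lab for _, _, _, lab in sent_records])
    ft, fb, fj, fn = [], [], [], []
    for n, (b, s, e, _) in enumerate(sent_records):
        for j, t in enumerate(range(s, e)):
            ft.append(t)
            fb.append(b)
            fj.append(j)
            fn.append(n)
        sent_mask[: e - s, n] = 1.0
    return Batch(instances=instances, word_ids=word_ids, type_ids=type_ids,
                 mask=mask, gold=gold, lengths=lengths, has_gold=has_gold,
                 n_sent=NS, sent_len=S, sent_lengths=sent_lengths,
                 sent_mask=sent_mask, sent_owner_b=sent_owner_b,
                 endet_labels=endet_labels,
                 flat_doc_t=np.array(ft), flat_doc_b=np.array(fb),
                 flat_sent_j=np.array(fj), flat_sent_n=np.array(fn))


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def endet_forward(sent_hf: np.ndarray, sent_hb: np.ndarray,
                  sent_lengths: np.ndarray, Wo: np.ndarray, bo: np.ndarray):
    """Entity-detector head on bottom Bi-LSTM states.

    ``sent_hf``/``sent_hb`` are the per-direction bottom outputs [S, NS, H];
    the sentence representation is the concatenation of the forward state at
    the last real token and the backward state at the first token.  Returns
    ``(probs [NS, 3], s [NS, 2H])``.
    """
    ns = sent_hf.shape[1]
    last = sent_lengths - 1
    s = np.concatenate([sent_hf[last, np.arange(ns)], sent_hb[0]], axis=1)
    logits = s @ Wo.T + bo
    return softmax(logits, axis=-1), s


class RelationTagger:
    """Full tagger: embeddings + DE + HE/EnDet + projection + CRF."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary, seed: int = 0):
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        c = config
        scale = 0.1
        self.word_emb = rng.uniform(-scale, scale, (len(vocab), c.word_emb_dim))
        self.word_emb[0] = 0.0  # <pad>
        self.type_emb = rng.uniform(-scale, scale,
                                    (len(TYPE_TAGS), c.type_emb_dim))
        self.de_f = LSTMParams(c.input_dim, c.de_hidden, rng)
        self.de_b = LSTMParams(c.input_dim, c.de_hidden, rng)
        self.bot_f = LSTMParams(c.input_dim, c.he_bottom_hidden, rng)
        self.bot_b = LSTMParams(c.input_dim, c.he_bottom_hidden, rng)
        self.top_f = LSTMParams(2 * c.he_bottom_hidden, c.he_top_hidden, rng)
        self.top_b = LSTMParams(2 * c.he_bottom_hidden, c.he_top_hidden, rng)
        k = 1.0 / np.sqrt(c.feature_dim)
        self.Wp = rng.uniform(-k, k, (c.n_tags, c.feature_dim))
        self.bp = np.zeros(c.n_tags)
        self.crf_trans = rng.uniform(-0.1, 0.1, (c.n_tags, c.n_tags))
        self.crf_start = rng.uniform(-0.1, 0.1, c.n_tags)
        self.crf_stop = rng.uniform(-0.1, 0.1, c.n_tags)
        ko = 1.0 / np.sqrt(2 * c.he_bottom_hidden)
        self.Wo = rng.uniform(-ko, ko, (3, 2 * c.he_bottom_hidden))
        self.bo = np.zeros(3)

    # -- parameter registry -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {
            "word_emb": self.word_emb, "type_emb": self.type_emb,
            "Wp": self.Wp, "bp": self.bp, "crf_trans": self.crf_trans,
            "crf_start": self.crf_start, "crf_stop": self.crf_stop,
            "Wo": self.Wo, "bo": self.bo,
        }
        for name in ("de_f", "de_b", "bot_f", "bot_b", "top_f", "top_b"):
            for k, v in getattr(self, name).arrays().items():
                out[f"{name}.{k}"] = v
        return out

    # -- forward pieces -----------------------------------------------------

    def embed(self, batch: Batch, train: bool, rng=None):
        x = np.concatenate([self.word_emb[batch.word_ids],
                            self.type_emb[batch.type_ids]], axis=2)
        dm = None
        if train and self.config.dropout_emb > 0:
            dm = dropout_mask(x.shape, self.config.dropout_emb, rng)
            x = x * dm
        return x, dm

    def encode_document(self, x, mask):
        """DE: Bi-LSTM over the full token sequence -> [T, B, 2*de_hidden]."""
        return bilstm_forward(x, mask, self.de_f, self.de_b)

    def encode_hierarchical(self, x, batch: Batch, train: bool, rng=None):
        """HE: per-sentence bottom Bi-LSTM, then top Bi-LSTM in doc order.

        Returns ``(h_top, cache)`` where cache carries everything needed for
        the backward pass (sentence gather indices, dropout mask, LSTM
        caches and per-direction bottom outputs for EnDet).
        """
        c = self.config
        D = x.shape[2]
        xs = np.zeros((batch.sent_len, batch.n_sent, D))
        xs[batch.flat_sent_j, batch.flat_sent_n] = \
            x[batch.flat_doc_t, batch.flat_doc_b]
        hf, cache_f = lstm_forward(xs, batch.sent_mask, self.bot_f)
        hb, cache_b = lstm_forward(xs, batch.sent_mask, self.bot_b,
                                   reverse=True)
        h_bot = np.concatenate([hf, hb], axis=2)
        dm = None
        if train and c.dropout_bottom > 0:
            dm = dropout_mask(h_bot.shape, c.dropout_bottom, rng)
            h_bot_seq = h_bot * dm
        else:
            h_bot_seq = h_bot
        # scatter back to document order
        T, B = batch.mask.shape
        doc_bot = np.zeros((T, B, 2 * c.he_bottom_hidden))
        doc_bot[batch.flat_doc_t, batch.flat_doc_b] = \
            h_bot_seq[batch.flat_sent_j, batch.flat_sent_n]
        h_top, top_caches = bilstm_forward(doc_bot, batch.mask,
                                           self.top_f, self.top_b)
        cache = {"cache_f": cache_f, "cache_b": cache_b, "hf": hf, "hb": hb,
                 "dm": dm, "top_caches": top_caches, "doc_bot": doc_bot}
        return h_top, cache

    def project_to_emissions(self, feats):
        """Affine map from concatenated DE/HE features to K emission scores."""
        return affine_forward(feats, self.Wp, self.bp)

    def forward(self, batch: Batch, train: bool = False, rng=None):
        """Full forward pass; returns ``(emissions [T,B,K], cache)``."""
        x, dm_emb = self.embed(batch, train, rng)
        cache: dict = {"x": x, "dm_emb": dm_emb}
        parts = []
        if self.config.use_de:
            h_do, de_caches = self.encode_document(x, batch.mask)
            cache["de_caches"] = de_caches
            parts.append(h_do)
        if self.config.use_he:
            h_he, he_cache = self.encode_hierarchical(x, batch, train, rng)
            cache["he_cache"] = he_cache
            parts.append(h_he)
        feats = np.concatenate(parts, axis=2) if len(parts) > 1 else parts[0]
        emissions, _ = self.project_to_emissions(feats)
        cache["feats"] = feats
        return emissions, cache

    # -- training -----------------------------------------------------------

    def loss_and_grads(self, batch: Batch, train: bool = True, rng=None):
        """Mean CRF negative log-likelihood and gradients for all params."""
        emissions, cache = self.forward(batch, train=train, rng=rng)
        loss, d_em, d_trans, d_start, d_stop = \
            crf_mod.crf_nll_batch_with_grad(
                emissions, batch.mask, self.crf_trans, self.crf_start,
                self.crf_stop, batch.gold)
        grads = self._backward(batch, cache, d_em)
        grads["crf_trans"] = d_trans
        grads["crf_start"] = d_start
        grads["crf_stop"] = d_stop
        return loss, grads

    def _backward(self, batch: Batch, cache: dict, d_em: np.ndarray):
        c = self.config
        d_feats, dWp, dbp = affine_backward(d_em, cache["feats"], self.Wp)
        grads: dict[str, np.ndarray] = {"Wp": dWp, "bp": dbp}
        d_x = np.zeros_like(cache["x"])
        col = 0
        if c.use_de:
            d_h_do = d_feats[:, :, col: col + 2 * c.de_hidden]
            col += 2 * c.de_hidden
            dx_de, g_f, g_b = bilstm_backward(d_h_do, cache["de_caches"])
            d_x += dx_de
            for k, v in g_f.items():
                grads[f"de_f.{k}"] = v
            for k, v in g_b.items():
                grads[f"de_b.{k}"] = v
        if c.use_he:
            hc = cache["he_cache"]
            d_h_top = d_feats[:, :, col: col + 2 * c.he_top_hidden]
            d_doc_bot, g_tf, g_tb = bilstm_backward(d_h_top, hc["top_caches"])
            for k, v in g_tf.items():
                grads[f"top_f.{k}"] = v
            for k, v in g_tb.items():
                grads[f"top_b.{k}"] = v
            d_h_bot_seq = np.zeros((batch.sent_len, batch.n_sent,
                                    2 * c.he_bottom_hidden))
            d_h_bot_seq[batch.flat_sent_j, batch.flat_sent_n] = \
                d_doc_bot[batch.flat_doc_t, batch.flat_doc_b]
            if hc["dm"] is not None:
                d_h_bot_seq = d_h_bot_seq * hc["dm"]
            H = c.he_bottom_hidden
            dxs_f, g_bf = lstm_backward(d_h_bot_seq[:, :, :H], hc["cache_f"])
            dxs_b, g_bb = lstm_backward(d_h_bot_seq[:, :, H:], hc["cache_b"])
            for k, v in g_bf.items():
                grads[f"bot_f.{k}"] = v
            for k, v in g_bb.items():
                grads[f"bot_b.{k}"] = v
            dxs = dxs_f + dxs_b
            d_x_he = np.zeros_like(d_x)
            d_x_he[batch.flat_doc_t, batch.flat_doc_b] = \
                dxs[batch.flat_sent_j, batch.flat_sent_n]
            d_x += d_x_he
        if cache["dm_emb"] is not None:
            d_x = d_x * cache["dm_emb"]
        wd = c.word_emb_dim
        d_word = np.zeros_like(self.word_emb)
        d_type = np.zeros_like(self.type_emb)
        np.add.at(d_word, batch.word_ids.reshape(-1),
                  d_x[:, :, :wd].reshape(-1, wd))
        np.add.at(d_type, batch.type_ids.reshape(-1),
                  d_x[:, :, wd:].reshape(-1, c.type_emb_dim))
        d_word[0] = 0.0  # <pad> row stays zero
        grads["word_emb"] = d_word
        grads["type_emb"] = d_type
        return grads

    def endet_loss_and_grads(self, batch: Batch, train: bool = True, rng=None):
        """Stage-1 loss: sentence cross-entropy for the entity detector.

        Only the embedding tables, the bottom Bi-LSTM and the EnDet head
        receive gradients.
        """
        if not np.all(batch.endet_labels >= 0):
            raise ValueError("entity-detector labels missing in batch")
        c = self.config
        x, dm_emb = self.embed(batch, train, rng)
        xs = np.zeros((batch.sent_len, batch.n_sent, x.shape[2]))
        xs[batch.flat_sent_j, batch.flat_sent_n] = \
            x[batch.flat_doc_t, batch.flat_doc_b]
        hf, cache_f = lstm_forward(xs, batch.sent_mask, self.bot_f)
        hb, cache_b = lstm_forward(xs, batch.sent_mask, self.bot_b,
                                   reverse=True)
        ns = batch.n_sent
        last = batch.sent_lengths - 1
        s = np.concatenate([hf[last, np.arange(ns)], hb[0]], axis=1)
        logits = s @ self.Wo.T + self.bo
        loss, d_logits = softmax_xent(logits, batch.endet_labels)
        dWo = d_logits.T @ s
        dbo = d_logits.sum(axis=0)
        d_s = d_logits @ self.Wo
        H = c.he_bottom_hidden
        d_hf = np.zeros_like(hf)
        d_hb = np.zeros_like(hb)
        d_hf[last, np.arange(ns)] = d_s[:, :H]
        d_hb[0] = d_s[:, H:]
        dxs_f, g_bf = lstm_backward(d_hf, cache_f)
        dxs_b, g_bb = lstm_backward(d_hb, cache_b)
        dxs = dxs_f + dxs_b
        d_x = np.zeros_like(x)
        d_x[batch.flat_doc_t, batch.flat_doc_b] = \
            dxs[batch.flat_sent_j, batch.flat_sent_n]
        if dm_emb is not None:
            d_x = d_x * dm_emb
        wd = c.word_emb_dim
        d_word = np.zeros_like(self.word_emb)
        d_type = np.zeros_like(self.type_emb)
        np.add.at(d_word, batch.word_ids.reshape(-1),
                  d_x[:, :, :wd].reshape(-1, wd))
        np.add.at(d_type, batch.type_ids.reshape(-1),
                  d_x[:, :, wd:].reshape(-1, c.type_emb_dim))
        d_word[0] = 0.0
        grads = {"Wo": dWo, "bo": dbo, "word_emb": d_word,
                 "type_emb": d_type}
        for k, v in g_bf.items():
            grads[f"bot_f.{k}"] = v
        for k, v in g_bb.items():
            grads[f"bot_b.{k}"] = v
        return loss, grads

    def endet_predict(self, batch: Batch) -> np.ndarray:
        """Per-sentence entity-detector classes in {1, 2, 3} (eval mode)."""
        x, _ = self.embed(batch, train=False)
        xs = np.zeros((batch.sent_len, batch.n_sent, x.shape[2]))
        xs[batch.flat_sent_j, batch.flat_sent_n] = \
            x[batch.flat_doc_t, batch.flat_doc_b]
        hf, _ = lstm_forward(xs, batch.sent_mask, self.bot_f)
        hb, _ = lstm_forward(xs, batch.sent_mask, self.bot_b, reverse=True)
        probs, _ = endet_forward(hf, hb, batch.sent_lengths, self.Wo, self.bo)
        return probs.argmax(axis=1) + 1

    # -- decoding -----------------------------------------------------------

    def decode(self, batch: Batch) -> list[list[str]]:
        """Viterbi tag sequences (strings), one list per instance."""
        emissions, _ = self.forward(batch, train=False)
        paths = crf_mod.viterbi_batch(emissions, batch.mask, self.crf_trans,
                                      self.crf_start, self.crf_stop)
        return [[OUTPUT_TAGS[k] for k in path] for path in paths]

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint (arrays + embedded config + vocabulary)."""
        meta = {"config": asdict(self.config), "vocab": self.vocab.itos}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **self.parameters())

    @classmethod
    def load(cls, path) -> "RelationTagger":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ModelConfig(**meta["config"])
        vocab = Vocabulary.__new__(Vocabulary)
        vocab.itos = meta["vocab"]
        vocab.stoi = {t: i for i, t in enumerate(vocab.itos)}
        model = cls(config, vocab, seed=0)
        for name, arr in model.parameters().items():
            arr[...] = data[name]
        return model
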