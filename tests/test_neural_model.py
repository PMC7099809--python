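"""Network components: LSTM cell vs a scalar transcription, the two
feature extractors, the entity-detector head, emissions, gradients."""

import numpy as np
import pytest

from docrel.instance_builder import build_instances
from docrel.layers import LSTMParams, lstm_forward, lstm_step, softmax
from docrel.neural_model import (Batch, ModelConfig, RelationTagger,
                                 Vocabulary, endet_forward, load_embeddings,
                                 make_batch)
from docrel.synthetic_corpus import GenConfig, generate


def scalar_lstm_step(x, h_prev, c_prev, p):
    """Independent loop-based transcription of the gated cell equations:
    i/f/o = sigma(W_i* x + b_i* + W_h* h + b_h*), g = tanh(...),
    c = f*c_prev + i*g, h = o*tanh(c), all elementwise."""
    H = p.hidden

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    def dot(W, v):
        return [sum(W[r][c] * v[c] for c in range(len(v)))
                for r in range(len(W))]

    i = [sig(a + b + c_ + d) for a, b, c_, d in
         zip(dot(p.W_ii, x), p.b_ii, dot(p.W_hi, h_prev), p.b_hi)]
    f = [sig(a + b + c_ + d) for a, b, c_, d in
         zip(dot(p.W_if, x), p.b_if, dot(p.W_hf, h_prev), p.b_hf)]
    g = [np.tanh(a + b + c_ + d) for a, b, c_, d in
         zip(dot(p.W_ig, x), p.b_ig, dot(p.W_hg, h_prev), p.b_hg)]
    o = [sig(a + b + c_ + d) for a, b, c_, d in
         zip(dot(p.W_io, x), p.b_io, dot(p.W_ho, h_prev), p.b_ho)]
    c = [ff * cc + ii * gg for ff, cc, ii, gg in zip(f, c_prev, i, g)]
    h = [oo * np.tanh(cc) for oo, cc in zip(o, c)]
    return np.array(h), np.array(c)


class TestLSTMCell:
    def test_zero_parameters_give_zero_state(self):
        p = LSTMParams(4, 3)
        h, c = lstm_step(np.ones(4), np.zeros(3), np.zeros(3), p)
        # i = f = o = 0.5 and g = 0 force c = 0 and h = 0
        np.testing.assert_allclose(c, 0.0)
        np.testing.assert_allclose(h, 0.0)

    def test_memory_preservation_limit(self):
        p = LSTMParams(4, 3)
        p.b_hf[:] = 100.0   # forget gate saturated open
        p.b_ii[:] = -100.0  # input gate saturated shut
        c_prev = np.array([0.3, -1.2, 2.5])
        _, c = lstm_step(np.ones(4), np.zeros(3), c_prev, p)
        np.testing.assert_allclose(c, c_prev, atol=1e-8)

    def test_matches_scalar_transcription(self, rng):
        for _ in range(20):
            p = LSTMParams(4, 3, rng)
            p.bx[:] = rng.normal(0, 1, 12)
            p.bh[:] = rng.normal(0, 1, 12)
            x = rng.normal(0, 1, 4)
            h0 = rng.normal(0, 1, 3)
            c0 = rng.normal(0, 1, 3)
            h, c = lstm_step(x, h0, c0, p)
            hs, cs = scalar_lstm_step(x, h0, c0, p)
            np.testing.assert_allclose(h, hs, atol=1e-10)
            np.testing.assert_allclose(c, cs, atol=1e-10)


@pytest.fixture(scope="module")
def tiny_setup():
    docs = generate(GenConfig(n_docs=4, seed=9))
    insts = [i for doc in docs for i in build_instances(doc)]
    vocab = Vocabulary.build(insts)
    cfg = ModelConfig(word_emb_dim=6, type_emb_dim=3, de_hidden=4,
                      he_bottom_hidden=3, he_top_hidden=4,
                      dropout_emb=0.0, dropout_bottom=0.0)
    model = RelationTagger(cfg, vocab, seed=1)
    return docs, insts, vocab, cfg, model


class TestEncoders:
    def test_document_encoder_dims(self, tiny_setup):
        _, insts, vocab, cfg, model = tiny_setup
        batch = make_batch(insts[:3], vocab)
        x, _ = model.embed(batch, train=False)
        h, _ = model.encode_document(x, batch.mask)
        assert h.shape == (x.shape[0], 3, 2 * cfg.de_hidden)

    def test_direction_symmetry(self, rng):
        """Reversing the input and swapping the directional parameters
        swaps the forward/backward halves (time-reversed)."""
        p_f = LSTMParams(5, 4, rng)
        p_b = LSTMParams(5, 4, rng)
        x = rng.normal(0, 1, (7, 1, 5))
        mask = np.ones((7, 1))
        hf, _ = lstm_forward(x, mask, p_f, reverse=False)
        hb, _ = lstm_forward(x, mask, p_b, reverse=True)
        hf2, _ = lstm_forward(x[::-1], mask, p_b, reverse=False)
        hb2, _ = lstm_forward(x[::-1], mask, p_f, reverse=True)
        np.testing.assert_allclose(hb, hf2[::-1], atol=1e-12)
        np.testing.assert_allclose(hf, hb2[::-1], atol=1e-12)

    def test_single_token_document(self, tiny_setup):
        _, insts, vocab, cfg, model = tiny_setup
        inst = insts[0]
        batch = make_batch([inst], vocab)
        x, _ = model.embed(batch, train=False)
        h, _ = model.encode_document(x, batch.mask)
        # the t=0 forward state depends only on x_0
        hf0, _ = lstm_forward(x[:1], batch.mask[:1], model.de_f)
        np.testing.assert_allclose(h[0, :, :cfg.de_hidden], hf0[0],
                                   atol=1e-12)

    def test_hierarchical_sentence_locality(self, tiny_setup):
        """Permuting tokens inside sentence 2 leaves the bottom Bi-LSTM
        outputs of sentence 1 unchanged."""
        _, insts, vocab, cfg, model = tiny_setup
        inst = next(i for i in insts if len(i.sentence_spans) >= 3)
        batch = make_batch([inst], vocab)
        x, _ = model.embed(batch, train=False)
        _, cache = model.encode_hierarchical(x, batch, train=False)
        s1 = inst.sentence_spans[1]
        s2 = inst.sentence_spans[2]
        x2 = x.copy()
        seg = x2[s2[0]:s2[1] - 1, 0].copy()  # keep <eos> in place
        x2[s2[0]:s2[1] - 1, 0] = seg[::-1]
        _, cache2 = model.encode_hierarchical(x2, batch, train=False)
        np.testing.assert_allclose(
            cache["hf"][:, 1, :], cache2["hf"][:, 1, :], atol=1e-12)
        np.testing.assert_allclose(
            cache["hb"][:, 1, :], cache2["hb"][:, 1, :], atol=1e-12)

    def test_one_sentence_doc_bottom_equals_whole_sequence(self, tiny_setup):
        """With a single sentence, the per-sentence bottom Bi-LSTM is the
        same as running it over the whole token sequence."""
        _, insts, vocab, cfg, model = tiny_setup
        inst = insts[0]
        one = type(inst)(
            doc_id=inst.doc_id, source_concept_id=inst.source_concept_id,
            source_entity_type=inst.source_entity_type,
            tokens=inst.tokens, types=inst.types,
            gold_tags=inst.gold_tags,
            sentence_spans=[(0, len(inst.tokens))],
            endet_labels=[1], token_concept_ids=inst.token_concept_ids,
            token_entity_types=inst.token_entity_types)
        batch = make_batch([one], vocab)
        x, _ = model.embed(batch, train=False)
        _, cache = model.encode_hierarchical(x, batch, train=False)
        hf_direct, _ = lstm_forward(x, batch.mask, model.bot_f)
        np.testing.assert_allclose(cache["hf"][:, 0, :], hf_direct[:, 0, :],
                                   atol=1e-12)


class TestEnDetHead:
    def test_zero_head_uniform(self, rng):
        hf = rng.normal(0, 1, (4, 2, 3))
        hb = rng.normal(0, 1, (4, 2, 3))
        probs, _ = endet_forward(hf, hb, np.array([4, 2]), np.zeros((3, 6)),
                                 np.zeros(3))
        np.testing.assert_allclose(probs, 1.0 / 3.0, atol=1e-12)

    def test_matches_hand_computed_softmax(self, rng):
        hf = rng.normal(0, 1, (5, 1, 2))
        hb = rng.normal(0, 1, (5, 1, 2))
        Wo = rng.normal(0, 1, (3, 4))
        bo = rng.normal(0, 1, 3)
        lengths = np.array([3])
        probs, s = endet_forward(hf, hb, lengths, Wo, bo)
        expect_s = np.concatenate([hf[2, 0], hb[0, 0]])
        np.testing.assert_allclose(s[0], expect_s, atol=1e-12)
        logits = Wo @ expect_s + bo
        expect = np.exp(logits) / np.exp(logits).sum()
        np.testing.assert_allclose(probs[0], expect, atol=1e-9)
        assert probs.sum(axis=1) == pytest.approx(1.0, abs=1e-9)


class TestEmissionsAndDeterminism:
    def test_zero_projection_zero_emissions(self, tiny_setup):
        _, insts, vocab, cfg, model = tiny_setup
        batch = make_batch(insts[:2], vocab)
        model.Wp[...] = 0.0
        model.bp[...] = 0.0
        em, _ = model.forward(batch, train=False)
        assert em.shape == (batch.mask.shape[0], 2, cfg.n_tags)
        np.testing.assert_allclose(em, 0.0)
        model2 = RelationTagger(cfg, vocab, seed=1)
        for k, v in model.parameters().items():
            v[...] = model2.parameters()[k]

    def test_eval_mode_deterministic(self, tiny_setup):
        _, insts, vocab, cfg, model = tiny_setup
        batch = make_batch(insts[:3], vocab)
        em1, _ = model.forward(batch, train=False)
        em2, _ = model.forward(batch, train=False)
        assert np.array_equal(em1, em2)
        assert model.decode(batch) == model.decode(batch)

    def test_train_mode_dropout_differs(self, tiny_setup):
        docs, insts, vocab, _, _ = tiny_setup
        cfg = ModelConfig(word_emb_dim=6, type_emb_dim=3, de_hidden=4,
                          he_bottom_hidden=3, he_top_hidden=4,
                          dropout_emb=0.5, dropout_bottom=0.5)
        model = RelationTagger(cfg, vocab, seed=1)
        batch = make_batch(insts[:2], vocab)
        rng = np.random.default_rng(0)
        em1, _ = model.forward(batch, train=True, rng=rng)
        em2, _ = model.forward(batch, train=True, rng=rng)
        assert not np.array_equal(em1, em2)

    def test_padding_invariance_end_to_end(self, tiny_setup):
        _, insts, vocab, cfg, model = tiny_setup
        short = min(insts, key=len)
        long = max(insts, key=len)
        alone = model.decode(make_batch([short], vocab))[0]
        padded = model.decode(make_batch([short, long], vocab))[0]
        assert alone == padded


class TestGradients:
    def test_full_model_gradient_check(self):
        """Numerical vs analytic gradients on a small instance, all
        parameter groups, hidden sizes 2."""
        docs = generate(GenConfig(n_docs=1, seed=3,
                                  entities_per_doc=(2, 2),
                                  relations_per_doc=(1, 1)))
        insts = build_instances(docs[0])
        vocab = Vocabulary.build(insts)
        cfg = ModelConfig(word_emb_dim=3, type_emb_dim=2, de_hidden=2,
                          he_bottom_hidden=2, he_top_hidden=2,
                          dropout_emb=0.0, dropout_bottom=0.0)
        model = RelationTagger(cfg, vocab, seed=5)
        batch = make_batch(insts[:2], vocab)
        _, grads = model.loss_and_grads(batch, train=False)
        rng = np.random.default_rng(1)
        params = model.parameters()
        eps = 1e-6
        for name, arr in params.items():
            if name in ("Wo", "bo"):
                continue  # entity-detector head: not part of the CRF loss
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                if name == "word_emb" and idx[0] == 0:
                    continue  # <pad> row is pinned to zero
                old = arr[idx]
                arr[idx] = old + eps
                lp, _ = model.loss_and_grads(batch, train=False)
                arr[idx] = old - eps
                lm, _ = model.loss_and_grads(batch, train=False)
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grads[name][idx], rel=1e-4,
                                            abs=1e-7), name


class TestAblationsAndIO:
    def test_de_only_reduces_feature_dim(self, tiny_setup):
        _, insts, vocab, _, _ = tiny_setup
        cfg = ModelConfig(word_emb_dim=6, type_emb_dim=3, de_hidden=4,
                          he_bottom_hidden=3, he_top_hidden=4, use_he=False,
                          use_endet=False, dropout_emb=0.0,
                          dropout_bottom=0.0)
        model = RelationTagger(cfg, vocab, seed=1)
        assert cfg.feature_dim == 8
        batch = make_batch(insts[:2], vocab)
        loss, grads = model.loss_and_grads(batch, train=False)
        assert np.isfinite(loss)
        assert not any(k.startswith("top_") for k in grads)

    def test_both_extractors_disabled_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(use_de=False, use_he=False)

    def test_checkpoint_round_trip(self, tiny_setup, tmp_path):
        _, insts, vocab, cfg, model = tiny_setup
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = RelationTagger.load(path)
        batch = make_batch(insts[:3], vocab)
        assert loaded.decode(batch) == model.decode(batch)
        for k, v in model.parameters().items():
            np.testing.assert_array_equal(v, loaded.parameters()[k])

    def test_embedding_file_loading(self, tiny_setup, tmp_path):
        _, _, vocab, _, _ = tiny_setup
        tok = vocab.itos[5]
        path = tmp_path / "emb.txt"
        vec = " ".join(str(i / 10) for i in range(6))
        path.write_text(f"{tok} {vec}\nunseen-token {vec}\n")
        mat = np.zeros((len(vocab), 6))
        hits = load_embeddings(path, vocab, mat)
        assert hits == 1
        np.testing.assert_allclose(mat[5], np.arange(6) / 10)
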