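"""Two-stage optimization of the relation tagger.

Stage 1 pre-trains the bottom (sentence-level) Bi-LSTM together with the
entity detector on per-sentence 3-class cross-entropy, baking
entity-location features into the shared bottom weights.  Stage 2 trains
the full network — both feature extractors, the projection and the CRF —
on sequence negative log-likelihood with Adam.  After each stage-2 epoch
the model is evaluated end-to-end on the development set (full Viterbi
decode, bidirectional confirmation, document-level F1) and the
best-on-dev parameters are kept.

By default the entity-detector loss is NOT continued in stage 2: EnDet
influences the final model only through the shared bottom Bi-LSTM
initialization and its continued fine-tuning (``joint_endet_weight`` adds
it back as a weighted auxiliary loss if desired).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .corpus_io import DocumentRecord
from .decoder_eval import EvalReport, RelationPrediction, decode_document, evaluate
from .instance_builder import LabeledInstance, build_instances
from .layers import Adam, clip_gradients
from .neural_model import Batch, ModelConfig, RelationTagger, Vocabulary, make_batch

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults: Adam with learning rate 0.001, mini-batch size 32,
    gradient-norm clipping at 5.0, model selection on document-level dev
    F1.  ``dev_fraction`` is used to carve a development split out of the
    training documents when none is supplied.
    """

    lr: float = 0.001
    batch_size: int = 32
    epochs_stage1: int = 10
    epochs_stage2: int = 30
    clip_norm: float = 5.0
    seed: int = 0
    dev_fraction: float = 0.2
    joint_endet_weight: float = 0.0
    confirm_mode: str = "intersection"

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("lr and batch_size must be positive")


@dataclass
class TrainResult:
    model: RelationTagger
    best_epoch: int
    best_f1: float
    dev_report: EvalReport | None
    history: dict = field(default_factory=dict)


def instances_for_docs(docs: list[DocumentRecord], with_gold: bool = True
                       ) -> dict[str, list[LabeledInstance]]:
    return {doc.doc_id: build_instances(doc, with_gold=with_gold)
            for doc in docs}


def _batches(instances: list[LabeledInstance], vocab: Vocabulary,
             batch_size: int, order: np.ndarray | None = None):
    idx = np.arange(len(instances)) if order is None else order
    for i in range(0, len(idx), batch_size):
        yield make_batch([instances[j] for j in idx[i:i + batch_size]], vocab)


def predict_pairs(model: RelationTagger, docs: list[DocumentRecord],
                  batch_size: int = 32, confirm_mode: str = "intersection"
                  ) -> set[RelationPrediction]:
    """Decode every instance of every document and confirm pairs."""
    per_doc = instances_for_docs(docs, with_gold=False)
    predictions: set[RelationPrediction] = set()
    flat: list[LabeledInstance] = [i for doc in docs for i in per_doc[doc.doc_id]]
    tags_by_key: dict[tuple[str, str], list[str]] = {}
    for batch in _batches(flat, model.vocab, batch_size):
        for inst, tags in zip(batch.instances, model.decode(batch)):
            tags_by_key[(inst.doc_id, inst.source_concept_id)] = tags
    for doc in docs:
        insts = per_doc[doc.doc_id]
        if not insts:
            continue
        tag_seqs = [tags_by_key[(i.doc_id, i.source_concept_id)]
                    for i in insts]
        predictions |= decode_document(insts, tag_seqs, mode=confirm_mode)
    return predictions


def evaluate_model(model: RelationTagger, docs: list[DocumentRecord],
                   batch_size: int = 32,
                   confirm_mode: str = "intersection") -> EvalReport:
    """End-to-end document-level evaluation (decode + confirm + score)."""
    preds = predict_pairs(model, docs, batch_size, confirm_mode)
    return evaluate(preds, docs)


def pretrain_endet(model: RelationTagger, instances: list[LabeledInstance],
                   config: TrainConfig) -> dict:
    """Stage 1: sentence cross-entropy for the bottom Bi-LSTM + EnDet.

    Returns a history dict with per-epoch mean loss and sentence accuracy.
    """
    insts = [i for i in instances if i.endet_labels]
    if not insts or not any(i.sentence_spans for i in insts):
        raise ValueError("no labeled sentences to pre-train on")
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    history: dict = {"loss": [], "accuracy": []}
    for epoch in range(config.epochs_stage1):
        order = rng.permutation(len(insts))
        losses, n_sent, n_hit = [], 0, 0
        for batch in _batches(insts, model.vocab, config.batch_size, order):
            loss, grads = model.endet_loss_and_grads(batch, train=True,
                                                     rng=rng)
            clip_gradients(grads, config.clip_norm)
            opt.step(grads)
            losses.append(loss)
            pred = model.endet_predict(batch)
            n_sent += batch.n_sent
            n_hit += int(np.sum(pred - 1 == batch.endet_labels))
        history["loss"].append(float(np.mean(losses)))
        history["accuracy"].append(n_hit / n_sent)
        logger.info("stage1 epoch %d: loss %.4f acc %.3f", epoch + 1,
                    history["loss"][-1], history["accuracy"][-1])
    return history


def train(train_docs: list[DocumentRecord],
          dev_docs: list[DocumentRecord] | None,
          model_config: ModelConfig, config: TrainConfig,
          skip_pretrain: bool = False) -> TrainResult:
    """Full two-stage training with best-on-dev model selection."""
    if not train_docs:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    if dev_docs is None:
        n_dev = max(1, int(round(config.dev_fraction * len(train_docs))))
        order = rng.permutation(len(train_docs))
        dev_docs = [train_docs[i] for i in order[:n_dev]]
        train_docs = [train_docs[i] for i in order[n_dev:]]
        if not train_docs:
            raise ValueError("dev split consumed all training documents")

    train_insts = [i for doc in train_docs
                   for i in build_instances(doc, with_gold=True)]
    if not train_insts:
        raise ValueError("training documents contain no entities")
    vocab = Vocabulary.build(train_insts)
    model = RelationTagger(model_config, vocab, seed=config.seed)

    history: dict = {"stage1": None, "loss": [], "dev_f1": [],
                     "dev_precision": [], "dev_recall": []}
    if model_config.use_endet and not skip_pretrain:
        history["stage1"] = pretrain_endet(model, train_insts, config)

    opt = Adam(model.parameters(), lr=config.lr)
    best_f1, best_epoch = -1.0, -1
    best_params = {k: v.copy() for k, v in model.parameters().items()}
    for epoch in range(config.epochs_stage2):
        order = rng.permutation(len(train_insts))
        losses = []
        for batch in _batches(train_insts, vocab, config.batch_size, order):
            loss, grads = model.loss_and_grads(batch, train=True, rng=rng)
            if config.joint_endet_weight > 0 and model_config.use_endet:
                eloss, egrads = model.endet_loss_and_grads(batch, train=True,
                                                           rng=rng)
                loss += config.joint_endet_weight * eloss
                for k, g in egrads.items():
                    grads[k] = grads.get(k, 0) + config.joint_endet_weight * g
            clip_gradients(grads, config.clip_norm)
            opt.step(grads)
            losses.append(loss)
        report = evaluate_model(model, dev_docs, config.batch_size,
                                config.confirm_mode)
        history["loss"].append(float(np.mean(losses)))
        history["dev_f1"].append(report.f1)
        history["dev_precision"].append(report.precision)
        history["dev_recall"].append(report.recall)
        logger.info("stage2 epoch %d: loss %.4f dev P %.3f R %.3f F1 %.3f",
                    epoch + 1, history["loss"][-1], report.precision,
                    report.recall, report.f1)
        if report.f1 > best_f1:
            best_f1, best_epoch = report.f1, epoch + 1
            best_params = {k: v.copy() for k, v in model.parameters().items()}
    for k, v in model.parameters().items():
        v[...] = best_params[k]
    dev_report = evaluate_model(model, dev_docs, config.batch_size,
                                config.confirm_mode)
    return TrainResult(model=model, best_epoch=best_epoch, best_f1=best_f1,
                       dev_report=dev_report, history=history)


def run_replicates(train_docs: list[DocumentRecord],
                   dev_docs: list[DocumentRecord] | None,
                   eval_docs: list[DocumentRecord],
                   model_config: ModelConfig, config: TrainConfig,
                   n_seeds: int) -> dict:
    """Train once per seed; report mean and standard deviation of P/R/F1.

    Seeds are ``config.seed, config.seed + 1, ...``; metrics are measured
    on ``eval_docs`` with the trained (best-on-dev) model of each run.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    runs = []
    for s in range(n_seeds):
        cfg = TrainConfig(**{**asdict(config), "seed": config.seed + s})
        result = train(train_docs, dev_docs, model_config, cfg)
        rep = evaluate_model(result.model, eval_docs, cfg.batch_size,
                             cfg.confirm_mode)
        runs.append({"seed": cfg.seed, "precision": rep.precision,
                     "recall": rep.recall, "f1": rep.f1})
    out: dict = {"runs": runs, "n_seeds": n_seeds}
    for metric in ("precision", "recall", "f1"):
        vals = np.array([r[metric] for r in runs])
        out[f"mean_{metric}"] = float(vals.mean())
        out[f"sd_{metric}"] = float(vals.std())
    return out
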