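"""Training loops: ReLoRA pre-training, LoRA fine-tuning, metrics, LOCOCV.

Pre-training runs the causal-LM objective full-rank for a warm start, then
switches the seven projection matrices of every block to LoRA adapters and
periodically *restarts*: adapters are merged into the frozen base, A is
re-initialized (Kaiming) and B zeroed, the adapters' Adam moments are
pruned, and the learning rate re-warms from zero — the "downward spikes"
on top of a cosine decay.  Fine-tuning attaches the 2-class head, trains
adapters + head only under a linearly decaying rate, and keeps the best
validation checkpoint.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .dataset_builder import DatasetConfig, build_dataset, lococv_splits
from .genome_io import CagePeak, Genome
from .model_core import (
    LlamaModel,
    ModelConfig,
    Param,
    causal_lm_loss_and_grad,
    classification_loss_and_grad,
    softmax,
)
from .tokenizer import BpeVocab, bpe_encode, make_word_corpus, Encoding

logger = logging.getLogger(__name__)

__all__ = [
    "ReloraSchedule",
    "TrainConfig",
    "Metrics",
    "AdamOptimizer",
    "TokenizedSample",
    "encode_samples",
    "lr_pretrain",
    "lr_finetune",
    "relora_restart",
    "pretrain",
    "finetune",
    "evaluate",
    "predict",
    "lococv_run",
]


@dataclass
class ReloraSchedule:
    """Warm start, restart cadence and LR shape for ReLoRA pre-training."""

    warm_start_steps: int = 1000  # full-rank steps before adapter mode
    restart_interval: int = 100  # steps between adapter merges
    adapter_warmup_steps: int = 20  # LR re-warm after each restart
    optimizer_prune_fraction: float = 1.0
    total_steps: int = 2000
    warmup_steps: int = 50  # initial linear LR warmup
    peak_lr: float = 1e-3
    min_lr: float = 0.0
    lora_rank: int = 8
    lora_alpha: float = 16.0

    def __post_init__(self):
        if self.warm_start_steps < 0:
            raise ValueError("warm_start_steps must be >= 0")
        if self.restart_interval <= self.adapter_warmup_steps:
            raise ValueError("restart_interval must exceed adapter_warmup_steps")


@dataclass
class TrainConfig:
    """Optimizer and batch settings.

    Defaults mirror the full-scale protocol (Adam beta1 0.9 / beta2 0.999 /
    eps 1e-8, fine-tune batch 64 at peak LR 5e-5 linearly decayed over 5
    epochs, pre-train batch 8).  ``desk_scale()`` returns settings sized
    for a tiny model trained from scratch on a CPU, where the full-scale
    fine-tuning rate is far below what a fresh model needs.
    """

    pretrain_batch_size: int = 8
    finetune_batch_size: int = 64
    epochs: int = 5
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    finetune_peak_lr: float = 5e-5
    finetune_lora_rank: int = 8
    finetune_lora_alpha: float = 16.0
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("pretrain_batch_size", "finetune_batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        return cls(
            pretrain_batch_size=8,
            finetune_batch_size=16,
            epochs=12,
            finetune_peak_lr=5e-3,
            seed=seed,
        )


@dataclass
class Metrics:
    """Binary classification metrics; the positive class is label 1."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "Metrics":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


# ---------------------------------------------------------------------------
# optimizer


class AdamOptimizer:
    """Adam with global-norm gradient clipping over trainable parameters."""

    def __init__(
        self,
        named_params: list[tuple[str, Param]],
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        grad_clip: float = 1.0,
    ):
        self.named_params = list(named_params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.grad_clip = grad_clip
        self.state: dict[str, dict[str, np.ndarray]] = {}
        self.t = 0

    def register(self, named_params: list[tuple[str, Param]]) -> None:
        existing = {id(p) for _, p in self.named_params}
        for name, p in named_params:
            if id(p) not in existing:
                self.named_params.append((name, p))

    def _state_for(self, name: str, p: Param) -> dict[str, np.ndarray]:
        st = self.state.get(name)
        if st is None or st["m"].shape != p.data.shape:
            st = {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data)}
            self.state[name] = st
        return st

    def step(self, lr: float) -> None:
        self.t += 1
        trainables = [(n, p) for n, p in self.named_params if p.trainable]
        if self.grad_clip:
            sq = sum(float(np.sum(p.grad**2)) for _, p in trainables)
            norm = math.sqrt(sq)
            scale = min(1.0, self.grad_clip / (norm + 1e-12))
        else:
            scale = 1.0
        b1, b2 = self.beta1, self.beta2
        for name, p in trainables:
            st = self._state_for(name, p)
            g = p.grad * scale
            st["m"] = b1 * st["m"] + (1 - b1) * g
            st["v"] = b2 * st["v"] + (1 - b2) * g * g
            mhat = st["m"] / (1 - b1**self.t)
            vhat = st["v"] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def prune_state(self, names: list[str], fraction: float) -> None:
        """Zero the smallest-magnitude ``fraction`` of moment entries."""
        for name in names:
            st = self.state.get(name)
            if st is None:
                continue
            for key in ("m", "v"):
                arr = st[key]
                if fraction >= 1.0:
                    arr[...] = 0.0
                    continue
                flat = np.abs(arr).ravel()
                k = int(fraction * flat.size)
                if k == 0:
                    continue
                thresh = np.partition(flat, k - 1)[k - 1]
                arr[np.abs(arr) <= thresh] = 0.0


# ---------------------------------------------------------------------------
# learning-rate schedules


def lr_pretrain(step: int, schedule: ReloraSchedule) -> float:
    """Linear warmup, cosine decay, and a drop-to-zero re-warm ("downward
    spike") after every ReLoRA restart."""
    if step < 0:
        raise ValueError("step must be >= 0")
    s = schedule
    if s.warmup_steps > 0 and step < s.warmup_steps:
        base = s.peak_lr * step / s.warmup_steps
    else:
        span = max(1, s.total_steps - s.warmup_steps)
        progress = min(1.0, (step - s.warmup_steps) / span)
        base = s.min_lr + 0.5 * (s.peak_lr - s.min_lr) * (1 + math.cos(math.pi * progress))
    if s.restart_interval and step >= s.warm_start_steps + s.restart_interval:
        since = (step - s.warm_start_steps) % s.restart_interval
        base *= min(1.0, since / max(1, s.adapter_warmup_steps))
    return base


def lr_finetune(step: int, total_steps: int, peak: float = 5e-5) -> float:
    """Linear decay from ``peak`` at step 0 to 0 at ``total_steps``."""
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    return peak * (1 - step / total_steps) if total_steps else 0.0


# ---------------------------------------------------------------------------
# ReLoRA restart


def relora_restart(
    model: LlamaModel,
    optimizer: AdamOptimizer,
    rng: np.random.Generator,
    prune_fraction: float = 1.0,
) -> None:
    """Merge adapters into the base, re-init them, prune optimizer moments.

    The model's function is unchanged: merging adds s*A@B to W, and the
    fresh adapters contribute zero (B = 0).
    """
    adapter_names = [
        name
        for name, p in model.params()
        if name.endswith(".A") or name.endswith(".B")
    ]
    for lin in model.lora_linears():
        if lin.adapters_enabled:
            lin.merge_adapters()
            lin.reinit_adapters(rng)
    optimizer.prune_state(adapter_names, prune_fraction)


# ---------------------------------------------------------------------------
# tokenized samples and batching


@dataclass
class TokenizedSample:
    """A labelled window together with its token ids and span map."""

    ids: list[int]
    label: int
    sequence: str
    chrom: str
    encoding: Encoding


def encode_samples(
    samples, vocab: BpeVocab, offsets: tuple[int, ...] = (0, 1, 2, 3)
) -> list[TokenizedSample]:
    out = []
    for s in samples:
        enc = bpe_encode(make_word_corpus(s.sequence, offsets), vocab)
        out.append(
            TokenizedSample(
                ids=enc.ids,
                label=s.label,
                sequence=s.sequence,
                chrom=s.chrom,
                encoding=enc,
            )
        )
    return out


def _pad_batch(id_lists: list[list[int]], pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([len(ids) for ids in id_lists])
    T = int(lens.max())
    ids = np.full((len(id_lists), T), pad_id, dtype=np.int64)
    for i, row in enumerate(id_lists):
        ids[i, : len(row)] = row
    return ids, lens


# ---------------------------------------------------------------------------
# pre-training


def make_lm_chunks(
    token_streams: list[list[int]], seq_len: int
) -> np.ndarray:
    """Concatenate token streams and cut contiguous fixed-length chunks."""
    flat = np.concatenate([np.asarray(s, dtype=np.int64) for s in token_streams])
    n = len(flat) // seq_len
    if n == 0:
        raise ValueError("corpus shorter than one LM chunk")
    return flat[: n * seq_len].reshape(n, seq_len)


def pretrain(
    model: LlamaModel,
    token_streams: list[list[int]],
    train_config: TrainConfig,
    schedule: ReloraSchedule,
    seq_len: int = 128,
    val_fraction: float = 0.1,
) -> tuple[LlamaModel, dict[str, list]]:
    """Causal-LM pre-training with the ReLoRA schedule.

    Full-rank for ``warm_start_steps``, then adapter-mode with a restart
    every ``restart_interval`` steps.  Returns the model and a trace with
    per-step training loss and periodic validation loss.  Deterministic
    under ``train_config.seed``.
    """
    if not token_streams or all(len(s) == 0 for s in token_streams):
        raise ValueError("empty pre-training corpus")
    rng = np.random.default_rng(train_config.seed)
    chunks = make_lm_chunks(token_streams, seq_len)
    n_val = max(1, int(val_fraction * len(chunks))) if len(chunks) > 1 else 0
    perm = rng.permutation(len(chunks))
    val_chunks = chunks[perm[:n_val]]
    train_chunks = chunks[perm[n_val:]] if n_val else chunks

    optimizer = AdamOptimizer(
        model.params(),
        train_config.beta1,
        train_config.beta2,
        train_config.eps,
        train_config.grad_clip,
    )
    trace: dict[str, list] = {"step": [], "lr": [], "train_loss": [], "val": []}
    bsz = train_config.pretrain_batch_size
    in_adapter_mode = False

    for step in range(schedule.total_steps):
        if not in_adapter_mode and step >= schedule.warm_start_steps:
            model.enable_lora(schedule.lora_rank, schedule.lora_alpha, rng)
            optimizer.register(model.params())
            in_adapter_mode = True
        if (
            in_adapter_mode
            and step > schedule.warm_start_steps
            and (step - schedule.warm_start_steps) % schedule.restart_interval == 0
        ):
            relora_restart(model, optimizer, rng, schedule.optimizer_prune_fraction)

        idx = rng.integers(0, len(train_chunks), size=min(bsz, len(train_chunks)))
        batch = train_chunks[idx]
        model.zero_grad()
        logits = model.forward_lm(batch)
        loss, dlogits = causal_lm_loss_and_grad(logits, batch)
        model.backward_lm(dlogits)
        lr = lr_pretrain(step, schedule)
        optimizer.step(lr)
        trace["step"].append(step)
        trace["lr"].append(lr)
        trace["train_loss"].append(loss)
        if n_val and (step % 50 == 0 or step == schedule.total_steps - 1):
            vl = _lm_eval_loss(model, val_chunks, bsz)
            trace["val"].append((step, vl))
            logger.info("pretrain step %d: train %.4f val %.4f", step, loss, vl)
    return model, trace


def _lm_eval_loss(model: LlamaModel, chunks: np.ndarray, bsz: int) -> float:
    losses, weights = [], []
    for i in range(0, len(chunks), bsz):
        batch = chunks[i : i + bsz]
        loss, _ = causal_lm_loss_and_grad(model.forward_lm(batch), batch)
        losses.append(loss)
        weights.append(len(batch))
    return float(np.average(losses, weights=weights))


# ---------------------------------------------------------------------------
# fine-tuning, prediction, evaluation


def _snapshot(model: LlamaModel) -> dict[str, np.ndarray]:
    return {name: p.data.copy() for name, p in model.params()}


def _restore(model: LlamaModel, snap: dict[str, np.ndarray]) -> None:
    for name, p in model.params():
        p.data[...] = snap[name]


def finetune(
    model: LlamaModel,
    train: list[TokenizedSample],
    val: list[TokenizedSample],
    train_config: TrainConfig,
    pad_id: int = 0,
) -> tuple[LlamaModel, dict[str, list]]:
    """LoRA fine-tuning for binary classification.

    Existing (pre-training) adapters are first merged into the base; fresh
    adapters plus the classification head are the only trainable
    parameters.  The learning rate decays linearly from the configured
    peak; the checkpoint with the best validation loss at an epoch
    boundary is returned.
    """
    if not train:
        raise ValueError("empty fine-tuning set")
    rng = np.random.default_rng(train_config.seed + 1)
    for lin in model.lora_linears():
        if lin.adapters_enabled:
            lin.merge_adapters()
    model.enable_lora(
        train_config.finetune_lora_rank, train_config.finetune_lora_alpha, rng
    )
    model.set_trainable(
        lambda name: name.endswith((".A", ".B")) or name.startswith("cls_head")
    )

    n_trainable = sum(p.data.size for _, p in model.params() if p.trainable)
    n_total = sum(p.data.size for _, p in model.params())
    logger.info(
        "fine-tuning %d of %d parameters (%.1f%%)",
        n_trainable, n_total, 100.0 * n_trainable / n_total,
    )

    optimizer = AdamOptimizer(
        model.params(),
        train_config.beta1,
        train_config.beta2,
        train_config.eps,
        train_config.grad_clip,
    )
    bsz = train_config.finetune_batch_size
    steps_per_epoch = math.ceil(len(train) / bsz)
    total_steps = steps_per_epoch * train_config.epochs
    history: dict[str, list] = {"train_loss": [], "val_loss": [], "val_acc": []}
    best = (math.inf, _snapshot(model))
    step = 0
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(train))
        for i in range(0, len(order), bsz):
            batch = [train[j] for j in order[i : i + bsz]]
            ids, lens = _pad_batch([b.ids for b in batch], pad_id)
            labels = np.array([b.label for b in batch])
            model.zero_grad()
            logits = model.forward_cls(ids, lens)
            loss, dlogits = classification_loss_and_grad(logits, labels)
            model.backward_cls(dlogits)
            optimizer.step(lr_finetune(step, total_steps, train_config.finetune_peak_lr))
            history["train_loss"].append(loss)
            step += 1
        if val:
            vl, vm = _cls_eval(model, val, bsz, pad_id)
            history["val_loss"].append(vl)
            history["val_acc"].append(vm.accuracy)
            logger.info(
                "epoch %d: val loss %.4f acc %.3f", epoch, vl, vm.accuracy
            )
            if vl < best[0]:
                best = (vl, _snapshot(model))
    if val:
        _restore(model, best[1])
    return model, history


def _cls_eval(
    model: LlamaModel, data: list[TokenizedSample], bsz: int, pad_id: int
) -> tuple[float, Metrics]:
    losses, weights, preds, trues = [], [], [], []
    for i in range(0, len(data), bsz):
        batch = data[i : i + bsz]
        ids, lens = _pad_batch([b.ids for b in batch], pad_id)
        labels = np.array([b.label for b in batch])
        logits = model.forward_cls(ids, lens)
        loss, _ = classification_loss_and_grad(logits, labels)
        losses.append(loss)
        weights.append(len(batch))
        preds.extend(np.argmax(logits, axis=1).tolist())
        trues.extend(labels.tolist())
    return float(np.average(losses, weights=weights)), Metrics.from_predictions(
        trues, preds
    )


def predict(
    model: LlamaModel,
    data: list[TokenizedSample],
    batch_size: int = 16,
    pad_id: int = 0,
) -> np.ndarray:
    """Argmax class predictions (no tunable threshold)."""
    preds = []
    for i in range(0, len(data), batch_size):
        batch = data[i : i + batch_size]
        ids, lens = _pad_batch([b.ids for b in batch], pad_id)
        logits = model.forward_cls(ids, lens)
        preds.extend(np.argmax(softmax(logits, axis=-1), axis=1).tolist())
    return np.asarray(preds)


def evaluate(
    model: LlamaModel,
    data: list[TokenizedSample],
    batch_size: int = 16,
    pad_id: int = 0,
) -> Metrics:
    """Confusion-count metrics over a tokenized dataset."""
    if not data:
        raise ValueError("empty evaluation set")
    preds = predict(model, data, batch_size, pad_id)
    return Metrics.from_predictions([d.label for d in data], preds)


# ---------------------------------------------------------------------------
# LOCOCV driver


@dataclass
class LococvResult:
    fold_chroms: list[str]
    fold_metrics: list[Metrics]
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        keys = ("accuracy", "precision", "recall", "f1")
        table = {k: [m.as_dict()[k] for m in self.fold_metrics] for k in keys}
        self.mean = {k: float(np.mean(v)) for k, v in table.items()}
        self.sd = {k: float(np.std(v)) for k, v in table.items()}


def lococv_run(
    genome: Genome,
    peaks: list[CagePeak],
    dataset_config: DatasetConfig,
    vocab: BpeVocab,
    model_config: ModelConfig,
    train_config: TrainConfig,
    schedule: ReloraSchedule,
    offsets: tuple[int, ...] = (0, 1, 2, 3),
) -> LococvResult:
    """Leave-one-chromosome-out evaluation.

    A single model is pre-trained on the full corpus (as at full scale,
    where pre-training uses whole genomes); each fold then fine-tunes a
    copy on all chromosomes but one and is scored on the held-out one.
    """
    dataset = build_dataset(genome, peaks, dataset_config)
    encoded = encode_samples(dataset.samples, vocab, offsets)
    base = LlamaModel(model_config, seed=train_config.seed)
    base, _ = pretrain(
        base, [e.ids for e in encoded], train_config, schedule
    )
    fold_chroms, fold_metrics = [], []
    for train_ds, val_ds in lococv_splits(dataset):
        chrom = val_ds.samples[0].chrom
        train_enc = encode_samples(train_ds.samples, vocab, offsets)
        val_enc = encode_samples(val_ds.samples, vocab, offsets)
        model = copy.deepcopy(base)
        model, _ = finetune(model, train_enc, val_enc, train_config, vocab.pad_id)
        fold_chroms.append(chrom)
        fold_metrics.append(evaluate(model, val_enc, pad_id=vocab.pad_id))
        logger.info("fold %s: %s", chrom, fold_metrics[-1].as_dict())
    return LococvResult(fold_chroms=fold_chroms, fold_metrics=fold_metrics)
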