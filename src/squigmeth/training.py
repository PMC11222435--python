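"""Composite-loss training, auxiliary self-supervision and distillation.

The total loss is ``L = L_mod + alpha * (L_bases + L_signal + L_diversity)``:
binary cross-entropy on the modification logit, cross-entropy on masked /
flipped window bases, cross-entropy of the codebook class of masked signal
blocks (targets from the *local* block representation, predictions from the
*contextualized* one), and a diversity penalty ``log K - H(p_bar)`` keeping
batch-average codeword usage spread out.  Optimization is Adam with decoupled
weight decay at a constant learning rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .features import MASK
from .model import (
    ModelConfig,
    base_logits,
    forward_batch,
    positional_encoding,
)
from .types import SiteExample

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "LossBundle",
    "mask_bases",
    "mask_signal",
    "compute_losses",
    "train",
    "distill",
    "stratified_sample",
    "label_from_truth",
    "predict_probabilities",
    "pad_batch",
]


@dataclass
class TrainConfig:
    """Optimization and auxiliary-task hyperparameters.

    Masking rates and the codebook weight follow common masked-pretraining
    practice: 15% of bases masked, 5% flipped to a uniformly random base,
    15% of signal blocks masked against a K=64 codebook, auxiliary weight
    alpha=0.1.  Optimizer settings are the published ones: AdamW with
    lr 3e-4, weight decay 1e-4, betas (0.9, 0.999), no schedule.
    """

    p_mask: float = 0.15
    p_flip: float = 0.05
    p_signal: float = 0.15
    alpha: float = 0.1
    learning_rate: float = 3e-4
    weight_decay: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 64
    epochs: int = 1
    max_steps: int | None = None
    seed: int = 0
    soft_labels: bool = False

    def __post_init__(self) -> None:
        for name in ("p_mask", "p_flip", "p_signal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.p_mask + self.p_flip > 1.0:
            raise ValueError("p_mask + p_flip must not exceed 1")


@dataclass
class LossBundle:
    """Per-step loss components; ``total`` keeps the autodiff graph."""

    mod: float
    bases: float
    signal: float
    diversity: float
    total: Tensor
    codeword_usage: np.ndarray | None = None  # hard assignment histogram

    def as_dict(self) -> dict[str, float]:
        return {
            "L_mod": self.mod,
            "L_bases": self.bases,
            "L_signal": self.signal,
            "L_diversity": self.diversity,
            "total": float(self.total.data),
        }


# ---------------------------------------------------------------------------
# masking tasks


def mask_bases(
    tokens: np.ndarray, p_mask: float, p_flip: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """BERT-style corruption of the token window.

    An independent ``p_mask`` fraction of positions becomes [MASK]; a
    disjoint ``p_flip`` fraction is replaced by a base drawn uniformly from
    the four canonical bases.  Returns (new_tokens, altered_positions,
    original_tokens_at_those_positions); positions whose original token is
    non-canonical are altered but excluded from the targets (the base head
    has four classes).
    """
    tokens = np.asarray(tokens)
    u = rng.random(tokens.shape)
    to_mask = u < p_mask
    to_flip = (u >= p_mask) & (u < p_mask + p_flip)
    out = tokens.copy()
    out[to_mask] = MASK
    out[to_flip] = rng.integers(0, 4, size=int(to_flip.sum()))
    altered = to_mask | to_flip
    altered &= tokens < 4  # only canonical originals are predictable
    idx = np.argwhere(altered)
    targets = tokens[altered]
    return out, idx, targets


def mask_signal(
    blocks: np.ndarray,
    r: np.ndarray,
    q: np.ndarray,
    p_signal: float,
    codebook: np.ndarray,
    w_signal: np.ndarray,
    rng: np.random.Generator,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mask a fraction of signal blocks for the codebook-classification task.

    The target class of a chosen block is the argmax codeword probability of
    its *local* representation (block . W^S), computed before masking with no
    gradient; the block's samples and its r/q entries are then zeroed.
    Returns (blocks, r, q, mask_positions, targets).
    """
    if codebook.shape[1] < 2:
        raise ValueError("codebook needs at least 2 codewords")
    blocks = np.asarray(blocks, dtype=np.float64).copy()
    r = np.asarray(r).copy()
    q = np.asarray(q).copy()
    chosen = rng.random(blocks.shape[:-1]) < p_signal
    if valid is not None:
        chosen &= valid.astype(bool)
    idx = np.argwhere(chosen)
    if len(idx) == 0:
        return blocks, r, q, idx, np.empty(0, dtype=np.int64)
    local = blocks[chosen] @ w_signal            # (m, f)
    targets = np.argmax(local @ codebook, axis=-1)  # argmax of softmax = argmax of logits
    blocks[chosen] = 0.0
    r[chosen] = 0
    q[chosen] = 0
    return blocks, r, q, idx, targets


# ---------------------------------------------------------------------------
# losses


def compute_losses(
    mod_logit: Tensor,
    labels: np.ndarray,
    base_logit_rows: Tensor | None,
    base_targets: np.ndarray,
    signal_logit_rows: Tensor | None,
    signal_targets: np.ndarray,
    alpha: float,
    K: int,
) -> LossBundle:
    """Assemble the composite loss; empty auxiliary target sets contribute 0."""
    l_mod = ag.bce_with_logits(mod_logit, labels)

    if base_logit_rows is not None and len(base_targets):
        l_bases = ag.cross_entropy(base_logit_rows, base_targets)
    else:
        l_bases = Tensor(0.0)

    usage = None
    if signal_logit_rows is not None and len(signal_targets):
        l_signal = ag.cross_entropy(signal_logit_rows, signal_targets)
        probs = signal_logit_rows.softmax(axis=-1)
        p_bar = probs.mean(axis=0)
        l_diversity = ag.xlogx_sum(p_bar) + np.log(K)
        hard = np.argmax(signal_logit_rows.data, axis=-1)
        usage = np.bincount(hard, minlength=K) / len(hard)
    else:
        l_signal = Tensor(0.0)
        l_diversity = Tensor(0.0)

    total = l_mod + (l_bases + l_signal + l_diversity) * alpha
    return LossBundle(
        mod=float(l_mod.data),
        bases=float(l_bases.data),
        signal=float(l_signal.data),
        diversity=float(l_diversity.data),
        total=total,
        codeword_usage=usage,
    )


def diversity_loss(p_bar: np.ndarray) -> float:
    """log K - H(p_bar): 0 iff usage is uniform, log K for a point mass."""
    p_bar = np.asarray(p_bar, dtype=np.float64)
    k = len(p_bar)
    safe = np.where(p_bar > 0, p_bar, 1.0)
    return float(np.log(k) + np.sum(p_bar * np.log(safe)))


# ---------------------------------------------------------------------------
# batching


def pad_batch(
    examples: list[SiteExample], config: ModelConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stack examples, padding blocks to the batch maximum.

    Returns (blocks, r, q, tokens, valid_mask); padded positions carry zeros
    and are excluded from attention by the mask.
    """
    n = len(examples)
    s_max = max(len(e.blocks) for e in examples)
    b = config.block_width
    blocks = np.zeros((n, s_max, b))
    r = np.zeros((n, s_max), dtype=np.int64)
    q = np.zeros((n, s_max), dtype=np.int64)
    tokens = np.stack([e.tokens for e in examples])
    valid = np.zeros((n, s_max), dtype=bool)
    for i, e in enumerate(examples):
        s = len(e.blocks)
        blocks[i, :s] = e.blocks
        r[i, :s] = e.ref_idx
        q[i, :s] = e.query_idx
        valid[i, :s] = True
    return blocks, r, q, tokens, valid


def _stack_pos_enc(r: np.ndarray, q: np.ndarray, config: ModelConfig) -> np.ndarray:
    s = r.shape[1]
    return np.stack([positional_encoding(s, r[i], q[i], config)
                     if config.mode == "reference"
                     else positional_encoding(s, None, None, config)
                     for i in range(r.shape[0])])


# ---------------------------------------------------------------------------
# optimizer


class AdamW:
    """Adam with decoupled weight decay; decay skips biases and layer norms."""

    def __init__(self, params: dict[str, Tensor], config: TrainConfig):
        self.config = config
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, Tensor]) -> None:
        c = self.config
        self.t += 1
        b1t = 1.0 - c.beta1**self.t
        b2t = 1.0 - c.beta2**self.t
        for k, p in params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + c.adam_eps)
            if p.data.ndim > 1:  # decoupled decay on weight matrices only
                p.data *= 1.0 - c.learning_rate * c.weight_decay
            p.data -= c.learning_rate * update

    @staticmethod
    def zero_grad(params: dict[str, Tensor]) -> None:
        for p in params.values():
            p.grad = None


# ---------------------------------------------------------------------------
# training loop


def _forward_training_step(
    params: dict[str, Tensor],
    mconfig: ModelConfig,
    tconfig: TrainConfig,
    batch: list[SiteExample],
    rng: np.random.Generator,
) -> LossBundle:
    blocks, r, q, tokens, valid = pad_batch(batch, mconfig)
    labels = np.array([e.label for e in batch], dtype=np.float64)

    masked_tokens, base_idx, base_targets = mask_bases(
        tokens, tconfig.p_mask, tconfig.p_flip, rng
    )
    blocks, r, q, sig_idx, sig_targets = mask_signal(
        blocks, r, q, tconfig.p_signal,
        params["codebook"].data, params["w_signal"].data, rng, valid,
    )
    pos = _stack_pos_enc(r, q, mconfig)
    out = forward_batch(params, mconfig, blocks, pos, masked_tokens, valid,
                        rng=rng, training=True)

    base_rows = None
    if len(base_idx) and mconfig.use_decoder:
        rows = out["decoded"][(base_idx[:, 0], base_idx[:, 1])]
        base_rows = rows @ params["base_head.w"] + params["base_head.b"]
    sig_rows = None
    if len(sig_idx):
        enc_rows = out["encoded"][(sig_idx[:, 0], sig_idx[:, 1])]
        sig_rows = enc_rows @ params["codebook"]

    return compute_losses(
        out["mod_logit"], labels, base_rows, base_targets,
        sig_rows, sig_targets, tconfig.alpha, mconfig.codebook_size,
    )


def train(
    params: dict[str, Tensor],
    mconfig: ModelConfig,
    examples: list[SiteExample],
    tconfig: TrainConfig,
) -> tuple[dict[str, Tensor], list[dict[str, float]]]:
    """Seeded AdamW training over labeled (hard or soft) site examples.

    Returns the trained parameters and a per-step history of loss
    components.  Raises on non-finite loss, naming the offending component.
    """
    labeled = [e for e in examples if e.label is not None]
    if not labeled:
        raise ValueError("no labeled examples to train on")
    rng = np.random.default_rng(tconfig.seed)
    optimizer = AdamW(params, tconfig)
    history: list[dict[str, float]] = []
    step = 0
    # bucket examples of similar block count into batches to minimize padding,
    # then shuffle the batch order each epoch
    by_size = sorted(range(len(labeled)), key=lambda i: len(labeled[i].blocks))
    batches = [
        by_size[lo : lo + tconfig.batch_size]
        for lo in range(0, len(by_size), tconfig.batch_size)
    ]
    for _epoch in range(tconfig.epochs):
        for bi in rng.permutation(len(batches)):
            batch = [labeled[i] for i in batches[bi]]
            losses = _forward_training_step(params, mconfig, tconfig, batch, rng)
            record = losses.as_dict()
            if not all(np.isfinite(v) for v in record.values()):
                bad = [k for k, v in record.items() if not np.isfinite(v)]
                raise RuntimeError(f"non-finite loss at step {step}: {bad} ({record})")
            AdamW.zero_grad(params)
            losses.total.backward()
            optimizer.step(params)
            record["step"] = step
            history.append(record)
            step += 1
            if tconfig.max_steps is not None and step >= tconfig.max_steps:
                return params, history
    return params, history


# ---------------------------------------------------------------------------
# inference helpers


def predict_probabilities(
    params: dict[str, Tensor],
    mconfig: ModelConfig,
    examples: list[SiteExample],
    batch_size: int = 256,
) -> np.ndarray:
    """Deterministic per-example modification probabilities (no dropout)."""
    probs = np.empty(len(examples))
    order = sorted(range(len(examples)), key=lambda i: len(examples[i].blocks))
    for lo in range(0, len(order), batch_size):
        idx = order[lo : lo + batch_size]
        batch = [examples[i] for i in idx]
        blocks, r, q, tokens, valid = pad_batch(batch, mconfig)
        pos = _stack_pos_enc(r, q, mconfig)
        out = forward_batch(params, mconfig, blocks, pos, tokens, valid)
        z = out["mod_logit"].data
        probs[idx] = 1.0 / (1.0 + np.exp(-z))
    return probs


def masked_base_accuracy(
    params: dict[str, Tensor],
    mconfig: ModelConfig,
    examples: list[SiteExample],
    p_mask: float = 0.15,
    seed: int = 0,
    batch_size: int = 256,
) -> float:
    """Accuracy of the base head at [MASK]ed positions (no flips)."""
    rng = np.random.default_rng(seed)
    correct = total = 0
    for lo in range(0, len(examples), batch_size):
        batch = examples[lo : lo + batch_size]
        blocks, r, q, tokens, valid = pad_batch(batch, mconfig)
        masked, idx, targets = mask_bases(tokens, p_mask, 0.0, rng)
        if len(idx) == 0:
            continue
        pos = _stack_pos_enc(r, q, mconfig)
        out = forward_batch(params, mconfig, blocks, pos, masked, valid)
        rows = out["decoded"].data[idx[:, 0], idx[:, 1]]
        pred = np.argmax(rows @ params["base_head.w"].data + params["base_head.b"].data, axis=-1)
        correct += int((pred == targets).sum())
        total += len(targets)
    return correct / total if total else float("nan")


# ---------------------------------------------------------------------------
# distillation


def label_from_truth(
    examples: list[SiteExample], truth, *, high: float = 0.99, low: float = 0.01
) -> list[SiteExample]:
    """Attach hard labels from ground-truth frequencies.

    Mirrors bisulfite-based training-set construction: sites with frequency
    >= ``high`` are positives, <= ``low`` negatives, partially methylated
    sites are excluded (their per-read state is ambiguous).
    """
    labeled = []
    for e in examples:
        freq = truth.frequency(e.position, e.strand)
        if freq is None:
            continue
        if freq >= high:
            e.label = 1.0
        elif freq <= low:
            e.label = 0.0
        else:
            continue
        labeled.append(e)
    return labeled


def distill(
    teacher_params: dict[str, Tensor],
    teacher_config: ModelConfig,
    examples: list[SiteExample],
    *,
    batch_size: int = 256,
) -> list[SiteExample]:
    """Soft-label an example stream with the teacher's probabilities."""
    probs = predict_probabilities(teacher_params, teacher_config, examples, batch_size)
    for e, p in zip(examples, probs):
        e.label = float(p)
    return examples


def stratified_sample(
    examples: list[SiteExample],
    n: int,
    seed: int = 0,
    threshold: float = 0.5,
) -> list[SiteExample]:
    """Exactly n/2 modified and n/2 unmodified examples by thresholded label."""
    rng = np.random.default_rng(seed)
    pos = [e for e in examples if e.label is not None and e.label > threshold]
    neg = [e for e in examples if e.label is not None and e.label <= threshold]
    half = n // 2
    if len(pos) < half or len(neg) < half:
        raise ValueError(
            f"cannot draw {half}+{half} from pools of {len(pos)} modified / {len(neg)} unmodified"
        )
    take_pos = [pos[i] for i in rng.choice(len(pos), half, replace=False)]
    take_neg = [neg[i] for i in rng.choice(len(neg), half, replace=False)]
    out = take_pos + take_neg
    rng.shuffle(out)
    return out
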