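"""Encoder-decoder attention model for per-read 5mC prediction.

The signal branch projects b-sample blocks into a latent space, adds hybrid
positional encodings (absolute sine/cosine plus, in reference-anchored mode,
cosines of the relative reference and query indices) and contextualizes them
with a Pre-LN transformer encoder.  The sequence branch embeds the length-l
token window, adds standard sinusoidal encodings and decodes with self- plus
cross-attention into the contextualized signal.  A linear head on the row of
the central cytosine yields the unnormalized modification probability; a
sigmoid turns it into the per-read call.  Auxiliary heads (base prediction,
signal codebook classification) are used during training only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

__all__ = [
    "ModelConfig",
    "init_params",
    "positional_encoding",
    "sequence_positional_encoding",
    "multi_head_attention",
    "encode_signal",
    "embed_and_decode",
    "predict_modification",
    "forward_batch",
    "save_checkpoint",
    "load_checkpoint",
]

VOCAB = 6  # A C G T [UNK] [MASK]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The published base model uses f=384, 12+12 layers and d_ff=2048; the
    small (student) model halves the layers and uses f=128 / d_ff=1024.
    Defaults here are the small model.  ``mode`` selects the positional
    encoding: reference-anchored data uses the 4-term encoding (absolute
    cos/sin plus reference- and query-index cosines), basecall-anchored data
    the plain 2-term one.
    """

    latent: int = 128          # f
    heads: int = 4             # H; per-head dim d = f / H
    n_enc: int = 6
    n_dec: int = 6
    d_ff: int = 1024
    window: int = 31           # l
    block_width: int = 5       # b
    codebook_size: int = 64    # K
    mode: str = "reference"    # "reference" (4-term PE) or "basecall" (2-term)
    dropout: float = 0.1
    use_decoder: bool = True

    def __post_init__(self) -> None:
        if self.latent % self.heads:
            raise ValueError("latent dimension must be divisible by the head count")
        if self.mode not in ("reference", "basecall"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def head_dim(self) -> int:
        return self.latent // self.heads


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """Truncated-normal(0, 0.02) projections, zero biases, unit layer norms."""
    rng = np.random.default_rng(seed)
    f, ff, K = config.latent, config.d_ff, config.codebook_size

    def tn(*shape):
        w = rng.normal(0.0, 0.02, size=shape)
        return ag.parameter(np.clip(w, -0.04, 0.04))

    params: dict[str, Tensor] = {
        "w_signal": tn(config.block_width, f),
        "embed": tn(VOCAB, f),
        "mod_head.w": tn(f, 1),
        "mod_head.b": ag.parameter(np.zeros(1)),
        "base_head.w": tn(f, 4),
        "base_head.b": ag.parameter(np.zeros(4)),
        "codebook": tn(f, K),
    }

    def add_ln(name):
        params[f"{name}.g"] = ag.parameter(np.ones(f))
        params[f"{name}.b"] = ag.parameter(np.zeros(f))

    def add_attn(name):
        for p in ("wq", "wk", "wv", "wo"):
            params[f"{name}.{p}"] = tn(f, f)

    def add_ffn(name):
        params[f"{name}.w_in"] = tn(f, ff)
        params[f"{name}.b_in"] = ag.parameter(np.zeros(ff))
        params[f"{name}.w_out"] = tn(ff, f)
        params[f"{name}.b_out"] = ag.parameter(np.zeros(f))

    for i in range(config.n_enc):
        add_ln(f"enc{i}.ln1"); add_attn(f"enc{i}.attn")
        add_ln(f"enc{i}.ln2"); add_ffn(f"enc{i}.ffn")
    for i in range(config.n_dec):
        add_ln(f"dec{i}.ln1"); add_attn(f"dec{i}.self")
        add_ln(f"dec{i}.ln2"); add_attn(f"dec{i}.cross")
        add_ln(f"dec{i}.ln3"); add_ffn(f"dec{i}.ffn")
    return params


# ---------------------------------------------------------------------------
# positional encodings


def positional_encoding(
    s: int, r: np.ndarray | None, q: np.ndarray | None, config: ModelConfig
) -> np.ndarray:
    """Signal-branch positional encoding matrix P (s x f).

    Reference-anchored mode cycles four terms over the feature axis —
    cos(i pt), sin(i pt), cos(r_i pt), cos(q_i pt) with
    pt(j) = 10000^(-4 floor(j/4) / f) — so each frequency group carries the
    absolute block position plus both relative indices.  Basecall-anchored
    mode uses the classic 2-term cos/sin with pt(j) = 10000^(-2 floor(j/2) / f).
    """
    f = config.latent
    j = np.arange(f)
    i = np.arange(s)[:, None]
    if config.mode == "reference":
        if r is None or q is None:
            raise ValueError("reference-anchored positional encoding needs r and q")
        r = np.asarray(r, dtype=np.float64)[:, None]
        q = np.asarray(q, dtype=np.float64)[:, None]
        pt = 10000.0 ** (-4.0 * (j // 4) / f)
        phase = i * pt
        out = np.where(
            j % 4 == 0, np.cos(phase),
            np.where(j % 4 == 1, np.sin(phase),
                     np.where(j % 4 == 2, np.cos(r * pt), np.cos(q * pt))),
        )
    else:
        pt = 10000.0 ** (-2.0 * (j // 2) / f)
        phase = i * pt
        out = np.where(j % 2 == 0, np.cos(phase), np.sin(phase))
    return out


def sequence_positional_encoding(l: int, f: int) -> np.ndarray:
    """Standard sinusoidal encoding for the token window (sin even, cos odd)."""
    j = np.arange(f)
    i = np.arange(l)[:, None]
    angle = i / 10000.0 ** (2.0 * (j // 2) / f)
    return np.where(j % 2 == 0, np.sin(angle), np.cos(angle))


# ---------------------------------------------------------------------------
# attention


def multi_head_attention(
    keys: Tensor,
    queries: Tensor,
    values: Tensor,
    params: dict[str, Tensor],
    prefix: str,
    heads: int,
    mask: np.ndarray | None = None,
) -> Tensor:
    """Scaled dot-product multi-head attention.

    Inputs are (..., L, f).  ``mask``, if given, is broadcastable to the
    attention score shape (..., H, Lq, Lk) with 1 for usable keys and 0 for
    padding; masked keys receive zero attention weight.
    """
    f = keys.shape[-1]
    d = f // heads

    def split(x: Tensor) -> Tensor:
        # (..., L, f) -> (..., H, L, d)
        *lead, L, _ = x.shape
        x = x.reshape(*lead, L, heads, d)
        axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
        return x.transpose(*axes)

    Q = split(queries @ params[f"{prefix}.wq"])
    K = split(keys @ params[f"{prefix}.wk"])
    V = split(values @ params[f"{prefix}.wv"])
    scores = (Q @ K.transpose(*range(K.data.ndim - 2), K.data.ndim - 1, K.data.ndim - 2)) * (
        1.0 / np.sqrt(d)
    )
    if mask is not None:
        scores = scores + np.where(mask, 0.0, -1e9)
    weights = scores.softmax(axis=-1)
    ctx = weights @ V  # (..., H, Lq, d)
    *lead, H, Lq, _ = ctx.shape
    axes = tuple(range(len(lead))) + (len(lead) + 1, len(lead), len(lead) + 2)
    ctx = ctx.transpose(*axes).reshape(*lead, Lq, f)
    return ctx @ params[f"{prefix}.wo"]


def _ffn(x: Tensor, params: dict[str, Tensor], prefix: str) -> Tensor:
    h = (x @ params[f"{prefix}.w_in"] + params[f"{prefix}.b_in"]).gelu()
    return h @ params[f"{prefix}.w_out"] + params[f"{prefix}.b_out"]


def _maybe_dropout(x: Tensor, config: ModelConfig, rng, training: bool) -> Tensor:
    if training and rng is not None and config.dropout > 0:
        return x.dropout(config.dropout, rng)
    return x


# ---------------------------------------------------------------------------
# encoder / decoder


def encode_signal(
    blocks: Tensor,
    pos_enc: np.ndarray,
    params: dict[str, Tensor],
    config: ModelConfig,
    mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> tuple[Tensor, Tensor]:
    """Contextualize signal blocks; returns (local, contextualized).

    ``local`` is the bare linear projection B W^S (the representation the
    codebook targets are computed from); the encoder input adds ``pos_enc``
    and runs n_enc Pre-LN layers of self-attention + feed-forward.
    """
    local = blocks @ params["w_signal"]
    x = local + pos_enc
    key_mask = None if mask is None else mask[..., None, None, :]
    for i in range(config.n_enc):
        h = x.layer_norm(params[f"enc{i}.ln1.g"], params[f"enc{i}.ln1.b"])
        att = multi_head_attention(h, h, h, params, f"enc{i}.attn", config.heads, key_mask)
        x = x + _maybe_dropout(att, config, rng, training)
        h = x.layer_norm(params[f"enc{i}.ln2.g"], params[f"enc{i}.ln2.b"])
        x = x + _maybe_dropout(_ffn(h, params, f"enc{i}.ffn"), config, rng, training)
    return local, x


def embed_and_decode(
    tokens: np.ndarray,
    enc_out: Tensor,
    params: dict[str, Tensor],
    config: ModelConfig,
    mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> Tensor:
    """Decode the token window against the contextualized signal.

    Each Pre-LN decoder layer applies self-attention over the sequence,
    cross-attention with queries from the sequence and keys/values from the
    signal, then the feed-forward projection, all with residual additions.
    """
    tokens = np.asarray(tokens, dtype=np.int64)
    if tokens.max() >= VOCAB or tokens.min() < 0:
        raise ValueError("token id outside the 6-symbol vocabulary")
    l = tokens.shape[-1]
    x = ag.embedding(params["embed"], tokens) + sequence_positional_encoding(l, config.latent)
    key_mask = None if mask is None else mask[..., None, None, :]
    for i in range(config.n_dec):
        h = x.layer_norm(params[f"dec{i}.ln1.g"], params[f"dec{i}.ln1.b"])
        att = multi_head_attention(h, h, h, params, f"dec{i}.self", config.heads)
        x = x + _maybe_dropout(att, config, rng, training)
        h = x.layer_norm(params[f"dec{i}.ln2.g"], params[f"dec{i}.ln2.b"])
        att = multi_head_attention(enc_out, h, enc_out, params, f"dec{i}.cross",
                                   config.heads, key_mask)
        x = x + _maybe_dropout(att, config, rng, training)
        h = x.layer_norm(params[f"dec{i}.ln3.g"], params[f"dec{i}.ln3.b"])
        x = x + _maybe_dropout(_ffn(h, params, f"dec{i}.ffn"), config, rng, training)
    return x


def predict_modification(
    dec_out: Tensor, params: dict[str, Tensor], config: ModelConfig
) -> Tensor:
    """Modification logit from the central-cytosine row; sigmoid gives the probability."""
    center = config.window // 2
    row = dec_out[(slice(None), center)] if dec_out.data.ndim == 3 else dec_out[center]
    z = row @ params["mod_head.w"] + params["mod_head.b"]
    return z.reshape(-1) if z.data.ndim > 1 else z


def base_logits(dec_out: Tensor, params: dict[str, Tensor]) -> Tensor:
    return dec_out @ params["base_head.w"] + params["base_head.b"]


def forward_batch(
    params: dict[str, Tensor],
    config: ModelConfig,
    blocks: np.ndarray,
    pos_enc: np.ndarray,
    tokens: np.ndarray,
    block_mask: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    training: bool = False,
) -> dict[str, Tensor]:
    """One forward pass over a padded batch.

    ``blocks`` is (n, s_max, b) with ``block_mask`` (n, s_max) marking real
    blocks; ``pos_enc`` is the matching stacked positional encoding.  When the
    decoder is bypassed (signal-only ablation) the prediction head runs on the
    masked mean of the contextualized signal instead of the central token row.
    """
    local, enc = encode_signal(Tensor(blocks), pos_enc, params, config,
                               block_mask, rng, training)
    out: dict[str, Tensor] = {"local": local, "encoded": enc}
    if config.use_decoder:
        dec = embed_and_decode(tokens, enc, params, config, block_mask, rng, training)
        out["decoded"] = dec
        out["mod_logit"] = predict_modification(dec, params, config)
    else:
        if block_mask is None:
            pooled = enc.mean(axis=-2)
        else:
            w = block_mask / block_mask.sum(axis=-1, keepdims=True)
            pooled = (enc * w[..., None]).sum(axis=-2)
        z = pooled @ params["mod_head.w"] + params["mod_head.b"]
        out["mod_logit"] = z.reshape(-1) if z.data.ndim > 1 else z
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(params: dict[str, Tensor], config: ModelConfig, path) -> None:
    arrays = {k.replace(".", "__"): v.data for k, v in params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(config)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict[str, Tensor], ModelConfig]:
    with np.load(path) as data:
        config = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        params = {
            k.replace("__", "."): ag.parameter(data[k])
            for k in data.files
            if k != "__config__"
        }
    return params, config
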