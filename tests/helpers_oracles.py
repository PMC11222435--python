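"""Independent brute-force oracles used by the acceptance battery."""

import numpy as np


def positional_encoding_scalar_loop(s, r, q, f, mode):
    """Direct scalar evaluation of the hybrid positional encodings."""
    P = np.zeros((s, f))
    for i in range(s):
        for j in range(f):
            if mode == "reference":
                pt = 10000.0 ** (-4.0 * (j // 4) / f)
                if j % 4 == 0:
                    P[i, j] = np.cos(i * pt)
                elif j % 4 == 1:
                    P[i, j] = np.sin(i * pt)
                elif j % 4 == 2:
                    P[i, j] = np.cos(r[i] * pt)
                else:
                    P[i, j] = np.cos(q[i] * pt)
            else:
                pt = 10000.0 ** (-2.0 * (j // 2) / f)
                P[i, j] = np.cos(i * pt) if j % 2 == 0 else np.sin(i * pt)
    return P


def mha_reference_loop(x_k, x_q, x_v, params, prefix, H, mask=None):
    """Explicit per-head scaled-dot-product attention; returns (output, weights)."""
    f = x_k.shape[-1]
    d = f // H
    wq = params[f"{prefix}.wq"].data
    wk = params[f"{prefix}.wk"].data
    wv = params[f"{prefix}.wv"].data
    heads, all_weights = [], []
    for h in range(H):
        sl = slice(h * d, (h + 1) * d)
        Q = x_q @ wq[:, sl]
        K = x_k @ wk[:, sl]
        V = x_v @ wv[:, sl]
        scores = Q @ K.T / np.sqrt(d)
        if mask is not None:
            scores = scores + np.where(mask, 0.0, -1e9)
        w = np.exp(scores - scores.max(axis=-1, keepdims=True))
        w /= w.sum(axis=-1, keepdims=True)
        heads.append(w @ V)
        all_weights.append(w)
    return np.concatenate(heads, axis=-1) @ params[f"{prefix}.wo"].data, all_weights
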