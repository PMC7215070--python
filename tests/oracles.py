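"""Independent brute-force oracles: literal plain-loop transcriptions of the
encoder and attention/merge formulas, kept free of the package's vectorized
code paths."""

import numpy as np

from ppistack.properties import ac_property_table, pseaac_property_table
from ppistack.records import STANDARD_AA


def ac_oracle(seq, lg):
    X = ac_property_table().profile(seq)
    L, p = X.shape
    out = []
    for lag in range(1, lg + 1):
        for j in range(p):
            mean_j = sum(X[i, j] for i in range(L)) / L
            s = 0.0
            for i in range(L - lag):
                s += (X[i, j] - mean_j) * (X[i + lag, j] - mean_j)
            out.append(s / (L - lag))
    return np.array(out)


def pseaac_oracle(seq, lam, omega=0.05):
    H = pseaac_property_table().profile(seq)
    L = len(seq)
    f = [seq.count(aa) / L for aa in STANDARD_AA]
    theta = []
    for j in range(1, lam + 1):
        s = 0.0
        for i in range(L - j):
            s += sum(H[i + j, p] - H[i, p] for p in range(3)) / 3
        theta.append(s / (L - j))
    denom = sum(f) + omega * sum(theta)
    return np.array(f + [omega * t for t in theta]) / denom


def softmax_rows(z):
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def attention_oracle(Q, K, V):
    scores = Q @ K.T / np.sqrt(Q.shape[-1])
    w = softmax_rows(scores)
    return w, w @ V


def multi_head_oracle(Q, K, V, Wq, Wk, Wv, Wmu, h):
    d_model = Wq.shape[1]
    d_k = d_model // h
    Qp, Kp, Vp = Q @ Wq, K @ Wk, V @ Wv
    heads = []
    for i in range(h):
        sl = slice(i * d_k, (i + 1) * d_k)
        _, out = attention_oracle(Qp[:, sl], Kp[:, sl], Vp[:, sl])
        heads.append(out)
    return np.concatenate(heads, axis=1) @ Wmu


def pooled_oracle(Q, K, V, Wq, Wk, Wv, Wmu, h):
    M = multi_head_oracle(Q, K, V, Wq, Wk, Wv, Wmu, h)
    G = M.T @ Q / Q.shape[0]
    return np.concatenate([G.mean(axis=1), G.max(axis=1)])


def merge_oracle(a, b, A):
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    cos = 0.0 if na == 0 or nb == 0 else float(a @ b) / (na * nb)
    return np.concatenate([[cos, float(a @ A @ b)], a, b])
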