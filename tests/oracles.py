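"""Scalar-loop reference implementations of every layer operation.

These are deliberately naive (explicit Python loops, no vectorization, no
shared code with the package) so they serve as independent oracles for the
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def highway_ref(e: np.ndarray, w_f, b_f, w_g, b_g) -> np.ndarray:
    n, E = e.shape
    out = np.zeros_like(e)
    for t in range(n):
        e_hat = np.zeros(E)
        for i in range(E):
            acc = b_f[i]
            for j in range(E):
                acc += w_f[i, j] * e[t, j]
            e_hat[i] = math.tanh(acc)
        for i in range(E):
            acc = b_g[i]
            for j in range(E):
                acc += w_g[i, j] * e_hat[j]
            g = 1.0 / (1.0 + math.exp(-acc))
            out[t, i] = g * e_hat[i] + (1.0 - g) * e[t, i]
    return out


def lstm_cell_ref(x, h_prev, c_prev, w, u, b):
    """One LSTM step; gate order input, forget, cell, output."""
    H = h_prev.shape[0]
    z = x @ w + h_prev @ u + b
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    i = sig(z[0 * H:1 * H])
    f = sig(z[1 * H:2 * H])
    g = np.tanh(z[2 * H:3 * H])
    o = sig(z[3 * H:4 * H])
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    return h, c


def attention_ref(ea, eb, mask_a, mask_b, mode="softmax"):
    """Triple-loop interaction attention on one example."""
    na, nb = ea.shape[0], eb.shape[0]
    sim = np.zeros((na, nb))
    for k in range(na):
        for s in range(nb):
            sim[k, s] = float(np.dot(ea[k], eb[s]))
    a_fwd = np.zeros((na, nb))
    a_bwd = np.zeros((na, nb))
    for k in range(na):
        if mode == "softmax":
            valid = [s for s in range(nb) if mask_b[s] > 0]
            mx = max(sim[k, s] for s in valid)
            exps = {s: math.exp(sim[k, s] - mx) for s in valid}
            Z = sum(exps.values())
            for s in valid:
                a_fwd[k, s] = exps[s] / Z
        else:
            Z = sum(sim[k, s] for s in range(nb) if mask_b[s] > 0)
            for s in range(nb):
                if mask_b[s] > 0:
                    a_fwd[k, s] = sim[k, s] / Z
    for s in range(nb):
        if mode == "softmax":
            valid = [k for k in range(na) if mask_a[k] > 0]
            mx = max(sim[k, s] for k in valid)
            exps = {k: math.exp(sim[k, s] - mx) for k in valid}
            Z = sum(exps.values())
            for k in valid:
                a_bwd[k, s] = exps[k] / Z
        else:
            Z = sum(sim[k, s] for k in range(na) if mask_a[k] > 0)
            for k in range(na):
                if mask_a[k] > 0:
                    a_bwd[k, s] = sim[k, s] / Z
    attended_a = np.zeros((na, eb.shape[1]))
    attended_b = np.zeros((nb, ea.shape[1]))
    for k in range(na):
        if mask_a[k] > 0:
            for s in range(nb):
                attended_a[k] += a_fwd[k, s] * eb[s]
    for s in range(nb):
        if mask_b[s] > 0:
            for k in range(na):
                attended_b[s] += a_bwd[k, s] * ea[k]
    return sim, a_fwd, a_bwd, attended_a, attended_b


def squash_ref(s: np.ndarray, variant: str = "printed") -> np.ndarray:
    norm = math.sqrt(sum(v * v for v in s))
    if variant == "printed":
        return np.array([v / (1.0 + norm) for v in s])
    return np.array([v * norm / (1.0 + norm * norm) for v in s])


def capsule_features_ref(S, mask, conv_w, conv_b, caps_w, caps_b, width, I, J, d, activation="relu"):
    """Brute-force conv + max-over-time + per-capsule transforms, one example."""
    n, F = S.shape
    C = conv_w.shape[1] // I
    Sm = S * mask[:, None]
    half = width // 2
    conv = np.zeros((n, I * C))
    for t in range(n):
        window = []
        for off in range(-half, width - half):
            src = t + off
            window.append(Sm[src] if 0 <= src < n else np.zeros(F))
        wvec = np.concatenate(window)
        conv[t] = wvec @ conv_w + conv_b
    channels = np.zeros(I * C)
    valid = [t for t in range(n) if mask[t] > 0]
    for ic in range(I * C):
        channels[ic] = max(conv[t, ic] for t in valid)
    U = channels.reshape(I, C)
    act = {"relu": lambda v: np.maximum(v, 0), "tanh": np.tanh,
           "sigmoid": lambda v: 1.0 / (1.0 + np.exp(-v))}[activation]
    u_hat = np.zeros((I, J, d))
    for i in range(I):
        pred = U[i] @ caps_w  # (J*d,)
        for j in range(J):
            u_hat[i, j] = act(pred[j * d:(j + 1) * d] + caps_b)
    return u_hat


def routing_ref(u_hat: np.ndarray, T: int, variant: str = "printed"):
    """Literal execution of the routing algorithm with scalar loops."""
    I, J, d = u_hat.shape
    b = np.zeros((I, J))
    c = np.zeros((I, J))
    d_out = np.zeros((J, d))
    for _ in range(T):
        for i in range(I):
            mx = b[i].max()
            exps = np.exp(b[i] - mx)
            c[i] = exps / exps.sum()
        for j in range(J):
            s_j = np.zeros(d)
            for i in range(I):
                s_j += c[i, j] * u_hat[i, j]
            d_out[j] = squash_ref(s_j, variant)
        for i in range(I):
            for j in range(J):
                b[i, j] += float(np.dot(d_out[j], u_hat[i, j]))
    return d_out, c


def confusion_ref(predicted, actual):
    tp = fp = fn = tn = 0
    for p, a in zip(predicted, actual):
        if p == 1 and a == 1:
            tp += 1
        elif p == 1 and a == 0:
            fp += 1
        elif p == 0 and a == 1:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
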