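"""The mathematical components of the capsule text matcher.

Each operation here is a pure function over :class:`~capstm.autodiff.Tensor`
values (plain arrays are accepted and wrapped), so every block — the highway
input transform, the BiLSTM encoders, the soft-attention interaction, the
convolutional capsule features, squash, dynamic routing, the pooling
ablations, fusion and the sigmoid head — can be tested in isolation against
a scalar reference implementation.

All sequence functions take a leading batch axis; a single (n, D) sequence
is promoted to batch size 1 and squeezed back on return.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concatenate, softmax, stack, zeros

ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "sigmoid": lambda t: t.sigmoid(),
}


def activation_fn(name: str):
    try:
        return ACTIVATIONS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}")


def _batched(x: Tensor) -> tuple[Tensor, bool]:
    if x.ndim == 2:
        return x.reshape(1, *x.shape), True
    return x, False


def _mask2d(mask, batch: int, n: int) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float64)
    if m.ndim == 1:
        m = m[None, :]
    assert m.shape == (batch, n), f"mask shape {m.shape} != {(batch, n)}"
    return m


# --------------------------------------------------------------------------
# input layer: highway transform
# --------------------------------------------------------------------------


@dataclass
class HighwayParams:
    """Gated square transform of the embedding space (size E preserved)."""

    w_f: Tensor  # (E, E)
    b_f: Tensor  # (E,)
    w_g: Tensor  # (E, E)
    b_g: Tensor  # (E,)


def highway(e: Tensor, params: HighwayParams) -> Tensor:
    """Gated interpolation between raw and transformed embeddings.

    Per position: ``ê = tanh(w_f e + b_f)``, ``g = sigmoid(w_g ê + b_g)``,
    ``e' = g ⊙ ê + (1 − g) ⊙ e``.  A gate near 0 passes the raw embedding
    through; a gate near 1 selects the tanh branch.
    """
    e = as_tensor(e)
    E = params.w_f.shape[0]
    if e.shape[-1] != E:
        raise ValueError(f"embedding dim {e.shape[-1]} != transform size {E}")
    e_hat = (e @ params.w_f.transpose((1, 0)) + params.b_f).tanh()
    g = (e_hat @ params.w_g.transpose((1, 0)) + params.b_g).sigmoid()
    return g * e_hat + (1.0 - g) * e


# --------------------------------------------------------------------------
# representation / aggregation: BiLSTM encoder
# --------------------------------------------------------------------------


@dataclass
class BiLstmParams:
    """One forward and one backward LSTM, hidden size H per direction.

    Gate order in the stacked weight matrices is input, forget, cell, output.
    Per-token output is the 2H concatenation of the two directions.
    """

    w_fwd: Tensor  # (D, 4H) input weights, forward direction
    u_fwd: Tensor  # (H, 4H) recurrent weights
    b_fwd: Tensor  # (4H,)
    w_bwd: Tensor
    u_bwd: Tensor
    b_bwd: Tensor

    @property
    def hidden_size(self) -> int:
        return self.u_fwd.shape[0]


def _lstm_direction(x: Tensor, mask: np.ndarray, w: Tensor, u: Tensor, b: Tensor, reverse: bool) -> Tensor:
    batch, n, _ = x.shape
    H = u.shape[0]
    h = zeros((batch, H))
    c = zeros((batch, H))
    steps: list[Tensor] = []
    order = range(n - 1, -1, -1) if reverse else range(n)
    for t in order:
        x_t = x[:, t, :]
        z = x_t @ w + h @ u + b
        i = z[:, 0 * H:1 * H].sigmoid()
        f = z[:, 1 * H:2 * H].sigmoid()
        g = z[:, 2 * H:3 * H].tanh()
        o = z[:, 3 * H:4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        m = Tensor(mask[:, t:t + 1])
        # padded steps carry the previous state through unchanged
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h
        steps.append(h)
    if reverse:
        steps.reverse()
    return stack(steps, axis=1)


def bilstm_encode(x: Tensor, mask, params: BiLstmParams) -> Tensor:
    """Per-token bidirectional LSTM states, (batch, n, 2H).

    Padded positions neither alter the recurrent state nor appear in the
    output (their rows are zeroed), so appending dummy tokens never changes
    the encoding of real ones.
    """
    x = as_tensor(x)
    x, squeeze = _batched(x)
    batch, n, _ = x.shape
    m = _mask2d(mask, batch, n)
    fwd = _lstm_direction(x, m, params.w_fwd, params.u_fwd, params.b_fwd, reverse=False)
    bwd = _lstm_direction(x, m, params.w_bwd, params.u_bwd, params.b_bwd, reverse=True)
    out = concatenate([fwd, bwd], axis=-1) * Tensor(m[:, :, None])
    return out.reshape(n, -1) if squeeze else out


def aggregate(c_seq: Tensor, mask, params: BiLstmParams) -> Tensor:
    """Fuse the concatenated representations with a second BiLSTM."""
    return bilstm_encode(c_seq, mask, params)


# --------------------------------------------------------------------------
# representation layer: attention interaction
# --------------------------------------------------------------------------


@dataclass
class AttentionResult:
    """Raw similarities, normalized weights and attended vectors.

    ``a_fwd[k, s]`` is the weight of position s of text b when attending
    for position k of text a (rows over valid columns sum to 1 in softmax
    mode); ``a_bwd`` normalizes the same similarity matrix along the text-a
    axis for the reverse direction.
    """

    sim: Tensor        # (batch, n, n)
    a_fwd: Tensor      # (batch, n, n) rows normalized over text-b positions
    a_bwd: Tensor      # (batch, n, n) columns normalized over text-a positions
    attended_a: Tensor  # (batch, n, D) cross-text summary for each a position
    attended_b: Tensor  # (batch, n, D) cross-text summary for each b position


def interaction_attention(
    ea: Tensor,
    eb: Tensor,
    mask_a,
    mask_b,
    norm_mode: str = "softmax",
) -> AttentionResult:
    """Attention-based interaction matrix between the two texts.

    ``sim[k, s]`` is the inner product of position k of text a with position
    s of text b.  ``softmax`` mode (default) applies a masked softmax over
    the attended axis; ``literal`` mode uses the raw ratio
    ``sim_ks / Σ_s sim_ks``, which is only well-defined when every valid row
    sum is positive.  Attended vectors are the weight-averaged positions of
    the opposite text.
    """
    ea, eb = as_tensor(ea), as_tensor(eb)
    ea, squeeze = _batched(ea)
    eb, _ = _batched(eb)
    batch, n, _ = ea.shape
    ma = _mask2d(mask_a, batch, n)
    mb = _mask2d(mask_b, batch, eb.shape[1])

    sim = ea @ eb.transpose((0, 2, 1))  # (batch, n_a, n_b)
    if norm_mode == "softmax":
        a_fwd = softmax(sim, axis=2, mask=mb[:, None, :])
        a_bwd = softmax(sim, axis=1, mask=ma[:, :, None])
    elif norm_mode == "literal":
        masked_fwd = sim * Tensor(mb[:, None, :])
        row_sums = masked_fwd.sum(axis=2, keepdims=True)
        valid_rows = ma.astype(bool)
        if np.any(row_sums.data[valid_rows, :] <= 0):
            raise ValueError(
                "literal ratio normalization hit a non-positive row sum; "
                "use norm_mode='softmax' instead"
            )
        masked_bwd = sim * Tensor(ma[:, :, None])
        col_sums = masked_bwd.sum(axis=1, keepdims=True)
        # a column that is entirely zero normalizes to zero weights (0/0 -> 0);
        # any other non-positive column sum is a genuine failure of the ratio
        col_all_zero = np.all(masked_bwd.data == 0.0, axis=1, keepdims=True)
        valid_cols = mb.astype(bool)
        bad_cols = (col_sums.data <= 0) & ~col_all_zero
        if np.any(np.transpose(bad_cols, (0, 2, 1))[valid_cols, :]):
            raise ValueError(
                "literal ratio normalization hit a non-positive column sum; "
                "use norm_mode='softmax' instead"
            )
        a_fwd = masked_fwd / row_sums
        a_bwd = masked_bwd / (col_sums + Tensor(col_all_zero.astype(np.float64)))
    else:
        raise ValueError(f"unknown norm_mode {norm_mode!r}")

    attended_a = (a_fwd @ eb) * Tensor(ma[:, :, None])
    attended_b = (a_bwd.transpose((0, 2, 1)) @ ea) * Tensor(mb[:, :, None])
    if squeeze:
        return AttentionResult(
            sim=sim.reshape(*sim.shape[1:]),
            a_fwd=a_fwd.reshape(*a_fwd.shape[1:]),
            a_bwd=a_bwd.reshape(*a_bwd.shape[1:]),
            attended_a=attended_a.reshape(*attended_a.shape[1:]),
            attended_b=attended_b.reshape(*attended_b.shape[1:]),
        )
    return AttentionResult(sim, a_fwd, a_bwd, attended_a, attended_b)


def concat_representation(h: Tensor, attended: Tensor) -> Tensor:
    """Per-position concatenation [h ; attended] (order is fixed)."""
    h, attended = as_tensor(h), as_tensor(attended)
    if h.shape[:-1] != attended.shape[:-1]:
        raise ValueError(f"sequence shapes differ: {h.shape[:-1]} vs {attended.shape[:-1]}")
    return concatenate([h, attended], axis=-1)


# --------------------------------------------------------------------------
# capsule layer
# --------------------------------------------------------------------------


@dataclass
class CapsuleParams:
    """Convolutional channel extractors plus per-capsule transforms.

    ``conv_w`` holds I width-w kernels over the aggregated sequence (stacked
    as one matrix); max-over-time of each kernel's output yields one channel
    vector per kernel.  ``caps_w`` maps each channel vector into J capsule
    prediction vectors of dimension d, with one shared bias.
    """

    conv_w: Tensor  # (w * F, I * C): I kernels of width w over F-dim tokens
    conv_b: Tensor  # (I * C,)
    caps_w: Tensor  # (C, J * d): J capsule transforms applied per channel
    caps_b: Tensor  # (d,) shared across capsules
    width: int
    n_channels: int  # I
    n_capsules: int  # J
    capsule_dim: int  # d

    @property
    def channel_dim(self) -> int:
        return self.conv_w.shape[1] // self.n_channels


def capsule_features(
    S: Tensor,
    mask,
    params: CapsuleParams,
    activation: str = "relu",
) -> Tensor:
    """Prediction vectors û (batch, I, J, d) from an aggregated sequence.

    Each of the I kernels slides over the token axis (same-padding, padded
    positions zeroed) and is reduced by max over valid positions into one
    channel vector; each channel is then mapped by every capsule transform
    through the configured nonlinearity.
    """
    S = as_tensor(S)
    S, squeeze = _batched(S)
    batch, n, feat = S.shape
    if n < params.width:
        raise ValueError(f"sequence length {n} shorter than kernel width {params.width}")
    m = _mask2d(mask, batch, n)
    S = S * Tensor(m[:, :, None])

    # same-padded windows: concatenate w shifted copies along the feature axis
    half = params.width // 2
    zero_row = zeros((batch, 1, feat))
    shifted = []
    for offset in range(-half, params.width - half):
        if offset < 0:
            parts = [zero_row] * (-offset) + [S[:, : n + offset, :]] if n + offset > 0 else [zero_row] * n
        elif offset > 0:
            parts = [S[:, offset:, :]] + [zero_row] * offset
        else:
            parts = [S]
        shifted.append(concatenate(parts, axis=1) if len(parts) > 1 else parts[0])
    windows = concatenate(shifted, axis=-1)  # (batch, n, w*F)

    conv = windows @ params.conv_w + params.conv_b  # (batch, n, I*C)
    # restrict max-over-time to valid positions
    neg = Tensor(((m - 1.0) * 1e9)[:, :, None])
    channels = (conv + neg).max(axis=1)  # (batch, I*C)
    I, C = params.n_channels, params.channel_dim
    U = channels.reshape(batch, I, C)

    J, d = params.n_capsules, params.capsule_dim
    act = activation_fn(activation)
    pred = U.reshape(batch * I, C) @ params.caps_w  # (batch*I, J*d)
    u_hat = act(pred.reshape(batch, I, J, d) + params.caps_b)
    return u_hat.reshape(I, J, d) if squeeze else u_hat


def squash(s: Tensor, variant: str = "printed") -> Tensor:
    """Capsule nonlinearity: same direction, norm squashed into [0, 1).

    ``printed`` is ``s / (1 + ‖s‖)`` (the algebraic simplification of
    ‖s‖²/(1+‖s‖) · s/‖s‖²); ``standard`` is the canonical
    ``s·‖s‖ / (1 + ‖s‖²)``.  Both map 0 to 0.  Applied over the last axis.
    """
    s = as_tensor(s)
    norm_sq = (s * s).sum(axis=-1, keepdims=True)
    norm = (norm_sq + 1e-24).sqrt()  # epsilon keeps the gradient finite at 0
    if variant == "printed":
        return s / (1.0 + norm)
    if variant == "standard":
        return s * norm / (1.0 + norm_sq)
    raise ValueError(f"unknown squash variant {variant!r}")


def dynamic_routing(
    u_hat: Tensor,
    T: int,
    squash_variant: str = "printed",
    coupling_history: list | None = None,
) -> tuple[Tensor, Tensor]:
    """Iterative routing-by-agreement from I input channels to J capsules.

    Logits start at zero (uniform couplings, like average pooling); each of
    the T iterations softmaxes the logits over the output-capsule axis,
    forms weighted sums, squashes them, and reinforces logits by the
    agreement ⟨d_j, û_{i|j}⟩.  Returns the final capsules (…, J, d) and the
    couplings (…, I, J) used in the last iteration.
    """
    if T < 1:
        raise ValueError(f"routing needs at least one iteration, got T={T}")
    u_hat = as_tensor(u_hat)
    lead = u_hat.shape[:-3]
    I, J, d = u_hat.shape[-3:]
    b_logits = zeros(lead + (I, J))
    couplings = None
    d_out = None
    for _ in range(T):
        couplings = softmax(b_logits, axis=-1)
        if coupling_history is not None:
            coupling_history.append(couplings.data.copy())
        s = (couplings.reshape(*lead, I, J, 1) * u_hat).sum(axis=-3)  # (…, J, d)
        d_out = squash(s, variant=squash_variant)
        agreement = (u_hat * d_out.reshape(*lead, 1, J, d)).sum(axis=-1)
        b_logits = b_logits + agreement
    return d_out, couplings


def pool_capsules(u_hat: Tensor, mode: str, squash_variant: str = "printed") -> Tensor:
    """Routing-free ablation: elementwise max or mean over input channels.

    The pooled vector is squashed so ablation outputs live on the same norm
    scale as routed capsules.
    """
    u_hat = as_tensor(u_hat)
    if mode == "max":
        pooled = u_hat.max(axis=-3)
    elif mode == "mean":
        pooled = u_hat.mean(axis=-3)
    else:
        raise ValueError(f"unknown pooling mode {mode!r}; use 'max' or 'mean'")
    return squash(pooled, variant=squash_variant)


# --------------------------------------------------------------------------
# prediction layer
# --------------------------------------------------------------------------


def fuse(C1: Tensor, C2: Tensor) -> Tensor:
    """Fusion vector [C1, C2, C1 − C2, cos(C1, C2)].

    The cosine of a zero vector is defined as 0.  Output length is
    3·len(C) + 1 per example.
    """
    C1, C2 = as_tensor(C1), as_tensor(C2)
    if C1.shape != C2.shape:
        raise ValueError(f"capsule vectors differ in shape: {C1.shape} vs {C2.shape}")
    squeeze = C1.ndim == 1
    if squeeze:
        C1, C2 = C1.reshape(1, -1), C2.reshape(1, -1)
    dot = (C1 * C2).sum(axis=-1, keepdims=True)
    n1 = (C1 * C1).sum(axis=-1, keepdims=True).sqrt()
    n2 = (C2 * C2).sum(axis=-1, keepdims=True).sqrt()
    cos = dot / (n1 * n2 + 1e-12)
    out = concatenate([C1, C2, C1 - C2, cos], axis=-1)
    return out.reshape(-1) if squeeze else out


@dataclass
class PredictHeadParams:
    """One hidden layer then a single-unit sigmoid output."""

    w1: Tensor  # (fusion_dim, hidden)
    b1: Tensor
    w2: Tensor  # (hidden, 1)
    b2: Tensor


def predict_head(C: Tensor, params: PredictHeadParams, activation: str = "relu") -> Tensor:
    """Match probability in (0, 1) from the fusion vector."""
    C = as_tensor(C)
    squeeze = C.ndim == 1
    if squeeze:
        C = C.reshape(1, -1)
    act = activation_fn(activation)
    hidden = act(C @ params.w1 + params.b1)
    logit = hidden @ params.w2 + params.b2
    p = logit.sigmoid().reshape(-1)
    return p
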