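"""End-to-end capsule text matcher and its ablation variants.

The model is a five-layer Siamese architecture: token embeddings pass
through a highway transform (input layer), a BiLSTM plus cross-text
attention (representation layer), a second BiLSTM (aggregation layer),
convolutional capsule features with dynamic routing (capsule layer), and a
fusion vector [C1, C2, C1−C2, cos] feeding a sigmoid head (prediction
layer).  All parameters are shared between the two questions.

Ablation switches reproduce the routing-free (max/mean pooling) and
attention-free variants studied for this architecture.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autodiff as ad
from .autodiff import Tensor, embedding, no_grad
from .corpus_io import PAD_INDEX, EmbeddingTable, TokenizedBatch, Vocab
from .layers import (
    BiLstmParams,
    CapsuleParams,
    HighwayParams,
    PredictHeadParams,
    aggregate,
    bilstm_encode,
    capsule_features,
    concat_representation,
    dynamic_routing,
    fuse,
    highway,
    interaction_attention,
    pool_capsules,
    predict_head,
)

CAPSULE_MODES = ("routing", "max", "mean")
NORM_MODES = ("softmax", "literal")
SIMILARITY_SOURCES = ("embedding", "hidden")
SQUASH_VARIANTS = ("printed", "standard")


@dataclass
class ModelConfig:
    """Every architecture and training hyperparameter in one place.

    The two presets mirror the published configurations: ``word2vec``
    (300-dim static character vectors, H=100, dropout 0.5) and
    ``contextual`` (768-dim precomputed contextual vectors, H=384, dropout
    0.9).  Both use 6 capsules of dimension 50, 3 routing iterations,
    learning rate 0.001, ReLU and batch size 32.  Dropout rates are *drop*
    probabilities as printed for each preset (0.9 is aggressive; older
    frameworks often quoted keep-probabilities, so the interpretation is
    made explicit here rather than guessed per preset).
    """

    embedding_size: int = 300
    hidden_size: int = 100
    n_capsules: int = 6
    capsule_dim: int = 50
    routing_iters: int = 3
    learning_rate: float = 0.001
    dropout_rate: float = 0.5
    activation: str = "relu"
    batch_size: int = 32
    # architecture details not fixed by the published table
    max_len: int = 50
    conv_channels: int = 16
    conv_width: int = 3
    conv_dim: int | None = None  # channel vector size; None -> 2 * hidden_size
    norm_mode: str = "softmax"
    similarity_source: str = "embedding"
    squash_variant: str = "printed"
    capsule_mode: str = "routing"
    use_attention: bool = True
    head_hidden: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("embedding_size", "hidden_size", "n_capsules", "capsule_dim",
                     "routing_iters", "batch_size", "max_len", "conv_channels",
                     "conv_width", "head_hidden"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.capsule_mode not in CAPSULE_MODES:
            raise ValueError(f"capsule_mode must be one of {CAPSULE_MODES}")
        if self.norm_mode not in NORM_MODES:
            raise ValueError(f"norm_mode must be one of {NORM_MODES}")
        if self.similarity_source not in SIMILARITY_SOURCES:
            raise ValueError(f"similarity_source must be one of {SIMILARITY_SOURCES}")
        if self.squash_variant not in SQUASH_VARIANTS:
            raise ValueError(f"squash_variant must be one of {SQUASH_VARIANTS}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate is a drop probability in [0, 1)")

    @property
    def resolved_conv_dim(self) -> int:
        return self.conv_dim if self.conv_dim is not None else 2 * self.hidden_size

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with Path(path).open(encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def preset(cls, name: str, **overrides) -> "ModelConfig":
        presets_dir = Path(__file__).parent / "configs"
        path = presets_dir / f"{name}.yaml"
        if not path.exists():
            available = sorted(p.stem for p in presets_dir.glob("*.yaml"))
            raise ValueError(f"unknown preset {name!r}; available: {available}")
        cfg = cls.from_yaml(path)
        return dataclasses.replace(cfg, **overrides) if overrides else cfg

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class MatchPrediction:
    """Model output for one pair: probability, thresholded label at 0.5,
    and (optionally) the attention weight matrix for visualization."""

    probability: float
    label: int
    attention: np.ndarray | None = None


def ablation_variants(base: ModelConfig) -> dict[str, ModelConfig]:
    """The base configuration plus the three single-switch ablations:
    routing replaced by max pooling, by mean pooling, and attention removed
    (routing kept)."""
    return {
        "full": base,
        "wo_routing_max": dataclasses.replace(base, capsule_mode="max"),
        "wo_routing_mean": dataclasses.replace(base, capsule_mode="mean"),
        "wo_attention": dataclasses.replace(base, use_attention=False),
    }


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _make_bilstm(rng: np.random.Generator, in_dim: int, H: int) -> BiLstmParams:
    def one_direction():
        w = Tensor(_glorot(rng, (in_dim, 4 * H)), requires_grad=True)
        u = Tensor(_glorot(rng, (H, 4 * H)), requires_grad=True)
        b = np.zeros(4 * H)
        b[H:2 * H] = 1.0  # forget-gate bias starts open
        return w, u, Tensor(b, requires_grad=True)

    wf, uf, bf = one_direction()
    wb, ub, bb = one_direction()
    return BiLstmParams(wf, uf, bf, wb, ub, bb)


class CapsTMModel:
    """Trainable capsule matcher bound to a vocabulary."""

    def __init__(self, config: ModelConfig, vocab: Vocab, embeddings: EmbeddingTable | None = None):
        if embeddings is not None and embeddings.matrix.shape != (len(vocab), config.embedding_size):
            raise ValueError(
                f"embedding table shape {embeddings.matrix.shape} does not match "
                f"(|vocab|={len(vocab)}, E={config.embedding_size})"
            )
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(config.seed)
        E, H = config.embedding_size, config.hidden_size
        J, d = config.n_capsules, config.capsule_dim
        I, w, C = config.conv_channels, config.conv_width, config.resolved_conv_dim

        if embeddings is None:
            table = rng.uniform(-0.1, 0.1, size=(len(vocab), E))
            table[PAD_INDEX] = 0.0
        else:
            table = embeddings.matrix.copy()
        self.embed = Tensor(table, requires_grad=True)

        self.highway = HighwayParams(
            w_f=Tensor(_glorot(rng, (E, E)), requires_grad=True),
            b_f=Tensor(np.zeros(E), requires_grad=True),
            w_g=Tensor(_glorot(rng, (E, E)), requires_grad=True),
            b_g=Tensor(np.zeros(E), requires_grad=True),
        )
        self.rep_lstm = _make_bilstm(rng, E, H)
        attended_dim = E if config.similarity_source == "embedding" else 2 * H
        agg_in = 2 * H + (attended_dim if config.use_attention else 0)
        self.agg_lstm = _make_bilstm(rng, agg_in, H)
        self.capsules = CapsuleParams(
            conv_w=Tensor(_glorot(rng, (w * 2 * H, I * C)), requires_grad=True),
            conv_b=Tensor(np.zeros(I * C), requires_grad=True),
            caps_w=Tensor(_glorot(rng, (C, J * d)), requires_grad=True),
            caps_b=Tensor(np.zeros(d), requires_grad=True),
            width=w,
            n_channels=I,
            n_capsules=J,
            capsule_dim=d,
        )
        fusion_dim = 3 * J * d + 1
        self.head = PredictHeadParams(
            w1=Tensor(_glorot(rng, (fusion_dim, config.head_hidden)), requires_grad=True),
            b1=Tensor(np.zeros(config.head_hidden), requires_grad=True),
            w2=Tensor(_glorot(rng, (config.head_hidden, 1)), requires_grad=True),
            b2=Tensor(np.zeros(1), requires_grad=True),
        )

    # -- parameter plumbing ---------------------------------------------------

    def named_parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {"embed": self.embed}
        for prefix, obj in (("highway", self.highway), ("rep", self.rep_lstm),
                            ("agg", self.agg_lstm), ("caps", self.capsules),
                            ("head", self.head)):
            for f in dataclasses.fields(obj):
                value = getattr(obj, f.name)
                if isinstance(value, Tensor):
                    params[f"{prefix}.{f.name}"] = value
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    # -- forward --------------------------------------------------------------

    def _dropout(self, x: Tensor, rng: np.random.Generator | None) -> Tensor:
        rate = self.config.dropout_rate
        if rng is None or rate <= 0.0:
            return x
        keep = 1.0 - rate
        mask = (rng.random(x.shape) < keep).astype(np.float64) / keep
        return x * Tensor(mask)

    def forward(
        self,
        batch: TokenizedBatch,
        training: bool = False,
        dropout_rng: np.random.Generator | None = None,
        return_attention: bool = False,
    ):
        """Match probabilities for a batch; optionally the attention weights.

        ``training=True`` enables dropout on the embeddings and on both
        BiLSTM outputs (``dropout_rng`` supplies the masks; omit it for a
        deterministic pass).
        """
        cfg = self.config
        rng = dropout_rng if training else None
        mask_a, mask_b = batch.mask_a, batch.mask_b

        emb_a = self._dropout(embedding(self.embed, batch.ids_a), rng)
        emb_b = self._dropout(embedding(self.embed, batch.ids_b), rng)
        e_a = highway(emb_a, self.highway)
        e_b = highway(emb_b, self.highway)
        h_a = self._dropout(bilstm_encode(e_a, mask_a, self.rep_lstm), rng)
        h_b = self._dropout(bilstm_encode(e_b, mask_b, self.rep_lstm), rng)

        attention = None
        if cfg.use_attention:
            if cfg.similarity_source == "embedding":
                src_a, src_b = e_a, e_b
            else:
                src_a, src_b = h_a, h_b
            att = interaction_attention(src_a, src_b, mask_a, mask_b, cfg.norm_mode)
            attention = att
            c_a = concat_representation(h_a, att.attended_a)
            c_b = concat_representation(h_b, att.attended_b)
        else:
            c_a, c_b = h_a, h_b

        S_a = self._dropout(aggregate(c_a, mask_a, self.agg_lstm), rng)
        S_b = self._dropout(aggregate(c_b, mask_b, self.agg_lstm), rng)
        u_hat_a = capsule_features(S_a, mask_a, self.capsules, cfg.activation)
        u_hat_b = capsule_features(S_b, mask_b, self.capsules, cfg.activation)

        if cfg.capsule_mode == "routing":
            d_a, _ = dynamic_routing(u_hat_a, cfg.routing_iters, cfg.squash_variant)
            d_b, _ = dynamic_routing(u_hat_b, cfg.routing_iters, cfg.squash_variant)
        else:
            d_a = pool_capsules(u_hat_a, cfg.capsule_mode, cfg.squash_variant)
            d_b = pool_capsules(u_hat_b, cfg.capsule_mode, cfg.squash_variant)

        batch_size = len(batch)
        C1 = d_a.reshape(batch_size, cfg.n_capsules * cfg.capsule_dim)
        C2 = d_b.reshape(batch_size, cfg.n_capsules * cfg.capsule_dim)
        fused = fuse(C1, C2)
        probs = predict_head(fused, self.head, cfg.activation)
        if return_attention:
            return probs, attention
        return probs

    def predict(self, batch: TokenizedBatch, return_attention: bool = False) -> list[MatchPrediction]:
        """Deterministic (no-dropout) predictions with labels at threshold 0.5."""
        with no_grad():
            if return_attention:
                probs, att = self.forward(batch, return_attention=True)
            else:
                probs = self.forward(batch)
                att = None
        out = []
        for i, p in enumerate(probs.data):
            weights = None
            if att is not None:
                la, lb = int(batch.lengths_a[i]), int(batch.lengths_b[i])
                weights = att.a_fwd.data[i, :la, :lb].copy()
            out.append(MatchPrediction(probability=float(p), label=int(p >= 0.5), attention=weights))
        return out

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write parameters (npz) plus a JSON sidecar with the full config,
        the vocabulary and its hash."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {name: t.data for name, t in self.named_parameters().items()}
        np.savez(str(path.with_suffix(".npz")), **arrays)
        sidecar = {
            "config": self.config.to_dict(),
            "vocab": self.vocab.tokens,
            "vocab_hash": self.vocab.content_hash(),
            "config_hash": self.config.config_hash(),
        }
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, ensure_ascii=False, indent=1), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "CapsTMModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
        config = ModelConfig.from_dict(sidecar["config"])
        vocab = Vocab(token_to_index={tok: i for i, tok in enumerate(sidecar["vocab"])})
        if vocab.content_hash() != sidecar["vocab_hash"]:
            raise ValueError("checkpoint vocabulary hash mismatch")
        model = cls(config, vocab)
        with np.load(str(path.with_suffix(".npz"))) as arrays:
            for name, tensor in model.named_parameters().items():
                tensor.data = arrays[name].astype(np.float64)
        return model


def loss(probabilities: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy; probabilities clipped 1e-7 away from 0/1."""
    p = ad.as_tensor(probabilities)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"probabilities shape {p.shape} != labels shape {y.shape}")
    p = p.clip(1e-7, 1.0 - 1e-7)
    yt = Tensor(y)
    bce = -(yt * p.log() + (1.0 - yt) * (1.0 - p).log())
    return bce.mean()
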