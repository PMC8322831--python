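"""Question-pair corpus I/O: datasets, tokenization, vocabularies, batches.

Datasets are UTF-8 TSV (``text_a<TAB>text_b<TAB>label``, label in {0,1};
two columns in prediction mode) or JSONL with keys ``text_a``, ``text_b``
and optional ``label``.  Pretrained token vectors are consumed in word2vec
text format.  Tokenization defaults to character level, the standard choice
for Chinese question matching; a whitespace mode is provided for
space-delimited text.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PAD_INDEX = 0
UNK_INDEX = 1
PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"


@dataclass(frozen=True)
class QuestionPair:
    """Two raw question texts and, when known, a binary match label."""

    pair_id: str
    text_a: str
    text_b: str
    label: int | None = None

    def __post_init__(self):
        if not self.text_a.strip() or not self.text_b.strip():
            raise ValueError(f"pair {self.pair_id}: empty text")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"pair {self.pair_id}: label must be 0 or 1, got {self.label}")


@dataclass
class Vocab:
    """Dense token -> index table with reserved PAD=0 and UNK=1 rows."""

    token_to_index: dict[str, int] = field(
        default_factory=lambda: {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    )

    def __len__(self) -> int:
        return len(self.token_to_index)

    def __contains__(self, token: str) -> bool:
        return token in self.token_to_index

    def index(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def add(self, token: str) -> int:
        if token not in self.token_to_index:
            self.token_to_index[token] = len(self.token_to_index)
        return self.token_to_index[token]

    @property
    def tokens(self) -> list[str]:
        return list(self.token_to_index)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for tok, idx in self.token_to_index.items():
            h.update(f"{tok}\t{idx}\n".encode("utf-8"))
        return h.hexdigest()[:16]


@dataclass
class TokenizedBatch:
    """Padded, masked index matrices for a batch of question pairs.

    Both sides are padded to one shared length ``n``; the mask is 1 exactly
    on non-PAD positions.
    """

    ids_a: np.ndarray
    ids_b: np.ndarray
    mask_a: np.ndarray
    mask_b: np.ndarray
    lengths_a: np.ndarray
    lengths_b: np.ndarray
    labels: np.ndarray | None = None

    def __len__(self) -> int:
        return self.ids_a.shape[0]

    @property
    def max_len(self) -> int:
        return self.ids_a.shape[1]


@dataclass
class EmbeddingTable:
    """|vocab| x E matrix of token vectors; the PAD row is all zeros."""

    matrix: np.ndarray

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def load_pairs(path: str | Path, format: str | None = None) -> list[QuestionPair]:
    """Read question pairs from a TSV or JSONL file, order preserved.

    ``format`` is inferred from the suffix when omitted.  Malformed records
    raise a ``ValueError`` naming the offending line.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in (".jsonl", ".json") else "tsv"
    if format not in ("tsv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")

    pairs: list[QuestionPair] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            try:
                if format == "tsv":
                    fields = line.split("\t")
                    if len(fields) == 3:
                        text_a, text_b, label_s = fields
                        label = _parse_label(label_s)
                    elif len(fields) == 2:
                        text_a, text_b = fields
                        label = None
                    else:
                        raise ValueError(f"expected 2 or 3 tab-separated fields, got {len(fields)}")
                else:
                    obj = json.loads(line)
                    text_a, text_b = obj["text_a"], obj["text_b"]
                    label = _parse_label(obj["label"]) if "label" in obj and obj["label"] is not None else None
                pairs.append(QuestionPair(pair_id=f"{path.name}:{lineno}", text_a=text_a, text_b=text_b, label=label))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed record: {exc}") from exc
    return pairs


def _parse_label(value) -> int:
    label = int(value)
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {value!r}")
    return label


def write_pairs_tsv(pairs: Iterable[QuestionPair], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for p in pairs:
            if p.label is None:
                fh.write(f"{p.text_a}\t{p.text_b}\n")
            else:
                fh.write(f"{p.text_a}\t{p.text_b}\t{p.label}\n")


def tokenize(text: str, mode: str = "char") -> list[str]:
    """Split text into tokens: ``char`` = Unicode characters (whitespace
    dropped), ``whitespace`` = split on runs of whitespace."""
    if mode == "char":
        return [ch for ch in text if not ch.isspace()]
    if mode == "whitespace":
        return text.split()
    raise ValueError(f"unknown tokenize mode {mode!r}")


def build_vocab(
    pairs: Sequence[QuestionPair], min_count: int = 1, mode: str = "char"
) -> Vocab:
    """Build a vocabulary over both sides of all pairs.

    Tokens with corpus frequency >= ``min_count`` enter in first-occurrence
    order (deterministic); a token appearing in both texts of a pair counts
    once per occurrence.
    """
    if not pairs:
        raise ValueError("cannot build a vocabulary from zero pairs")
    counts: Counter[str] = Counter()
    order: list[str] = []
    seen: set[str] = set()
    for pair in pairs:
        for text in (pair.text_a, pair.text_b):
            for tok in tokenize(text, mode):
                counts[tok] += 1
                if tok not in seen:
                    seen.add(tok)
                    order.append(tok)
    vocab = Vocab()
    for tok in order:
        if counts[tok] >= min_count:
            vocab.add(tok)
    return vocab


def encode_batch(
    pairs: Sequence[QuestionPair],
    vocab: Vocab,
    n: int,
    mode: str = "char",
) -> TokenizedBatch:
    """Tokenize, index, truncate to ``n`` and right-pad a batch of pairs.

    Unknown tokens map to UNK; both sides share the same padded length so
    that the downstream attention matrix is square.
    """
    if n < 1:
        raise ValueError(f"max length n must be >= 1, got {n}")
    batch = len(pairs)
    ids_a = np.zeros((batch, n), dtype=np.int64)
    ids_b = np.zeros((batch, n), dtype=np.int64)
    lengths_a = np.zeros(batch, dtype=np.int64)
    lengths_b = np.zeros(batch, dtype=np.int64)
    for row, pair in enumerate(pairs):
        for ids, lengths, text in ((ids_a, lengths_a, pair.text_a), (ids_b, lengths_b, pair.text_b)):
            toks = tokenize(text, mode)[:n]
            lengths[row] = len(toks)
            for col, tok in enumerate(toks):
                ids[row, col] = vocab.index(tok)
    mask_a = (np.arange(n)[None, :] < lengths_a[:, None]).astype(np.float64)
    mask_b = (np.arange(n)[None, :] < lengths_b[:, None]).astype(np.float64)
    labels = None
    if all(p.label is not None for p in pairs) and batch > 0:
        labels = np.array([p.label for p in pairs], dtype=np.float64)
    return TokenizedBatch(ids_a, ids_b, mask_a, mask_b, lengths_a, lengths_b, labels)


def load_word_vectors(
    path: str | Path,
    vocab: Vocab,
    dim: int,
    seed: int = 0,
    init_scale: float = 0.05,
) -> EmbeddingTable:
    """Load vectors in word2vec text format for the tokens of ``vocab``.

    Format: header line ``vocab_size dim``, then one ``token v1 ... vdim``
    per line.  Vocabulary tokens absent from the file get a seeded uniform
    row in [-init_scale, init_scale]; the PAD row is zeroed.
    """
    path = Path(path)
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(-init_scale, init_scale, size=(len(vocab), dim))
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header!r}")
        file_dim = int(header[1])
        if file_dim != dim:
            raise ValueError(f"{path}: file declares dim {file_dim}, requested {dim}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(" ")
            if not parts or parts == [""]:
                continue
            token, values = parts[0], parts[1:]
            if len(values) != dim:
                raise ValueError(f"{path}:{lineno}: expected {dim} values, got {len(values)}")
            if token in vocab:
                matrix[vocab.index(token)] = [float(v) for v in values]
    matrix[PAD_INDEX] = 0.0
    return EmbeddingTable(matrix=matrix)


def random_embeddings(vocab: Vocab, dim: int, seed: int = 0, scale: float = 0.1) -> EmbeddingTable:
    """Seeded random table for training from scratch; PAD row zeroed."""
    rng = np.random.default_rng(seed)
    matrix = rng.uniform(-scale, scale, size=(len(vocab), dim))
    matrix[PAD_INDEX] = 0.0
    return EmbeddingTable(matrix=matrix)
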