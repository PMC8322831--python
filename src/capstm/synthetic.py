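"""Synthetic question-pair corpora with controllable difficulty.

Real short-question matching corpora pair questions that share an intent
(paraphrases) against questions about different topics, with topic-swap
confusions as the documented hard case.  This generator emulates that
structure at desk scale:

* a small symbol vocabulary (CJK-range characters, so character-level
  tokenization applies unchanged) split into *topic* tokens and *content*
  tokens, the content tokens grouped into synonym pairs;
* a handful of question *templates* ("families"), each a fixed content-token
  sequence with one topic slot;
* **positive** pairs: two realizations of the same (family, topic), each
  independently perturbed by synonym substitution and local token swaps at
  rate ``paraphrase_ops``;
* **negative** pairs: different topics — half of them *hard* negatives from
  the same family (identical phrasing, one swapped topic token), the rest
  from different families.

Labels are correct by construction (match iff the topics agree) and the
whole corpus is reproducible from the seed.  The default class balance
(39% positive) follows the published corpus statistics for this task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .corpus_io import QuestionPair, TokenizedBatch, Vocab, encode_batch

_CJK_BASE = 0x4E00


@dataclass
class SynthConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_pairs: int = 1000
    positive_fraction: float = 0.39
    vocab_size: int = 60
    n_topics: int = 10
    n_families: int = 6
    template_length: int = 8
    paraphrase_ops: float = 0.2
    hard_negative_fraction: float = 0.5
    dev_fraction: float = 0.1
    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if self.vocab_size <= self.n_topics:
            raise ValueError("vocab_size must exceed n_topics")
        if not 0.0 <= self.paraphrase_ops <= 1.0:
            raise ValueError("paraphrase_ops must lie in [0, 1]")
        n_content_pairs = (self.vocab_size - self.n_topics) // 2
        if n_content_pairs < self.template_length - 1:
            raise ValueError(
                f"vocabulary too small: {self.vocab_size} symbols minus "
                f"{self.n_topics} topic tokens leaves {n_content_pairs} synonym "
                f"pairs, but templates need {self.template_length - 1}"
            )

    def to_dict(self) -> dict:
        import dataclasses

        return dataclasses.asdict(self)


@dataclass
class PairOrigin:
    """Generator-side provenance of one pair, for label re-derivation."""

    family_a: int
    topic_a: int
    family_b: int
    topic_b: int

    @property
    def label(self) -> int:
        return int(self.topic_a == self.topic_b)

    @property
    def is_hard_negative(self) -> bool:
        return self.label == 0 and self.family_a == self.family_b


@dataclass
class SynthCorpus:
    train: list[QuestionPair]
    dev: list[QuestionPair]
    test: list[QuestionPair]
    generator_metadata: SynthConfig = field(default_factory=SynthConfig)
    origins: dict[str, PairOrigin] = field(default_factory=dict)

    @property
    def splits(self) -> dict[str, list[QuestionPair]]:
        return {"train": self.train, "dev": self.dev, "test": self.test}

    def hard_negative_slice(self, split: str = "test") -> list[QuestionPair]:
        return [p for p in self.splits[split] if self.origins[p.pair_id].is_hard_negative]


class _Generator:
    def __init__(self, config: SynthConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        symbols = [chr(_CJK_BASE + i) for i in range(config.vocab_size)]
        self.topics = symbols[: config.n_topics]
        content = symbols[config.n_topics:]
        self.synonym_pairs = [
            (content[2 * k], content[2 * k + 1]) for k in range(len(content) // 2)
        ]
        self.synonym_of = {}
        for a, b in self.synonym_pairs:
            self.synonym_of[a] = b
            self.synonym_of[b] = a
        # one template per family: distinct synonym-pair representatives plus
        # a topic slot at a family-specific position
        self.templates: list[tuple[list[str], int]] = []
        for _ in range(config.n_families):
            pair_idx = self.rng.choice(len(self.synonym_pairs),
                                       size=config.template_length - 1, replace=False)
            tokens = [self.synonym_pairs[k][0] for k in pair_idx]
            slot = int(self.rng.integers(0, config.template_length))
            self.templates.append((tokens, slot))

    def realize(self, family: int, topic: int) -> str:
        tokens, slot = self.templates[family]
        seq = list(tokens)
        seq.insert(slot, self.topics[topic])
        ops = self.config.paraphrase_ops
        if ops > 0:
            seq = [
                self.synonym_of.get(t, t) if t in self.synonym_of and self.rng.random() < ops else t
                for t in seq
            ]
            if len(seq) > 1 and self.rng.random() < ops:
                i = int(self.rng.integers(0, len(seq) - 1))
                seq[i], seq[i + 1] = seq[i + 1], seq[i]
        return "".join(seq)

    def make_pair(self, pair_id: str, label: int) -> tuple[QuestionPair, PairOrigin]:
        cfg = self.config
        family_a = int(self.rng.integers(0, cfg.n_families))
        topic_a = int(self.rng.integers(0, cfg.n_topics))
        if label == 1:
            family_b, topic_b = family_a, topic_a
        else:
            if self.rng.random() < cfg.hard_negative_fraction:
                family_b = family_a
            else:
                family_b = int((family_a + 1 + self.rng.integers(0, cfg.n_families - 1)) % cfg.n_families) \
                    if cfg.n_families > 1 else family_a
            topic_b = int((topic_a + 1 + self.rng.integers(0, cfg.n_topics - 1)) % cfg.n_topics)
        origin = PairOrigin(family_a, topic_a, family_b, topic_b)
        pair = QuestionPair(
            pair_id=pair_id,
            text_a=self.realize(family_a, topic_a),
            text_b=self.realize(family_b, topic_b),
            label=label,
        )
        return pair, origin

    def make_split(self, name: str, size: int) -> tuple[list[QuestionPair], dict[str, PairOrigin]]:
        n_pos = int(round(size * self.config.positive_fraction))
        labels = np.array([1] * n_pos + [0] * (size - n_pos))
        self.rng.shuffle(labels)
        pairs, origins = [], {}
        for i, y in enumerate(labels):
            pair, origin = self.make_pair(f"synth-{name}-{i:06d}", int(y))
            pairs.append(pair)
            origins[pair.pair_id] = origin
        return pairs, origins


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate disjoint train/dev/test splits per the configuration.

    Each split independently realizes ``round(size · positive_fraction)``
    positive pairs, so the realized class balance is exact by construction.
    """
    gen = _Generator(config)
    n_dev = int(round(config.n_pairs * config.dev_fraction))
    n_test = int(round(config.n_pairs * config.test_fraction))
    n_train = config.n_pairs - n_dev - n_test
    if n_train < 1:
        raise ValueError("split fractions leave no training pairs")
    corpus = SynthCorpus(train=[], dev=[], test=[], generator_metadata=config)
    for name, size in (("train", n_train), ("dev", n_dev), ("test", n_test)):
        pairs, origins = gen.make_split(name, size)
        corpus.splits[name].extend(pairs)
        corpus.origins.update(origins)
    return corpus


# --------------------------------------------------------------------------
# fixed worked example shared by layer-level tests
# --------------------------------------------------------------------------

_WORKED_PAIRS = [
    QuestionPair("worked-0", "甲乙丙丁", "甲乙丙戊", 1),
    QuestionPair("worked-1", "甲乙丙丁", "己庚辛", 0),
]


def worked_vocab() -> Vocab:
    vocab = Vocab()
    for ch in "甲乙丙丁戊己庚辛":
        vocab.add(ch)
    return vocab


def make_worked_batch() -> TokenizedBatch:
    """Fixed 2-example batch (one match, one mismatch), padded to n=6.

    Identical on every call; the shared fixture for layer-level tests.
    """
    return encode_batch(_WORKED_PAIRS, worked_vocab(), n=6)


def worked_pairs() -> list[QuestionPair]:
    return list(_WORKED_PAIRS)


def write_corpus(corpus: SynthCorpus, out_dir) -> None:
    """Write train/dev/test TSVs plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    from .corpus_io import write_pairs_tsv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, pairs in corpus.splits.items():
        write_pairs_tsv(pairs, out / f"{name}.tsv")
    meta = {
        "config": corpus.generator_metadata.to_dict(),
        "sizes": {k: len(v) for k, v in corpus.splits.items()},
        "positives": {k: sum(p.label for p in v) for k, v in corpus.splits.items()},
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
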