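"""Encoders producing per-word hidden vectors ``H = [h_1 .. h_n]``.

The downstream modules only rely on the encoder contract: given ``n`` input
tokens, return an ``(n, d1)`` matrix of finite hidden vectors whose parameters
are trainable end-to-end. Two encoder kinds are declared:

* ``tiny`` — a seeded, self-contained transformer-style encoder (token +
  learned position embeddings followed by one or two single-head
  self-attention blocks with a small feed-forward). It is fully determined by
  ``(d1, vocabulary, seed)`` and exists so the complete tagging pipeline can
  be trained and tested at desk scale.
* ``pretrained-transformer`` — the profile a full-scale biomedical run would
  use (a 12-layer, 768-wide pretrained encoder, fine-tuned). Constructing it
  requires external pretrained weights and is not available in this build.

Subword-based encoders are reduced to word level with the first-subtoken rule
(:func:`pool_subwords`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, masked_softmax
from .corpus_io import Corpus
from .errors import ConfigurationError, DataError

__all__ = [
    "WordVocabulary",
    "EncoderSpec",
    "TinyEncoder",
    "build_encoder",
    "encode",
    "pool_subwords",
]


@dataclass
class WordVocabulary:
    """Word-form to id mapping with a reserved UNK entry.

    Built deterministically (sorted forms) so two builds from the same corpora
    are identical. Special tokens (e.g. multi-task tag identifiers) are
    appended as atomic entries and never split.
    """

    UNK: str = "<UNK>"
    _ids: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._ids:
            self._ids = {self.UNK: 0}

    @classmethod
    def from_corpora(
        cls, corpora: Sequence[Corpus], special_tokens: Iterable[str] = ()
    ) -> "WordVocabulary":
        vocab = cls()
        forms = sorted({tok for corpus in corpora for s in corpus for tok in s.tokens})
        for form in forms:
            vocab._ids.setdefault(form, len(vocab._ids))
        for tok in special_tokens:
            vocab._ids.setdefault(tok, len(vocab._ids))
        return vocab

    def add_special_tokens(self, tokens: Iterable[str]) -> None:
        for tok in tokens:
            self._ids.setdefault(tok, len(self._ids))

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, form: str) -> bool:
        return form in self._ids

    def __getitem__(self, form: str) -> int:
        return self._ids.get(form, self._ids[self.UNK])

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self[t] for t in tokens], dtype=np.int64)

    def to_dict(self) -> dict[str, int]:
        return dict(self._ids)

    @classmethod
    def from_dict(cls, mapping: dict[str, int]) -> "WordVocabulary":
        vocab = cls()
        vocab._ids = dict(mapping)
        return vocab


@dataclass
class EncoderSpec:
    """Configuration of an encoder profile."""

    kind: str = "tiny"  # "tiny" | "pretrained-transformer"
    d1: int = 32
    seed: int = 0
    n_blocks: int = 1
    max_seq_len: int = 128
    subword_pooling: str = "first-subtoken"
    pretrained_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.d1 <= 0:
            raise ConfigurationError("encoder width d1 must be positive")
        if self.kind not in ("tiny", "pretrained-transformer"):
            raise ConfigurationError(f"unknown encoder kind {self.kind!r}")
        if self.subword_pooling != "first-subtoken":
            raise ConfigurationError("only first-subtoken pooling is supported")


class TinyEncoder:
    """Seeded trainable word encoder: embeddings + single-head attention blocks.

    All parameters are float64 and updated by the training loop; with a fixed
    seed and vocabulary the initial forward pass is bit-reproducible.
    """

    def __init__(self, vocab: WordVocabulary, spec: EncoderSpec):
        if spec.kind != "tiny":
            raise ConfigurationError("TinyEncoder requires spec.kind == 'tiny'")
        self.vocab = vocab
        self.spec = spec
        d = spec.d1
        rng = np.random.default_rng(spec.seed)
        scale = 1.0 / np.sqrt(d)
        self.params: dict[str, Parameter] = {
            "tok_emb": Parameter(rng.normal(0.0, 0.3, size=(len(vocab), d))),
            "pos_emb": Parameter(rng.normal(0.0, 0.1, size=(spec.max_seq_len, d))),
        }
        for b in range(spec.n_blocks):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                self.params[f"block{b}.{name}"] = Parameter(
                    rng.normal(0.0, scale, size=(d, d))
                )
            self.params[f"block{b}.W1"] = Parameter(rng.normal(0.0, scale, size=(d, 2 * d)))
            self.params[f"block{b}.b1"] = Parameter(np.zeros(2 * d))
            self.params[f"block{b}.W2"] = Parameter(
                rng.normal(0.0, 1.0 / np.sqrt(2 * d), size=(2 * d, d))
            )
            self.params[f"block{b}.b2"] = Parameter(np.zeros(d))
        # Local bigram mixing: adds each position's left neighbour through a
        # learned projection. Attention with absolute position embeddings
        # generalizes poorly on relative-neighbour patterns at tiny scale;
        # this width-2 causal convolution supplies that inductive bias.
        self.params["W_prev"] = Parameter(rng.normal(0.0, scale, size=(d, d)))

    @property
    def d1(self) -> int:
        return self.spec.d1

    def parameters(self) -> dict[str, Parameter]:
        return dict(self.params)

    def forward(self, tokens: Sequence[str]) -> Tensor:
        """Encode a token sequence into an ``(n, d1)`` hidden matrix."""
        if len(tokens) == 0:
            raise DataError("cannot encode an empty token sequence")
        if len(tokens) > self.spec.max_seq_len:
            raise DataError(
                f"sequence of {len(tokens)} tokens exceeds max_seq_len "
                f"{self.spec.max_seq_len}; truncate before encoding"
            )
        ids = self.vocab.encode(tokens)
        n = len(ids)
        d = self.spec.d1
        x = self.params["tok_emb"].take_rows(ids) + self.params["pos_emb"].take_rows(
            np.arange(n)
        )
        for b in range(self.spec.n_blocks):
            q = x @ self.params[f"block{b}.Wq"]
            k = x @ self.params[f"block{b}.Wk"]
            v = x @ self.params[f"block{b}.Wv"]
            scores = (q @ k.swapaxes(-1, -2)) / np.sqrt(d)
            attn = masked_softmax(scores)
            x = x + (attn @ v) @ self.params[f"block{b}.Wo"]
            hidden = (x @ self.params[f"block{b}.W1"] + self.params[f"block{b}.b1"]).relu()
            x = x + hidden @ self.params[f"block{b}.W2"] + self.params[f"block{b}.b2"]
        prev_idx = np.maximum(np.arange(n) - 1, 0)
        not_first = Tensor((np.arange(n) > 0).astype(np.float64)[:, None])
        shifted = x.take_rows(prev_idx) * not_first
        return x + shifted @ self.params["W_prev"]


def build_encoder(spec: EncoderSpec, vocab: WordVocabulary) -> TinyEncoder:
    """Instantiate the encoder described by ``spec``."""
    if spec.kind == "pretrained-transformer":
        raise ConfigurationError(
            "encoder kind 'pretrained-transformer' requires external pretrained "
            "weights and a transformer runtime; this build ships the 'tiny' profile"
        )
    return TinyEncoder(vocab, spec)


def encode(tokens: Sequence[str], encoder: TinyEncoder) -> Tensor:
    """Functional wrapper over :meth:`TinyEncoder.forward`."""
    return encoder.forward(tokens)


def pool_subwords(
    subword_vectors: np.ndarray, word_alignment: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Reduce subword vectors to word vectors with the first-subtoken rule.

    ``word_alignment`` maps each word to a half-open ``[start, end)`` range of
    subword rows (0-based, contiguous, nonempty).
    """
    vectors = np.asarray(subword_vectors)
    rows = []
    for w, (start, end) in enumerate(word_alignment):
        if not 0 <= start < end <= vectors.shape[0]:
            raise DataError(f"word {w}: empty or out-of-range subword span [{start}, {end})")
        rows.append(start)
    return vectors[np.array(rows, dtype=np.int64)]
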