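"""Combined Feature Attention (CFA).

For each word ``x_i`` with hidden state ``h_i`` and syntactic context
``(S_i, L_i)`` of length ``m_i``:

1. context words are embedded by re-using the encoder hidden states,
   ``e^S_{i,j} = h_k`` where ``k`` is the sentence position of the context
   word (no separate word embedding table, so no out-of-vocabulary problem);
2. syntactic labels get trainable embeddings ``e^L_{i,j}`` of width ``d2``;
3. each pair is fused and projected back to the encoder width,
   ``e_{i,j} = W_e (e^S_{i,j} + e^L_{i,j}) + b_e`` (concatenation inside the
   parentheses), with ``W_e`` of shape ``(d1, d1 + d2)``;
4. scaled dot-product attention queried by ``h_i`` produces weights
   ``a_{i,j} = softmax(h_i . e_{i,j} / sqrt(d1))`` and the summary
   ``a_i = sum_j a_{i,j} e_{i,j}``;
5. the module output is the concatenation ``o_i = a_i (+) h_i`` of width
   ``2 d1``.

The per-token operations below state the contract one token at a time;
:func:`cfa_forward` is the batched implementation used in training (identical
values, padded to the longest context with masked softmax). Positions without
a syntactic context — multi-task tag identifiers — bypass attention with
``a_i = 0`` so the output width stays uniform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, concat, masked_softmax
from .errors import ConfigurationError
from .syntax_features import LabelVocabulary, SyntacticContext

__all__ = [
    "CfaParameters",
    "AttentionResult",
    "embed_context_features",
    "embed_syntactic_labels",
    "fuse_and_project",
    "attend",
    "cfa_forward",
]


@dataclass
class CfaParameters:
    """Trainable CFA parameters: label embedding table, projection, bias."""

    label_embeddings: Parameter
    projection_weight: Parameter  # W_e, shape (d1, d1 + d2)
    projection_bias: Parameter  # b_e, shape (d1,), broadcast across context columns
    init_seed: int = 0

    @classmethod
    def create(
        cls, n_labels: int, d1: int, d2: Optional[int] = None, seed: int = 0
    ) -> "CfaParameters":
        """Seeded initialization: label embeddings uniform in [-0.1, 0.1],
        projection uniform at the usual fan-in scale, zero bias."""
        d2 = d1 if d2 is None else d2
        if d1 <= 0 or d2 <= 0 or n_labels <= 0:
            raise ConfigurationError("CFA dimensions and label count must be positive")
        rng = np.random.default_rng(seed)
        bound = 1.0 / np.sqrt(d1 + d2)
        return cls(
            label_embeddings=Parameter(rng.uniform(-0.1, 0.1, size=(n_labels, d2))),
            projection_weight=Parameter(rng.uniform(-bound, bound, size=(d1, d1 + d2))),
            projection_bias=Parameter(np.zeros(d1)),
            init_seed=seed,
        )

    @property
    def d1(self) -> int:
        return self.projection_weight.shape[0]

    @property
    def d2(self) -> int:
        return self.label_embeddings.shape[1]

    def parameters(self) -> dict[str, Parameter]:
        return {
            "cfa.label_embeddings": self.label_embeddings,
            "cfa.projection_weight": self.projection_weight,
            "cfa.projection_bias": self.projection_bias,
        }


@dataclass
class AttentionResult:
    """Attention weights, summary vector and concatenated output for one token."""

    weights: np.ndarray  # (m_i,), positive, sums to 1
    summary: Tensor  # a_i, shape (1, d1)
    output: Tensor  # o_i = a_i (+) h_i, shape (1, 2*d1)


def embed_context_features(H: Tensor, context: SyntacticContext) -> Tensor:
    """Rows of ``H`` at the context positions: ``E^S_i`` with shape (m_i, d1)."""
    n = H.shape[0]
    for k in context.context_positions:
        if not 1 <= k <= n:
            raise IndexError(f"context position {k} outside sentence of length {n}")
    idx = np.array(context.context_positions, dtype=np.int64) - 1
    return H.take_rows(idx)


def embed_syntactic_labels(
    context: SyntacticContext, params: CfaParameters, vocab: LabelVocabulary
) -> Tensor:
    """Label embedding rows for ``L_i``: ``E^L_i`` with shape (m_i, d2)."""
    idx = np.array([vocab[label] for label in context.syntactic_labels], dtype=np.int64)
    return params.label_embeddings.take_rows(idx)


def fuse_and_project(E_S: Tensor, E_L: Tensor, params: CfaParameters) -> Tensor:
    """Fused syntactic feature matrix ``E_i``: project each concatenated column.

    Row ``j`` of the result is ``W_e (e^S_{i,j} (+) e^L_{i,j}) + b_e``.
    """
    if E_S.shape[0] != E_L.shape[0]:
        raise ConfigurationError(
            f"context and label embeddings disagree on m_i: {E_S.shape[0]} vs {E_L.shape[0]}"
        )
    if E_S.shape[-1] + E_L.shape[-1] != params.projection_weight.shape[1]:
        raise ConfigurationError(
            "projection expects width d1+d2 = "
            f"{params.projection_weight.shape[1]}, got {E_S.shape[-1]} + {E_L.shape[-1]}"
        )
    fused = concat([E_S, E_L], axis=-1)
    return fused @ params.projection_weight.swapaxes(0, 1) + params.projection_bias


def attend(h_i: Tensor, E_i: Tensor, d1: int) -> AttentionResult:
    """Scaled dot-product attention of ``h_i`` over the columns of ``E_i``."""
    if E_i.shape[0] < 1:
        raise ConfigurationError("attend requires a nonempty feature matrix (m_i >= 1)")
    h_row = h_i.reshape(1, d1)
    logits = (E_i @ h_row.swapaxes(0, 1)).swapaxes(0, 1) / np.sqrt(d1)  # (1, m)
    weights = masked_softmax(logits)
    summary = weights @ E_i  # (1, d1)
    output = concat([summary, h_row], axis=-1)
    return AttentionResult(weights=weights.data[0].copy(), summary=summary, output=output)


def cfa_forward(
    H: Tensor,
    contexts: Sequence[Optional[SyntacticContext]],
    params: CfaParameters,
    vocab: LabelVocabulary,
) -> Tensor:
    """Batched CFA over a sentence: one ``o_i`` row of width ``2 d1`` per position.

    ``contexts[i]`` may be ``None`` for positions without a parse (tag
    identifiers); those rows get ``a_i = 0`` and ``o_i = 0 (+) h_i``.
    """
    n, d1 = H.shape
    if len(contexts) != n:
        raise ConfigurationError(f"{len(contexts)} contexts for {n} hidden vectors")
    m_max = max((c.m if c is not None else 1) for c in contexts)
    pos_idx = np.zeros((n, m_max), dtype=np.int64)
    lab_idx = np.full((n, m_max), vocab.unk_id, dtype=np.int64)
    valid = np.zeros((n, m_max), dtype=bool)
    has_syntax = np.zeros(n, dtype=np.float64)
    for row, ctx in enumerate(contexts):
        if ctx is None:
            pos_idx[row, 0] = row  # dummy self-context; output zeroed below
            valid[row, 0] = True
            continue
        has_syntax[row] = 1.0
        m = ctx.m
        pos_idx[row, :m] = np.array(ctx.context_positions, dtype=np.int64) - 1
        lab_idx[row, :m] = [vocab[label] for label in ctx.syntactic_labels]
        valid[row, :m] = True

    E_S = H.take_rows(pos_idx)  # (n, m_max, d1)
    E_L = params.label_embeddings.take_rows(lab_idx)  # (n, m_max, d2)
    fused = concat([E_S, E_L], axis=-1)
    E = fused @ params.projection_weight.swapaxes(0, 1) + params.projection_bias
    logits = (E * H.reshape(n, 1, d1)).sum(axis=-1) / np.sqrt(d1)  # (n, m_max)
    weights = masked_softmax(logits, mask=valid)
    summary = (weights.reshape(n, m_max, 1) * E).sum(axis=1)  # (n, d1)
    summary = summary * Tensor(has_syntax[:, None])
    return concat([summary, H], axis=-1)
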