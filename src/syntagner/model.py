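"""Assembly of encoder, combined feature attention and tagging head.

:class:`NerModel` owns the vocabularies and all trainable parameter groups
and knows how to run a (possibly tag-wrapped) sentence end to end:

1. encode the wrapped token sequence into hidden vectors ``H``;
2. extract syntactic contexts on the *original* sentence and re-index them by
   the wrapping offset — tag identifier positions get no context and bypass
   attention with a zero summary;
3. concatenate attention summaries with hidden states and apply the softmax
   tagging head.

With ``feature_type="none"`` the attention module is disabled entirely and
the head reads the hidden states directly (the vanilla-encoder baseline).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, cross_entropy, masked_softmax
from .cfa import CfaParameters, cfa_forward
from .corpus_io import AnnotatedSentence, Corpus
from .encoding import EncoderSpec, TinyEncoder, WordVocabulary, build_encoder
from .errors import ConfigurationError
from .mtl import TagScheme, WrappedSentence, shift_context, wrap
from .syntax_features import (
    CONLL2003_CHUNK_LABELS,
    LabelVocabulary,
    SyntacticContext,
    build_context_sequences,
    build_label_vocabulary,
)
from .tagging import DEFAULT_LABELS, TagHead, decode

__all__ = ["NerModel", "build_model"]


@dataclass
class NerModel:
    """A complete syntax-aware sequence tagger."""

    word_vocab: WordVocabulary
    encoder: TinyEncoder
    head: TagHead
    scheme: TagScheme
    feature_type: str = "dependency"  # pos | constituent | dependency | none
    cfa_params: Optional[CfaParameters] = None
    syntax_vocab: Optional[LabelVocabulary] = None
    acceptable_labels: frozenset[str] = CONLL2003_CHUNK_LABELS
    window: int = 1
    label_set: tuple[str, ...] = DEFAULT_LABELS

    def __post_init__(self) -> None:
        if self.feature_type not in ("pos", "constituent", "dependency", "none"):
            raise ConfigurationError(f"unknown feature type {self.feature_type!r}")
        if self.feature_type != "none" and (self.cfa_params is None or self.syntax_vocab is None):
            raise ConfigurationError("CFA parameters and a syntax vocabulary are required")
        expected = 2 * self.encoder.d1 if self.feature_type != "none" else self.encoder.d1
        if self.head.input_width != expected:
            raise ConfigurationError(
                f"head width {self.head.input_width} incompatible with encoder "
                f"d1={self.encoder.d1} and feature_type={self.feature_type!r}"
            )
        self._label_ids = {lab: i for i, lab in enumerate(self.label_set)}

    @property
    def max_seq_len(self) -> int:
        return self.encoder.spec.max_seq_len

    def parameters(self) -> dict[str, Parameter]:
        params = {f"encoder.{k}": v for k, v in self.encoder.parameters().items()}
        if self.cfa_params is not None:
            params.update(self.cfa_params.parameters())
        params.update(self.head.parameters())
        return params

    # -- forward ---------------------------------------------------------

    def _contexts_for(self, ws: WrappedSentence) -> list[Optional[SyntacticContext]]:
        n_wrapped = len(ws.tokens)
        offset = ws.syntax_offset
        n_kept = int(sum(ws.label_mask))
        contexts = build_context_sequences(
            ws.sentence, self.feature_type, self.acceptable_labels, self.window
        )[:n_kept]
        if n_kept < len(ws.sentence):
            # Truncated wrapping: clip context positions to the surviving words.
            contexts = [_clip_context(c, n_kept) for c in contexts]
        shifted: list[Optional[SyntacticContext]] = [None] * n_wrapped
        for ctx in contexts:
            shifted[ctx.token_index - 1 + offset] = shift_context(ctx, offset)
        return shifted

    def forward_wrapped(self, ws: WrappedSentence) -> Tensor:
        """Per-position label logits for a wrapped sentence, shape (len, |labels|)."""
        H = self.encoder.forward(ws.tokens)
        if self.feature_type == "none":
            O = H
        else:
            O = cfa_forward(H, self._contexts_for(ws), self.cfa_params, self.syntax_vocab)
        return self.head.logits(O)

    def loss_wrapped(self, ws: WrappedSentence) -> Tensor:
        logits = self.forward_wrapped(ws)
        targets = np.array([self._label_ids[lab] for lab in ws.labels], dtype=np.int64)
        mask = np.array(ws.label_mask, dtype=bool)
        return cross_entropy(logits, targets, mask)

    def predict_wrapped(self, ws: WrappedSentence) -> tuple[str, ...]:
        """BIO labels for the original tokens of a wrapped sentence."""
        logits = self.forward_wrapped(ws)
        probs = masked_softmax(logits).data
        labels = decode(probs, self.label_set)
        return tuple(lab for lab, keep in zip(labels, ws.label_mask) if keep)

    def predict(self, sentence: AnnotatedSentence) -> tuple[str, ...]:
        """Predict a bare sentence (wrapping it if the model's scheme requires)."""
        ws = wrap(sentence, self.scheme, self.max_seq_len)
        return self.predict_wrapped(ws)


def _clip_context(ctx: SyntacticContext, n_kept: int) -> SyntacticContext:
    pairs = [
        (k, lab)
        for k, lab in zip(ctx.context_positions, ctx.syntactic_labels)
        if k <= n_kept
    ]
    return SyntacticContext(
        token_index=ctx.token_index,
        context_positions=tuple(k for k, _ in pairs),
        syntactic_labels=tuple(lab for _, lab in pairs),
        feature_type=ctx.feature_type,
    )


def build_model(
    corpora: Sequence[Corpus],
    scheme: Optional[TagScheme] = None,
    feature_type: str = "dependency",
    encoder_spec: Optional[EncoderSpec] = None,
    d2: Optional[int] = None,
    cfa_seed: int = 0,
    head_seed: int = 0,
    acceptable_labels: frozenset[str] = CONLL2003_CHUNK_LABELS,
    window: int = 1,
    label_set: Sequence[str] = DEFAULT_LABELS,
) -> NerModel:
    """Construct a model whose vocabularies are derived from training corpora.

    The word vocabulary covers all corpus tokens plus the scheme's tag
    identifier tokens (the only extra parameters a multi-task model carries);
    the syntactic label vocabulary covers all labels the chosen extractor
    emits on the training corpora, plus UNK.
    """
    scheme = scheme if scheme is not None else TagScheme(variant="NONE")
    encoder_spec = encoder_spec if encoder_spec is not None else EncoderSpec()
    word_vocab = WordVocabulary.from_corpora(corpora, scheme.all_special_tokens())
    encoder = build_encoder(encoder_spec, word_vocab)
    cfa_params = None
    syntax_vocab = None
    if feature_type != "none":
        syntax_vocab = build_label_vocabulary(corpora, feature_type, acceptable_labels, window)
        cfa_params = CfaParameters.create(
            n_labels=len(syntax_vocab), d1=encoder_spec.d1, d2=d2, seed=cfa_seed
        )
        head_width = 2 * encoder_spec.d1
    else:
        head_width = encoder_spec.d1
    head = TagHead(head_width, label_set=label_set, seed=head_seed)
    return NerModel(
        word_vocab=word_vocab,
        encoder=encoder,
        head=head,
        scheme=scheme,
        feature_type=feature_type,
        cfa_params=cfa_params,
        syntax_vocab=syntax_vocab,
        acceptable_labels=frozenset(acceptable_labels),
        window=window,
        label_set=tuple(label_set),
    )
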