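"""Fully-shared multi-task learning over multiple BIO corpora.

Instead of per-dataset decoder heads, every training sentence is wrapped in a
pair of tag identifier tokens that name its origin — ``<T> x_1 .. x_n </T>``
for a sentence from dataset ``T`` — and all datasets are pooled into a single
training stream. The tags are atomic vocabulary entries with trainable
embeddings; they are the only parameters the multi-task model adds over the
single-task model, so all task knowledge lives in shared weights. At
inference, the caller chooses which dataset's (or entity type's) annotation
convention to apply by picking the tag to wrap the input with; different
choices condition the shared representation differently and may yield
different predictions for the same sentence.

Wrapping variants:

* ``DN`` — dataset-name tag pair (default; distinguishes datasets even within
  one entity type),
* ``TN`` — entity-type-name tag pair,
* ``TN_DN`` — both pairs, type outermost,
* ``DN_no_end`` — leading dataset tag only (end-tag ablation),
* ``NONE`` — no tags: direct mixing, the degradation baseline.

Tag positions are labelled ``O`` internally but masked out of both the loss
and the evaluation, and they carry no syntactic context (the attention module
bypasses them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import AnnotatedSentence, Corpus
from .errors import ConfigurationError
from .syntax_features import SyntacticContext

__all__ = [
    "VARIANTS",
    "TagScheme",
    "WrappedSentence",
    "wrap",
    "unwrap_labels",
    "TrainingStream",
    "mix",
    "predict_with_tag",
    "parameter_count",
]

VARIANTS = ("DN", "TN", "TN_DN", "DN_no_end", "NONE")


@dataclass
class TagScheme:
    """Wrapping variant plus the dataset registry.

    ``registry`` maps a dataset name to ``(tag_name, entity_type)``; the tag
    tokens are derived as ``<tag_name>`` / ``</tag_name>`` (and likewise for
    the entity type), guaranteed not to collide with corpus words as long as
    corpus tokens never carry angle brackets in this shape.
    """

    variant: str = "DN"
    registry: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown MTL variant {self.variant!r}; choose from {VARIANTS}")
        tags = [tag for tag, _ in self.registry.values()]
        if len(tags) != len(set(tags)):
            raise ConfigurationError("tag names in the registry must be unique")

    def lookup(self, dataset_name: str) -> tuple[str, str]:
        if dataset_name not in self.registry:
            raise ConfigurationError(
                f"dataset {dataset_name!r} not registered; known: {sorted(self.registry)}"
            )
        return self.registry[dataset_name]

    def tag_tokens(self, dataset_name: str) -> tuple[list[str], list[str]]:
        """(leading tokens, trailing tokens) for a sentence of this dataset."""
        if self.variant == "NONE":
            return [], []
        tag, etype = self.lookup(dataset_name)
        if self.variant == "DN":
            return [f"<{tag}>"], [f"</{tag}>"]
        if self.variant == "DN_no_end":
            return [f"<{tag}>"], []
        if self.variant == "TN":
            return [f"<{etype}>"], [f"</{etype}>"]
        # TN_DN: type pair outermost, dataset pair inside
        return [f"<{etype}>", f"<{tag}>"], [f"</{tag}>", f"</{etype}>"]

    def all_special_tokens(self) -> list[str]:
        """Every tag token this scheme can emit, in deterministic order."""
        tokens: list[str] = []
        for dataset in sorted(self.registry):
            lead, trail = self.tag_tokens(dataset)
            for tok in lead + trail:
                if tok not in tokens:
                    tokens.append(tok)
        return tokens

    def resolve_tag(self, chosen: str) -> str:
        """Map a dataset name, entity type, or tag name to a registered dataset.

        Inference callers may know only the entity type; any dataset
        registered under that type is an acceptable carrier of its convention,
        so the first (sorted) one is used.
        """
        if chosen in self.registry:
            return chosen
        for dataset in sorted(self.registry):
            tag, etype = self.registry[dataset]
            if chosen in (tag, etype):
                return dataset
        raise ConfigurationError(
            f"unknown tag {chosen!r}; registered datasets: {sorted(self.registry)}, "
            f"types: {sorted({e for _, e in self.registry.values()})}"
        )


@dataclass
class WrappedSentence:
    """A sentence with tag identifiers attached and bookkeeping to undo it."""

    sentence: AnnotatedSentence
    tokens: tuple[str, ...]
    labels: tuple[str, ...]  # tag positions carry "O"
    label_mask: tuple[bool, ...]  # True = real word, participates in loss/eval
    syntax_offset: int  # displacement of original token positions

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def n_original(self) -> int:
        return len(self.sentence)


def wrap(
    sentence: AnnotatedSentence,
    scheme: TagScheme,
    max_seq_len: Optional[int] = None,
) -> WrappedSentence:
    """Attach tag identifiers around a sentence according to the scheme.

    If ``max_seq_len`` is given and wrapping would exceed it, interior words
    are truncated from the right so that the trailing tags always survive.
    """
    lead, trail = scheme.tag_tokens(sentence.source_dataset) if scheme.variant != "NONE" else ([], [])
    words = list(sentence.tokens)
    labels = list(sentence.labels) if sentence.labels is not None else ["O"] * len(words)
    if max_seq_len is not None:
        budget = max_seq_len - len(lead) - len(trail)
        if budget < 1:
            raise ConfigurationError(f"max_seq_len {max_seq_len} leaves no room for words")
        if len(words) > budget:
            words = words[:budget]
            labels = labels[:budget]
    tokens = tuple(lead + words + trail)
    full_labels = tuple(["O"] * len(lead) + labels + ["O"] * len(trail))
    mask = tuple([False] * len(lead) + [True] * len(words) + [False] * len(trail))
    return WrappedSentence(
        sentence=sentence,
        tokens=tokens,
        labels=full_labels,
        label_mask=mask,
        syntax_offset=len(lead),
    )


def unwrap_labels(wrapped: WrappedSentence, labels: Sequence[str]) -> tuple[str, ...]:
    """Strip tag positions from a per-position label sequence."""
    if len(labels) != len(wrapped.tokens):
        raise ConfigurationError(
            f"{len(labels)} labels for a wrapped sentence of {len(wrapped.tokens)} tokens"
        )
    return tuple(lab for lab, keep in zip(labels, wrapped.label_mask) if keep)


def shift_context(ctx: SyntacticContext, offset: int) -> SyntacticContext:
    """Re-index a syntactic context after tag tokens displaced the sentence."""
    if offset == 0:
        return ctx
    return SyntacticContext(
        token_index=ctx.token_index + offset,
        context_positions=tuple(k + offset for k in ctx.context_positions),
        syntactic_labels=ctx.syntactic_labels,
        feature_type=ctx.feature_type,
    )


class TrainingStream:
    """Pooled wrapped sentences with a deterministic per-epoch shuffle."""

    def __init__(self, wrapped: list[WrappedSentence], seed: int):
        if not wrapped:
            raise ConfigurationError("training stream is empty")
        self.wrapped = wrapped
        self.seed = int(seed)

    def __len__(self) -> int:
        return len(self.wrapped)

    def epoch(self, epoch_index: int) -> list[WrappedSentence]:
        """Sentence order for one epoch, a pure function of (seed, epoch)."""
        rng = np.random.default_rng((self.seed, epoch_index))
        order = rng.permutation(len(self.wrapped))
        return [self.wrapped[i] for i in order]


def mix(
    corpora: Sequence[Corpus],
    scheme: TagScheme,
    seed: int,
    max_seq_len: Optional[int] = None,
) -> TrainingStream:
    """Pool all corpora into one wrapped, seeded-shuffled training stream."""
    if not corpora:
        raise ConfigurationError("mix requires at least one corpus")
    wrapped = [
        wrap(sentence, scheme, max_seq_len)
        for corpus in corpora
        for sentence in corpus
    ]
    return TrainingStream(wrapped, seed)


def predict_with_tag(model, sentence: AnnotatedSentence, chosen: str) -> tuple[str, ...]:
    """Predict BIO labels for a sentence under a chosen dataset/type tag.

    The sentence is wrapped with the tag's pair, run through the model, and
    the tag positions are stripped from the output, so the result aligns with
    the original tokens.
    """
    scheme = model.scheme
    dataset = scheme.resolve_tag(chosen) if scheme.variant != "NONE" else sentence.source_dataset
    carrier = sentence
    if scheme.variant != "NONE" and sentence.source_dataset != dataset:
        from dataclasses import replace

        carrier = replace(sentence, source_dataset=dataset)
    wrapped = wrap(carrier, scheme, model.max_seq_len)
    return model.predict_wrapped(wrapped)


def parameter_count(parameters: dict) -> int:
    """Total number of scalar trainable parameters in a named parameter dict."""
    return int(sum(p.data.size for p in parameters.values()))
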