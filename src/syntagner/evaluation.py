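"""Entity-level precision / recall / F1 with macro averaging over entity types.

An entity is an exact ``(span, type)`` match between gold and prediction; a
boundary-shifted span counts as both a false positive and a false negative.
BIO sequences are converted to spans leniently, matching the default of the
widely used sequence-evaluation scorers: ``B`` always opens a span, and an
``I`` following ``O``, the sentence start, or a different type also opens one.

The macro-averaged F1 is the unweighted mean of per-type F1 over the entity
types present in the gold standard; with a single type it equals that type's
F1, which is the setting of the standard single-type benchmark corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .corpus_io import Corpus
from .errors import AlignmentError, ValidationError

__all__ = ["EntitySpan", "TypeScores", "EvalReport", "extract_entities", "score", "score_corpus"]


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A half-open token-position interval ``[start, end)`` with an entity type."""

    start: int
    end: int
    entity_type: str = ""


@dataclass(frozen=True)
class TypeScores:
    precision: float
    recall: float
    f1: float
    support: int  # number of gold entities of this type


@dataclass
class EvalReport:
    per_type: dict[str, TypeScores] = field(default_factory=dict)
    macro_f1: float = 0.0

    def as_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "per_type": {
                t: {"precision": s.precision, "recall": s.recall, "f1": s.f1, "support": s.support}
                for t, s in self.per_type.items()
            },
        }


def _split(label: str) -> tuple[str, str]:
    if label == "O":
        return "O", ""
    if label in ("B", "I"):
        return label, ""
    if label.startswith(("B-", "I-")):
        return label[0], label[2:]
    raise ValidationError(f"unknown BIO label {label!r}")


def extract_entities(bio_sequence: Sequence[str]) -> set[EntitySpan]:
    """Convert a BIO sequence into entity spans (1-based, half-open)."""
    spans: set[EntitySpan] = set()
    start = None
    current_type = ""
    prev_tag = "O"
    for i, label in enumerate(bio_sequence, start=1):
        tag, etype = _split(label)
        if tag == "O":
            if start is not None:
                spans.add(EntitySpan(start, i, current_type))
                start = None
            prev_tag = "O"
            continue
        opens = tag == "B" or prev_tag == "O" or etype != current_type
        if opens:
            if start is not None:
                spans.add(EntitySpan(start, i, current_type))
            start = i
            current_type = etype
        prev_tag = tag
    if start is not None:
        spans.add(EntitySpan(start, len(bio_sequence) + 1, current_type))
    return spans


def score(
    gold: Sequence[Sequence[str]],
    predicted: Sequence[Sequence[str]],
) -> EvalReport:
    """Entity-level scores of predicted label sequences against gold.

    Raises :class:`AlignmentError` if the two sides disagree on sentence count
    or on any sentence length.
    """
    if len(gold) != len(predicted):
        raise AlignmentError(f"{len(predicted)} predictions for {len(gold)} gold sentences")
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    gold_types: set[str] = set()
    total_pred = 0
    for k, (g, p) in enumerate(zip(gold, predicted), start=1):
        if len(g) != len(p):
            raise AlignmentError(
                f"sentence {k}: prediction length {len(p)} != gold length {len(g)}"
            )
        g_spans = extract_entities(g)
        p_spans = extract_entities(p)
        total_pred += len(p_spans)
        gold_types.update(s.entity_type for s in g_spans)
        for s in g_spans & p_spans:
            tp[s.entity_type] = tp.get(s.entity_type, 0) + 1
        for s in g_spans - p_spans:
            fn[s.entity_type] = fn.get(s.entity_type, 0) + 1
        for s in p_spans - g_spans:
            fp[s.entity_type] = fp.get(s.entity_type, 0) + 1

    report = EvalReport()
    if not gold_types:
        # Degenerate gold with no entities: perfect only if nothing was predicted.
        report.macro_f1 = 1.0 if total_pred == 0 else 0.0
        return report
    f1_values = []
    for etype in sorted(gold_types):
        t, f_p, f_n = tp.get(etype, 0), fp.get(etype, 0), fn.get(etype, 0)
        precision = t / (t + f_p) if (t + f_p) else 0.0
        recall = t / (t + f_n) if (t + f_n) else 0.0
        f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
        report.per_type[etype] = TypeScores(precision, recall, f1, t + f_n)
        f1_values.append(f1)
    report.macro_f1 = sum(f1_values) / len(f1_values)
    return report


def score_corpus(corpus: Corpus, predicted: Sequence[Sequence[str]]) -> EvalReport:
    """Score predictions against the gold labels carried by a corpus."""
    gold = []
    for s in corpus:
        if s.labels is None:
            raise ValidationError("corpus sentence without gold labels cannot be scored")
        gold.append(s.labels)
    return score(gold, predicted)
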