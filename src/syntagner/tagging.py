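"""BIO tagging head, cross-entropy loss, greedy decoding and the training loop.

The head is a single fully-connected layer over the attention output
``o_i`` (width ``2 d1``) followed by a softmax over the label set (default
``[B, I, O]``). Decoding is per-token argmax; ties break toward the earlier
label in the label order. A CRF decoder is deliberately not provided: greedy
softmax decoding is the configuration of record, and illegal transitions are
left to the lenient span conversion of the evaluator.

Training is plain Adam on mean cross-entropy with seeded shuffling; model
selection keeps the checkpoint with the best validation macro-F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .autodiff import Parameter, Tensor, masked_softmax
from .errors import ConfigurationError, SyntagnerError
from .evaluation import score
from .optim import Adam

__all__ = [
    "TagHead",
    "TrainConfig",
    "tag_logits",
    "sequence_loss",
    "decode",
    "train",
    "TrainResult",
]

DEFAULT_LABELS = ("B", "I", "O")


class TagHead:
    """Linear + softmax tagging head with weight ``W`` of shape (|labels|, 2 d1)."""

    def __init__(self, input_width: int, label_set: Sequence[str] = DEFAULT_LABELS, seed: int = 0):
        if input_width <= 0:
            raise ConfigurationError("tag head input width must be positive")
        self.label_set = tuple(label_set)
        self.input_width = input_width
        rng = np.random.default_rng(seed)
        bound = 1.0 / np.sqrt(input_width)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(len(self.label_set), input_width)))
        self.bias = Parameter(np.zeros(len(self.label_set)))

    def parameters(self) -> dict[str, Parameter]:
        return {"head.weight": self.weight, "head.bias": self.bias}

    def logits(self, O: Tensor) -> Tensor:
        """Unnormalized label scores for a stack of output vectors (n, 2 d1)."""
        if O.shape[-1] != self.input_width:
            raise ConfigurationError(
                f"tag head expects width {self.input_width}, got {O.shape[-1]}"
            )
        return O @ self.weight.swapaxes(0, 1) + self.bias


def tag_logits(o_i: Tensor, head: TagHead) -> Tensor:
    """Tagging probability distribution for a single output vector ``o_i``."""
    row = o_i.reshape(1, head.input_width)
    return masked_softmax(head.logits(row)).reshape(len(head.label_set))


def sequence_loss(
    probabilities: np.ndarray,
    gold_ids: Sequence[int],
    loss_mask: Optional[Sequence[bool]] = None,
) -> float:
    """Mean negative log-probability of the gold labels over unmasked positions.

    Operates on already-normalized probability rows; the training loop uses the
    numerically fused logits path in :func:`~syntagner.autodiff.cross_entropy`,
    which computes the same quantity.
    """
    probs = np.asarray(probabilities, dtype=np.float64)
    gold = np.asarray(gold_ids, dtype=np.int64)
    mask = (
        np.ones(len(gold), dtype=bool)
        if loss_mask is None
        else np.asarray(loss_mask, dtype=bool)
    )
    if not mask.any():
        raise ConfigurationError("sequence_loss: every position is masked")
    picked = probs[np.arange(len(gold)), gold]
    return float(-(np.log(picked) * mask).sum() / mask.sum())


def decode(probabilities: np.ndarray, label_set: Sequence[str] = DEFAULT_LABELS) -> list[str]:
    """Greedy per-token argmax; ties break toward the earlier label."""
    probs = np.asarray(probabilities)
    return [label_set[int(i)] for i in probs.argmax(axis=-1)]


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the full-scale configuration
    (Adam, learning rate 5e-5, batch size 64, 30 epochs)."""

    learning_rate: float = 5e-5
    batch_size: int = 64
    max_epochs: int = 30
    seed: int = 0
    optimizer_name: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ConfigurationError("TrainConfig numerics must be positive (lr may be zero)")
        if self.optimizer_name.lower() != "adam":
            raise ConfigurationError("only the Adam optimizer is supported")


@dataclass
class TrainResult:
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_f1: float = 0.0


def train(model, stream, val_wrapped: Sequence, config: TrainConfig) -> TrainResult:
    """Train a model on a wrapped-sentence stream with per-epoch validation.

    ``model`` exposes ``parameters()``, ``loss_wrapped(ws)`` and
    ``predict_wrapped(ws)``; ``stream`` yields a deterministic sentence order
    per epoch. The parameters of the best validation-F1 epoch are restored
    into the model before returning.
    """
    params = model.parameters()
    optimizer = Adam(params.values(), lr=config.learning_rate)
    result = TrainResult()
    best_state: Optional[dict[str, np.ndarray]] = None

    for epoch in range(config.max_epochs):
        order = stream.epoch(epoch)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            optimizer.zero_grad()
            batch_loss = 0.0
            for ws in batch:
                loss = model.loss_wrapped(ws)
                value = float(loss.data)
                if not np.isfinite(value):
                    raise SyntagnerError(
                        f"training diverged at epoch {epoch}: non-finite loss {value}"
                    )
                loss.backward(np.asarray(1.0 / len(batch)))
                batch_loss += value
            optimizer.step()
            epoch_loss += batch_loss
        mean_loss = epoch_loss / len(order)

        gold = [list(ws.sentence.labels) for ws in val_wrapped]
        preds = [list(model.predict_wrapped(ws)) for ws in val_wrapped]
        val_f1 = score(gold, preds).macro_f1
        result.history.append({"epoch": epoch, "train_loss": mean_loss, "val_macro_f1": val_f1})
        if val_f1 > result.best_val_f1 or best_state is None:
            result.best_val_f1 = val_f1
            result.best_epoch = epoch
            best_state = {name: p.data.copy() for name, p in params.items()}

    if best_state is not None:
        for name, p in params.items():
            p.data = best_state[name].copy()
    return result
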