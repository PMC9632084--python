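"""Checkpoint serialization: all parameter groups, vocabularies and config.

A checkpoint is a directory holding ``params.npz`` (named float64 arrays) and
``model.json`` (everything needed to rebuild the model skeleton: encoder
spec, feature type, label sets, vocabularies, tag scheme). Loading rebuilds
the model and overwrites its freshly initialized parameters with the stored
arrays, so a reloaded model reproduces the saved model's predictions exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .cfa import CfaParameters
from .encoding import EncoderSpec, TinyEncoder, WordVocabulary
from .errors import ConfigurationError
from .model import NerModel
from .mtl import TagScheme
from .syntax_features import LabelVocabulary
from .tagging import TagHead

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(model: NerModel, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = model.parameters()
    np.savez(directory / "params.npz", **{k: p.data for k, p in params.items()})
    meta = {
        "encoder_spec": asdict(model.encoder.spec),
        "feature_type": model.feature_type,
        "window": model.window,
        "acceptable_labels": sorted(model.acceptable_labels),
        "label_set": list(model.label_set),
        "word_vocab": model.word_vocab.to_dict(),
        "syntax_vocab": model.syntax_vocab.to_dict() if model.syntax_vocab else None,
        "d2": model.cfa_params.d2 if model.cfa_params else None,
        "scheme": {"variant": model.scheme.variant, "registry": model.scheme.registry},
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_checkpoint(directory: str | Path) -> NerModel:
    directory = Path(directory)
    meta_path = directory / "model.json"
    if not meta_path.exists():
        raise ConfigurationError(f"no checkpoint at {directory}")
    meta = json.loads(meta_path.read_text())
    spec = EncoderSpec(**meta["encoder_spec"])
    word_vocab = WordVocabulary.from_dict(meta["word_vocab"])
    encoder = TinyEncoder(word_vocab, spec)
    feature_type = meta["feature_type"]
    syntax_vocab = None
    cfa_params = None
    if feature_type != "none":
        syntax_vocab = LabelVocabulary.from_dict(meta["syntax_vocab"])
        cfa_params = CfaParameters.create(
            n_labels=len(syntax_vocab), d1=spec.d1, d2=meta["d2"]
        )
        head_width = 2 * spec.d1
    else:
        head_width = spec.d1
    head = TagHead(head_width, label_set=meta["label_set"])
    scheme = TagScheme(
        variant=meta["scheme"]["variant"],
        registry={k: tuple(v) for k, v in meta["scheme"]["registry"].items()},
    )
    model = NerModel(
        word_vocab=word_vocab,
        encoder=encoder,
        head=head,
        scheme=scheme,
        feature_type=feature_type,
        cfa_params=cfa_params,
        syntax_vocab=syntax_vocab,
        acceptable_labels=frozenset(meta["acceptable_labels"]),
        window=meta["window"],
        label_set=tuple(meta["label_set"]),
    )
    arrays = np.load(directory / "params.npz")
    params = model.parameters()
    if set(arrays.files) != set(params):
        raise ConfigurationError("checkpoint parameter names do not match the rebuilt model")
    for name, p in params.items():
        stored = arrays[name]
        if stored.shape != p.data.shape:
            raise ConfigurationError(f"checkpoint shape mismatch for {name}")
        p.data = stored.astype(np.float64)
    return model
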