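"""Run configuration: a validated, serializable description of a whole run.

The YAML/JSON layout mirrors the dataclasses below, e.g.::

    seed: 0
    output_dir: runs/demo
    feature_type: dependency
    mtl_variant: DN
    encoder: {kind: tiny, d1: 32, seed: 0, n_blocks: 1, max_seq_len: 128}
    train: {learning_rate: 0.005, batch_size: 16, max_epochs: 15, seed: 0}
    datasets:
      - name: synthA
        tag: A
        entity_type: disease
        bio: data/synthA.bio
        conllu: data/synthA.conllu
        trees: data/synthA.trees
        val_bio: data/synthA.val.bio
        val_conllu: data/synthA.val.conllu

Every run directory receives a copy of the resolved configuration, so the
directory together with the seeds is sufficient to reproduce the run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .corpus_io import Corpus, align_annotations, read_bio_corpus, read_conllu, read_ptb_trees
from .encoding import EncoderSpec
from .errors import ConfigurationError
from .mtl import TagScheme
from .syntax_features import CONLL2003_CHUNK_LABELS
from .tagging import TrainConfig

__all__ = ["DatasetConfig", "RunConfig", "load_dataset"]


@dataclass
class DatasetConfig:
    """One registered dataset: identity plus file paths for its splits."""

    name: str
    tag: str = ""
    entity_type: str = "synthetic"
    bio: Optional[str] = None
    conllu: Optional[str] = None
    trees: Optional[str] = None
    val_bio: Optional[str] = None
    val_conllu: Optional[str] = None
    val_trees: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ConfigurationError("dataset name must be nonempty")
        if not self.tag:
            self.tag = self.name


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "runs/run"
    log_level: str = "INFO"
    feature_type: str = "dependency"
    d2: Optional[int] = None
    cfa_seed: int = 0
    head_seed: int = 0
    window: int = 1
    acceptable_labels: list[str] = field(
        default_factory=lambda: sorted(CONLL2003_CHUNK_LABELS)
    )
    mtl_variant: str = "NONE"
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    datasets: list[DatasetConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_type not in ("pos", "constituent", "dependency", "none"):
            raise ConfigurationError(f"unknown feature_type {self.feature_type!r}")
        if isinstance(self.encoder, dict):
            self.encoder = EncoderSpec(**self.encoder)
        if isinstance(self.train, dict):
            self.train = TrainConfig(**self.train)
        self.datasets = [
            DatasetConfig(**d) if isinstance(d, dict) else d for d in self.datasets
        ]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"cannot parse config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def scheme(self) -> TagScheme:
        registry = {d.name: (d.tag, d.entity_type) for d in self.datasets}
        return TagScheme(variant=self.mtl_variant, registry=registry)


def load_dataset(dataset: DatasetConfig, split: str = "train") -> Corpus:
    """Read one split of a dataset and align its annotation layers."""
    if split == "train":
        bio, conllu, trees = dataset.bio, dataset.conllu, dataset.trees
    elif split == "val":
        bio, conllu, trees = dataset.val_bio, dataset.val_conllu, dataset.val_trees
    else:
        raise ConfigurationError(f"unknown split {split!r}")
    if bio is None:
        raise ConfigurationError(f"dataset {dataset.name!r} has no {split} BIO file")
    with open(bio) as fh:
        corpus = read_bio_corpus(fh, dataset.name, dataset.entity_type)
    records = None
    tree_list = None
    if conllu is not None:
        with open(conllu) as fh:
            records = read_conllu(fh)
    if trees is not None:
        with open(trees) as fh:
            tree_list = read_ptb_trees(fh)
    if records is not None or tree_list is not None:
        corpus = align_annotations(corpus, records, tree_list)
    return corpus
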