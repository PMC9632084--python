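"""Per-token syntactic context extraction.

For each word ``x_i`` of a sentence one of three rule systems selects a context
feature sequence ``S_i`` (positions of context words) and a parallel syntactic
label sequence ``L_i`` of the same length ``m_i``:

* ``pos`` — a symmetric 1-word window (clipped at the sentence boundary); the
  labels are the POS tags of the selected words.
* ``constituent`` — walk up from the leaf of ``x_i`` to the first ancestor
  whose label is in an acceptable-label inventory (default: the CoNLL-2003
  chunking labels); the context is every word under that ancestor, and each
  context word is labelled with its own lowest phrasal (non-pre-terminal)
  ancestor.
* ``dependency`` — the word itself, its governor (if not the virtual root) and
  all of its dependents; each context word is labelled with the relation on its
  own incoming arc.

Contexts are emitted in surface order, always include ``x_i``, and are never
empty. Extraction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .corpus_io import AnnotatedSentence, ConstituencyNode, Corpus
from .errors import ConfigurationError

__all__ = [
    "CONLL2003_CHUNK_LABELS",
    "FeatureType",
    "SyntacticContext",
    "LabelVocabulary",
    "extract_pos_context",
    "extract_constituent_context",
    "extract_dependency_context",
    "build_context_sequences",
    "build_label_vocabulary",
]

FeatureType = Literal["pos", "constituent", "dependency"]

#: Chunk label inventory of the CoNLL-2003 shared task, used as the default set
#: of acceptable ancestor labels for constituent context extraction.
CONLL2003_CHUNK_LABELS: frozenset[str] = frozenset(
    {"NP", "VP", "PP", "ADJP", "ADVP", "SBAR", "PRT", "INTJ", "CONJP", "LST"}
)


@dataclass(frozen=True)
class SyntacticContext:
    """The context positions and syntactic labels selected for one token."""

    token_index: int
    context_positions: tuple[int, ...]
    syntactic_labels: tuple[str, ...]
    feature_type: str

    def __post_init__(self) -> None:
        m = len(self.context_positions)
        if m < 1 or len(self.syntactic_labels) != m:
            raise ConfigurationError(
                "context positions and labels must be nonempty and equal-length"
            )
        if any(b <= a for a, b in zip(self.context_positions, self.context_positions[1:])):
            raise ConfigurationError("context positions must be strictly increasing")

    @property
    def m(self) -> int:
        """Context length ``m_i``."""
        return len(self.context_positions)


@dataclass
class LabelVocabulary:
    """Dense integer ids for syntactic label strings, with a reserved UNK id.

    Unseen labels map to UNK at lookup time, so inference never fails on a
    label that was absent from training.
    """

    UNK: str = "<UNK>"
    _ids: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._ids:
            self._ids = {self.UNK: 0}

    @classmethod
    def from_labels(cls, labels: Iterable[str]) -> "LabelVocabulary":
        vocab = cls()
        vocab._ids = {vocab.UNK: 0}
        for label in sorted(set(labels)):
            if label not in vocab._ids:
                vocab._ids[label] = len(vocab._ids)
        return vocab

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, label: str) -> bool:
        return label in self._ids

    @property
    def unk_id(self) -> int:
        return self._ids[self.UNK]

    def __getitem__(self, label: str) -> int:
        return self._ids.get(label, self._ids[self.UNK])

    def to_dict(self) -> dict[str, int]:
        return dict(self._ids)

    @classmethod
    def from_dict(cls, mapping: dict[str, int]) -> "LabelVocabulary":
        vocab = cls()
        vocab._ids = dict(mapping)
        return vocab


def extract_pos_context(
    sentence: AnnotatedSentence, i: int, window: int = 1
) -> SyntacticContext:
    """POS-window rule: the word and its neighbours within ``window`` positions."""
    if sentence.pos_tags is None:
        raise ConfigurationError("POS context extraction requires pos_tags")
    n = len(sentence)
    _check_position(i, n)
    lo = max(1, i - window)
    hi = min(n, i + window)
    positions = tuple(range(lo, hi + 1))
    labels = tuple(sentence.pos_tags[k - 1] for k in positions)
    return SyntacticContext(i, positions, labels, "pos")


def extract_constituent_context(
    sentence: AnnotatedSentence,
    i: int,
    acceptable_labels: frozenset[str] | set[str] = CONLL2003_CHUNK_LABELS,
) -> SyntacticContext:
    """Constituent rule: all words under the first acceptable ancestor of leaf ``i``.

    Each context word is labelled with its lowest non-pre-terminal ancestor
    within the whole tree; if no ancestor of leaf ``i`` has an acceptable
    label, the tree root is used as the covering node.
    """
    if sentence.tree is None:
        raise ConfigurationError("constituent context extraction requires a tree")
    n = len(sentence)
    _check_position(i, n)
    path = _path_to_leaf(sentence.tree, i)
    # path[0] is the root, path[-1] the leaf; first acceptable = lowest ancestor
    # with an acceptable label, found scanning from the leaf upwards.
    covering = path[0]
    for node in reversed(path[:-1]):
        if node.label in acceptable_labels:
            covering = node
            break
    positions = tuple(range(covering.span[0], covering.span[1]))
    labels = tuple(_phrasal_ancestor_label(sentence.tree, k) for k in positions)
    return SyntacticContext(i, positions, labels, "constituent")


def extract_dependency_context(sentence: AnnotatedSentence, i: int) -> SyntacticContext:
    """Dependency rule: the word, its governor and its dependents.

    Each context word is labelled with the relation of its own incoming arc
    (the root-governed word is labelled ``root``).
    """
    if sentence.dep_arcs is None:
        raise ConfigurationError("dependency context extraction requires dep_arcs")
    n = len(sentence)
    _check_position(i, n)
    members = {i}
    incoming = sentence.head_of(i)
    if incoming.head > 0:
        members.add(incoming.head)
    for arc in sentence.dependents_of(i):
        members.add(arc.dependent)
    positions = tuple(sorted(members))
    labels = tuple(sentence.head_of(k).relation for k in positions)
    return SyntacticContext(i, positions, labels, "dependency")


def build_context_sequences(
    sentence: AnnotatedSentence,
    feature_type: FeatureType,
    acceptable_labels: frozenset[str] | set[str] = CONLL2003_CHUNK_LABELS,
    window: int = 1,
) -> list[SyntacticContext]:
    """Apply one extraction rule to every token position of a sentence."""
    n = len(sentence)
    if feature_type == "pos":
        return [extract_pos_context(sentence, i, window) for i in range(1, n + 1)]
    if feature_type == "constituent":
        return [
            extract_constituent_context(sentence, i, acceptable_labels)
            for i in range(1, n + 1)
        ]
    if feature_type == "dependency":
        return [extract_dependency_context(sentence, i) for i in range(1, n + 1)]
    raise ConfigurationError(f"unknown feature type {feature_type!r}")


def build_label_vocabulary(
    corpora: Sequence[Corpus],
    feature_type: FeatureType,
    acceptable_labels: frozenset[str] | set[str] = CONLL2003_CHUNK_LABELS,
    window: int = 1,
) -> LabelVocabulary:
    """Collect every syntactic label seen in training into a sorted vocabulary."""
    labels: set[str] = set()
    for corpus in corpora:
        for sentence in corpus:
            for ctx in build_context_sequences(sentence, feature_type, acceptable_labels, window):
                labels.update(ctx.syntactic_labels)
    return LabelVocabulary.from_labels(labels)


def _check_position(i: int, n: int) -> None:
    if not 1 <= i <= n:
        raise ConfigurationError(f"position {i} out of range [1, {n}]")


def _path_to_leaf(root: ConstituencyNode, i: int) -> list[ConstituencyNode]:
    """Root-to-leaf path of nodes covering leaf position ``i``."""
    path = [root]
    node = root
    while not node.is_leaf:
        for child in node.children:
            if child.span[0] <= i < child.span[1]:
                node = child
                path.append(node)
                break
        else:  # pragma: no cover - malformed span structure
            raise ConfigurationError(f"tree spans do not cover position {i}")
    return path


def _phrasal_ancestor_label(root: ConstituencyNode, k: int) -> str:
    """Label of the lowest non-pre-terminal ancestor of leaf ``k``."""
    path = _path_to_leaf(root, k)
    for node in reversed(path):
        if not node.is_leaf and not node.is_preterminal:
            return node.label
    return root.label
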