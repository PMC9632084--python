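"""Corpus containers and readers/writers for the standard annotation formats.

The in-memory unit is :class:`AnnotatedSentence`: a pre-tokenized sentence with
optional BIO labels, POS tags, a basic dependency tree and a constituency tree.
Token positions are 1-based everywhere (the first word is position 1); spans are
half-open ``[start, end)`` intervals of positions.

Three text formats are consumed:

* token-per-line BIO files (CoNLL-2003 style, blank line between sentences),
* CoNLL-U for POS tags and dependency arcs,
* Penn bracketed trees for constituency structure.

The package never tokenizes raw text: annotation layers must match the corpus
tokens exactly, position by position, and :func:`align_annotations` makes any
mismatch a hard error rather than attempting repair.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from .errors import AlignmentError, ParseError, ValidationError

__all__ = [
    "DependencyArc",
    "ConstituencyNode",
    "AnnotatedSentence",
    "Corpus",
    "ConlluRecord",
    "read_bio_corpus",
    "write_bio_corpus",
    "read_conllu",
    "write_conllu",
    "read_ptb_trees",
    "write_ptb_tree",
    "align_annotations",
    "write_predictions",
]

_BIO_RE = re.compile(r"^(?:O|[BI](?:-[^\s]+)?)$")


@dataclass(frozen=True, order=True)
class DependencyArc:
    """A directed, typed link ``head -> dependent`` in a basic dependency tree.

    ``head`` is a token position, or 0 for the virtual root; ``dependent`` is
    always a real token position. ``relation`` is the dependency type of the
    dependent (``amod``, ``root``, ...).
    """

    head: int
    dependent: int
    relation: str


@dataclass(frozen=True)
class ConstituencyNode:
    """A node of a constituency parse tree.

    Leaves carry the word as ``label`` and have no children; pre-terminals are
    POS nodes dominating a single leaf. ``span`` is the half-open interval of
    1-based token positions the node covers.
    """

    label: str
    children: tuple["ConstituencyNode", ...] = ()
    span: tuple[int, int] = (0, 0)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) == 1 and self.children[0].is_leaf

    def leaves(self) -> Iterator["ConstituencyNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def words(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]


@dataclass
class AnnotatedSentence:
    """A pre-tokenized sentence plus optional annotation layers.

    All per-token layers, when present, have exactly one entry per token.
    """

    tokens: tuple[str, ...]
    labels: Optional[tuple[str, ...]] = None
    pos_tags: Optional[tuple[str, ...]] = None
    dep_arcs: Optional[tuple[DependencyArc, ...]] = None
    tree: Optional[ConstituencyNode] = None
    source_dataset: str = ""

    def __post_init__(self) -> None:
        self.tokens = tuple(self.tokens)
        if len(self.tokens) < 1:
            raise ValidationError("a sentence must contain at least one token")
        for name in ("labels", "pos_tags"):
            layer = getattr(self, name)
            if layer is not None:
                layer = tuple(layer)
                setattr(self, name, layer)
                if len(layer) != len(self.tokens):
                    raise ValidationError(
                        f"{name} has {len(layer)} entries for {len(self.tokens)} tokens"
                    )
        if self.labels is not None:
            for j, tag in enumerate(self.labels, start=1):
                if not _BIO_RE.match(tag):
                    raise ValidationError(f"illegal BIO tag {tag!r} at position {j}")
        if self.dep_arcs is not None:
            self.dep_arcs = tuple(sorted(self.dep_arcs, key=lambda a: a.dependent))
            _validate_arcs(self.dep_arcs, len(self.tokens))
        if self.tree is not None:
            n_leaves = sum(1 for _ in self.tree.leaves())
            if n_leaves != len(self.tokens):
                raise ValidationError(
                    f"tree has {n_leaves} leaves for {len(self.tokens)} tokens"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    def head_of(self, i: int) -> DependencyArc:
        """The (unique) incoming arc of token ``i``."""
        if self.dep_arcs is None:
            raise ValidationError("sentence has no dependency arcs")
        for arc in self.dep_arcs:
            if arc.dependent == i:
                return arc
        raise ValidationError(f"no incoming arc for position {i}")

    def dependents_of(self, i: int) -> list[DependencyArc]:
        """All arcs whose head is token ``i``, in surface order of dependents."""
        if self.dep_arcs is None:
            raise ValidationError("sentence has no dependency arcs")
        return [arc for arc in self.dep_arcs if arc.head == i]


def _validate_arcs(arcs: Sequence[DependencyArc], n: int) -> None:
    dependents = [a.dependent for a in arcs]
    if sorted(dependents) != list(range(1, n + 1)):
        raise ValidationError(
            "dependency arcs must give every token exactly one head "
            f"(got dependents {sorted(dependents)} for n={n})"
        )
    roots = [a for a in arcs if a.head == 0]
    if len(roots) != 1 or roots[0].relation != "root":
        raise ValidationError("exactly one arc must have head 0 with relation 'root'")
    for a in arcs:
        if not (0 <= a.head <= n):
            raise ValidationError(f"arc head {a.head} out of range [0, {n}]")
        if a.head == a.dependent:
            raise ValidationError(f"self-loop at position {a.dependent}")


@dataclass
class Corpus:
    """An ordered collection of sentences sharing a dataset identity."""

    sentences: list[AnnotatedSentence] = field(default_factory=list)
    dataset_name: str = "corpus"
    entity_type: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.dataset_name:
            raise ValidationError("dataset_name must be nonempty")
        for s in self.sentences:
            s.source_dataset = self.dataset_name

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self.sentences)


Stream = Union[str, TextIO, Iterable[str]]


def _lines(stream: Stream) -> Iterator[str]:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for line in stream:
        yield line.rstrip("\n").rstrip("\r")


def read_bio_corpus(
    stream: Stream,
    dataset_name: str,
    entity_type: str = "synthetic",
    label_set: Optional[set[str]] = None,
) -> Corpus:
    """Read a token-per-line BIO corpus (``token<TAB or SPACE>tag``).

    Blank lines separate sentences. Tags are validated against ``label_set``
    when given, otherwise against the BIO shape ``O | B[-TYPE] | I[-TYPE]``.
    An empty stream yields an empty corpus.
    """
    sentences: list[AnnotatedSentence] = []
    tokens: list[str] = []
    tags: list[str] = []

    def flush() -> None:
        if tokens:
            sentences.append(
                AnnotatedSentence(tuple(tokens), tuple(tags), source_dataset=dataset_name)
            )
            tokens.clear()
            tags.clear()

    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(f"line {lineno}: expected 'token<TAB or SPACE>tag', got {line!r}")
        token, tag = parts
        if label_set is not None:
            if tag not in label_set:
                raise ValidationError(f"line {lineno}: tag {tag!r} not in label set {sorted(label_set)}")
        elif not _BIO_RE.match(tag):
            raise ValidationError(f"line {lineno}: illegal BIO tag {tag!r}")
        tokens.append(token)
        tags.append(tag)
    flush()
    return Corpus(sentences, dataset_name=dataset_name, entity_type=entity_type)


def write_bio_corpus(corpus: Corpus, stream: TextIO) -> None:
    """Write a corpus in token-per-line BIO format (inverse of :func:`read_bio_corpus`)."""
    for sentence in corpus:
        labels = sentence.labels or ("O",) * len(sentence)
        for token, tag in zip(sentence.tokens, labels):
            stream.write(f"{token}\t{tag}\n")
        stream.write("\n")


@dataclass(frozen=True)
class ConlluRecord:
    """Per-sentence payload extracted from CoNLL-U: surface forms, POS tags, arcs."""

    forms: tuple[str, ...]
    pos_tags: tuple[str, ...]
    dep_arcs: tuple[DependencyArc, ...]


def read_conllu(stream: Stream) -> list[ConlluRecord]:
    """Read 10-column CoNLL-U into per-sentence (forms, POS, arcs) records.

    XPOS is used as the POS tag, falling back to UPOS when XPOS is ``_``.
    Comment lines, multiword-token ranges (``1-2``) and empty nodes (``1.1``)
    are skipped. Only basic trees are accepted: the arcs of each sentence must
    form a single-rooted tree over the tokens.
    """
    records: list[ConlluRecord] = []
    forms: list[str] = []
    pos: list[str] = []
    arcs: list[DependencyArc] = []

    def flush() -> None:
        if forms:
            _validate_arcs(arcs, len(forms))
            records.append(ConlluRecord(tuple(forms), tuple(pos), tuple(arcs)))
            forms.clear()
            pos.clear()
            arcs.clear()

    for lineno, line in enumerate(_lines(stream), start=1):
        if not line.strip():
            flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseError(f"line {lineno}: expected 10 tab-separated columns, got {len(cols)}")
        token_id = cols[0]
        if "-" in token_id or "." in token_id:  # multiword ranges / empty nodes
            continue
        try:
            dep = int(token_id)
            head = int(cols[6])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer ID or HEAD field") from exc
        forms.append(cols[1])
        xpos = cols[4]
        pos.append(xpos if xpos != "_" else cols[3])
        arcs.append(DependencyArc(head=head, dependent=dep, relation=cols[7]))
    flush()
    return records


def write_conllu(sentences: Iterable[AnnotatedSentence], stream: TextIO) -> None:
    """Write POS tags and dependency arcs of annotated sentences as CoNLL-U."""
    for sentence in sentences:
        if sentence.pos_tags is None or sentence.dep_arcs is None:
            raise ValidationError("write_conllu needs pos_tags and dep_arcs")
        by_dep = {arc.dependent: arc for arc in sentence.dep_arcs}
        for i, (token, tag) in enumerate(zip(sentence.tokens, sentence.pos_tags), start=1):
            arc = by_dep[i]
            cols = [str(i), token, "_", tag, tag, "_", str(arc.head), arc.relation, "_", "_"]
            stream.write("\t".join(cols) + "\n")
        stream.write("\n")


_PTB_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def read_ptb_trees(stream: Stream) -> list[ConstituencyNode]:
    """Parse Penn bracketed trees (one per line or whitespace-separated).

    Leaf spans are assigned left to right starting at position 1 within each
    tree; internal spans are the concatenation of child spans. Unbalanced
    brackets raise :class:`ParseError` with the character offset.
    """
    text = stream if isinstance(stream, str) else "\n".join(_lines(stream))
    trees: list[ConstituencyNode] = []
    tokens = [(m.group(0), m.start()) for m in _PTB_TOKEN_RE.finditer(text)]
    idx = 0
    while idx < len(tokens):
        tok, off = tokens[idx]
        if tok != "(":
            raise ParseError(f"character {off}: expected '(' starting a tree, got {tok!r}")
        node, idx, _ = _parse_node(tokens, idx, text, next_leaf=1)
        trees.append(node)
    return trees


def _parse_node(
    tokens: list[tuple[str, int]], idx: int, text: str, next_leaf: int
) -> tuple[ConstituencyNode, int, int]:
    tok, off = tokens[idx]
    assert tok == "("
    idx += 1
    if idx >= len(tokens):
        raise ParseError(f"character {len(text)}: unbalanced brackets (unexpected end of input)")
    label, _ = tokens[idx]
    if label in "()":
        raise ParseError(f"character {tokens[idx][1]}: expected a node label after '('")
    idx += 1
    children: list[ConstituencyNode] = []
    while True:
        if idx >= len(tokens):
            raise ParseError(f"character {len(text)}: unbalanced brackets (unexpected end of input)")
        tok, off = tokens[idx]
        if tok == ")":
            idx += 1
            break
        if tok == "(":
            child, idx, next_leaf = _parse_node(tokens, idx, text, next_leaf)
            children.append(child)
        else:
            children.append(ConstituencyNode(tok, (), (next_leaf, next_leaf + 1)))
            next_leaf += 1
            idx += 1
    if not children:
        raise ParseError(f"character {off}: node with no children")
    span = (children[0].span[0], children[-1].span[1])
    return ConstituencyNode(label, tuple(children), span), idx, next_leaf


def write_ptb_tree(node: ConstituencyNode) -> str:
    """Serialize a constituency tree back to single-line bracketed form."""
    if node.is_leaf:
        return node.label
    inner = " ".join(write_ptb_tree(child) for child in node.children)
    return f"({node.label} {inner})"


def align_annotations(
    corpus: Corpus,
    conllu_records: Optional[Sequence[ConlluRecord]] = None,
    trees: Optional[Sequence[ConstituencyNode]] = None,
) -> Corpus:
    """Attach POS/dependency and/or constituency layers to a corpus, positionally.

    Alignment is strictly positional: record *k* annotates sentence *k*, and the
    annotation's surface forms must match the sentence tokens exactly. Any count
    or surface mismatch raises :class:`AlignmentError` naming the sentence and
    the first offending position; no re-tokenization is ever attempted.
    """
    if conllu_records is not None and len(conllu_records) != len(corpus):
        raise AlignmentError(
            f"{len(conllu_records)} CoNLL-U records for {len(corpus)} sentences"
        )
    if trees is not None and len(trees) != len(corpus):
        raise AlignmentError(f"{len(trees)} trees for {len(corpus)} sentences")

    aligned: list[AnnotatedSentence] = []
    for k, sentence in enumerate(corpus, start=1):
        new = sentence
        if conllu_records is not None:
            record = conllu_records[k - 1]
            _check_surface(sentence.tokens, record.forms, k, "CoNLL-U")
            new = replace(new, pos_tags=record.pos_tags, dep_arcs=record.dep_arcs)
        if trees is not None:
            tree = trees[k - 1]
            _check_surface(sentence.tokens, tuple(tree.words()), k, "tree")
            new = replace(new, tree=tree)
        aligned.append(new)
    return Corpus(aligned, dataset_name=corpus.dataset_name, entity_type=corpus.entity_type)


def _check_surface(tokens: tuple[str, ...], forms: tuple[str, ...], k: int, what: str) -> None:
    if len(forms) != len(tokens):
        raise AlignmentError(
            f"sentence {k}: {what} has {len(forms)} tokens, corpus has {len(tokens)}"
        )
    for i, (a, b) in enumerate(zip(tokens, forms), start=1):
        if a != b:
            raise AlignmentError(
                f"sentence {k}, position {i}: corpus token {a!r} != {what} token {b!r}"
            )


def write_predictions(
    corpus: Corpus, predictions: Sequence[Sequence[str]], stream: TextIO
) -> None:
    """Write ``token<TAB>gold<TAB>pred`` lines, blank line between sentences."""
    if len(predictions) != len(corpus):
        raise AlignmentError(f"{len(predictions)} prediction rows for {len(corpus)} sentences")
    for k, (sentence, pred) in enumerate(zip(corpus, predictions), start=1):
        if len(pred) != len(sentence):
            raise AlignmentError(
                f"sentence {k}: {len(pred)} predicted tags for {len(sentence)} tokens"
            )
        gold = sentence.labels or ("O",) * len(sentence)
        for token, g, p in zip(sentence.tokens, gold, pred):
            stream.write(f"{token}\t{g}\t{p}\n")
        stream.write("\n")
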