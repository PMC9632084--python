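"""The worked example sentence used throughout the documentation and tests.

"This case is a paternally transmitted congenital myotonic dystrophy" — nine
words, with the disease entity "congenital myotonic dystrophy" at positions
7–9. The constituency tree, the POS tags and the arcs
(``dystrophy`` as sentence root, ``congenital``/``myotonic`` as ``amod`` of
``dystrophy``, ``paternally`` as the sole dependent of ``transmitted``) follow
the published analysis of this sentence; the remaining arcs of the dependency
tree are a synthetic completion using the standard copular-clause analysis
(``case`` as ``nsubj`` and ``is`` as ``cop`` of the predicate nominal).
"""

from __future__ import annotations

from .corpus_io import AnnotatedSentence, DependencyArc, read_ptb_trees

__all__ = ["WORKED_EXAMPLE_TREE", "worked_example"]

WORKED_EXAMPLE_TREE = (
    "(S (NP (DT This) (NN case)) (VP (VBZ is) (NP (DT a) "
    "(ADJP (RB paternally) (VBN transmitted)) (JJ congenital) "
    "(JJ myotonic) (NN dystrophy))))"
)

_TOKENS = (
    "This", "case", "is", "a", "paternally",
    "transmitted", "congenital", "myotonic", "dystrophy",
)
_LABELS = ("O", "O", "O", "O", "O", "O", "B", "I", "I")
_POS = ("DT", "NN", "VBZ", "DT", "RB", "VBN", "JJ", "JJ", "NN")
_ARCS = (
    DependencyArc(2, 1, "det"),
    DependencyArc(9, 2, "nsubj"),
    DependencyArc(9, 3, "cop"),
    DependencyArc(9, 4, "det"),
    DependencyArc(6, 5, "advmod"),
    DependencyArc(9, 6, "amod"),
    DependencyArc(9, 7, "amod"),
    DependencyArc(9, 8, "amod"),
    DependencyArc(0, 9, "root"),
)


def worked_example() -> AnnotatedSentence:
    """The fully annotated nine-word example sentence."""
    tree = read_ptb_trees(WORKED_EXAMPLE_TREE)[0]
    return AnnotatedSentence(
        tokens=_TOKENS,
        labels=_LABELS,
        pos_tags=_POS,
        dep_arcs=_ARCS,
        tree=tree,
        source_dataset="worked-example",
    )
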