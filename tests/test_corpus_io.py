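"""Readers/writers for BIO, CoNLL-U and Penn bracketed trees."""

import io

import pytest

from syntagner.corpus_io import (
    align_annotations,
    read_bio_corpus,
    read_conllu,
    read_ptb_trees,
    write_bio_corpus,
    write_conllu,
    write_ptb_tree,
)
from syntagner.errors import AlignmentError, ParseError, ValidationError
from syntagner.examples import WORKED_EXAMPLE_TREE
from syntagner.synthetic import GeneratorConfig, generate_corpus

FIG1_BIO = """This\tO
case\tO
is\tO
a\tO
paternally\tO
transmitted\tO
congenital\tB
myotonic\tI
dystrophy\tI

"""


class TestBioCorpus:
    def test_worked_example_sentence(self):
        corpus = read_bio_corpus(FIG1_BIO, "ncbi")
        assert len(corpus) == 1
        sentence = corpus.sentences[0]
        assert len(sentence) == 9
        assert sentence.labels[6:9] == ("B", "I", "I")
        assert all(lab == "O" for lab in sentence.labels[:6])
        assert sentence.source_dataset == "ncbi"

    def test_space_separated_and_empty_input(self):
        corpus = read_bio_corpus("word O\nother B\n", "x")
        assert corpus.sentences[0].tokens == ("word", "other")
        assert len(read_bio_corpus("", "x")) == 0
        assert len(read_bio_corpus("\n\n\n", "x")) == 0

    def test_roundtrip_through_write(self):
        original = generate_corpus(GeneratorConfig(n_sentences=50, seed=3))
        buf = io.StringIO()
        write_bio_corpus(original, buf)
        reread = read_bio_corpus(buf.getvalue(), original.dataset_name)
        assert len(reread) == len(original)
        for a, b in zip(original, reread):
            assert a.tokens == b.tokens
            assert a.labels == b.labels

    def test_malformed_line_reports_line_number(self):
        with pytest.raises(ParseError, match="line 2"):
            read_bio_corpus("ok O\nbroken_line_without_tag\n", "x")

    def test_illegal_tag_rejected(self):
        with pytest.raises(ValidationError, match="line 1"):
            read_bio_corpus("word Q\n", "x")
        with pytest.raises(ValidationError):
            read_bio_corpus("word B\n", "x", label_set={"O"})


def _conllu_for_worked_example():
    rows = [
        (1, "This", "DT", 2, "det"),
        (2, "case", "NN", 9, "nsubj"),
        (3, "is", "VBZ", 9, "cop"),
        (4, "a", "DT", 9, "det"),
        (5, "paternally", "RB", 6, "advmod"),
        (6, "transmitted", "VBN", 9, "amod"),
        (7, "congenital", "JJ", 9, "amod"),
        (8, "myotonic", "JJ", 9, "amod"),
        (9, "dystrophy", "NN", 0, "root"),
    ]
    lines = ["# text = worked example"]
    for idx, form, pos, head, rel in rows:
        lines.append(f"{idx}\t{form}\t_\t_\t{pos}\t_\t{head}\t{rel}\t_\t_")
    return "\n".join(lines) + "\n\n"


class TestConllu:
    def test_worked_example_arcs_and_pos(self):
        records = read_conllu(_conllu_for_worked_example())
        assert len(records) == 1
        record = records[0]
        assert record.pos_tags[5:8] == ("VBN", "JJ", "JJ")
        arcs = {(a.head, a.dependent, a.relation) for a in record.dep_arcs}
        assert (9, 7, "amod") in arcs
        assert (0, 9, "root") in arcs

    def test_minimal_single_token_tree(self):
        records = read_conllu("1\tword\t_\tNOUN\t_\t_\t0\troot\t_\t_\n")
        arc = records[0].dep_arcs[0]
        assert (arc.head, arc.dependent, arc.relation) == (0, 1, "root")
        # XPOS "_" falls back to UPOS
        assert records[0].pos_tags == ("NOUN",)

    def test_generated_corpus_roundtrip_keeps_invariants(self, small_corpus):
        buf = io.StringIO()
        write_conllu(small_corpus, buf)
        records = read_conllu(buf.getvalue())
        assert len(records) == len(small_corpus)
        for sentence, record in zip(small_corpus, records):
            assert record.forms == sentence.tokens
            assert set(record.dep_arcs) == set(sentence.dep_arcs)

    @pytest.mark.parametrize(
        "text,match",
        [
            ("1\tword\t_\t_\t_\t_\t0\n", "10"),
            ("1\tword\t_\t_\t_\t_\tX\troot\t_\t_\n", "HEAD"),
        ],
    )
    def test_parse_errors(self, text, match):
        with pytest.raises(ParseError, match=match):
            read_conllu(text)

    def test_multiword_and_empty_node_lines_ignored(self):
        text = (
            "1-2\tcannot\t_\t_\t_\t_\t_\t_\t_\t_\n"
            "1\tcan\t_\tAUX\t_\t_\t0\troot\t_\t_\n"
            "1.1\telided\t_\t_\t_\t_\t_\t_\t_\t_\n"
        )
        records = read_conllu(text)
        assert records[0].forms == ("can",)


class TestPtbTrees:
    def test_worked_example_tree_spans(self):
        tree = read_ptb_trees(WORKED_EXAMPLE_TREE)[0]
        assert tree.span == (1, 10)
        assert tree.words() == [
            "This", "case", "is", "a", "paternally",
            "transmitted", "congenital", "myotonic", "dystrophy",
        ]
        inner_np = tree.children[1].children[1]
        assert inner_np.label == "NP"
        assert inner_np.span == (4, 10)
        assert len(list(inner_np.leaves())) == 6

    def test_minimal_tree(self):
        tree = read_ptb_trees("(X (Y w))")[0]
        assert tree.label == "X"
        assert tree.span == (1, 2)
        assert [leaf.label for leaf in tree.leaves()] == ["w"]

    def test_serialize_reparse_identity(self, small_corpus):
        for sentence in small_corpus:
            text = write_ptb_tree(sentence.tree)
            reparsed = read_ptb_trees(text)[0]
            assert write_ptb_tree(reparsed) == text
            assert reparsed.span == sentence.tree.span

    def test_unbalanced_brackets_report_offset(self):
        with pytest.raises(ParseError, match="character"):
            read_ptb_trees("(S (NP (DT a)")
        with pytest.raises(ParseError):
            read_ptb_trees("(S (NP))) extra )")


class TestAlignment:
    def test_attach_annotations(self):
        corpus = read_bio_corpus(FIG1_BIO, "ncbi")
        records = read_conllu(_conllu_for_worked_example())
        trees = read_ptb_trees(WORKED_EXAMPLE_TREE)
        aligned = align_annotations(corpus, records, trees)
        sentence = aligned.sentences[0]
        assert sentence.pos_tags[6] == "JJ"
        assert sentence.head_of(7).relation == "amod"
        assert sentence.tree.span == (1, 10)

    def test_token_count_mismatch_names_sentence(self):
        corpus = read_bio_corpus(FIG1_BIO, "ncbi")
        extra = _conllu_for_worked_example().replace(
            "9\tdystrophy", "9\tdystrophy"
        ) + "1\tstray\t_\tX\t_\t_\t0\troot\t_\t_\n"
        records = read_conllu(extra)
        with pytest.raises(AlignmentError, match="2 CoNLL-U records for 1"):
            align_annotations(corpus, records)

    def test_alignment_is_positional_not_content_matched(self, small_corpus):
        buf = io.StringIO()
        write_conllu(small_corpus, buf)
        records = read_conllu(buf.getvalue())
        shuffled = list(reversed(records))
        bio = io.StringIO()
        write_bio_corpus(small_corpus, bio)
        corpus = read_bio_corpus(bio.getvalue(), small_corpus.dataset_name)
        with pytest.raises(AlignmentError):
            align_annotations(corpus, shuffled)

    def test_surface_form_mismatch_names_position(self):
        corpus = read_bio_corpus("alpha O\nbeta O\n", "x")
        records = read_conllu(
            "1\talpha\t_\tX\t_\t_\t0\troot\t_\t_\n2\tGAMMA\t_\tX\t_\t_\t1\tdep\t_\t_\n"
        )
        with pytest.raises(AlignmentError, match="position 2"):
            align_annotations(corpus, records)
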