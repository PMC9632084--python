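"""The synthetic corpus generator: self-consistency, cues, conventions, ceiling."""

import numpy as np
import pytest

from syntagner.errors import ConfigurationError
from syntagner.evaluation import extract_entities, score, score_corpus
from syntagner.synthetic import (
    SYNTHETIC_ACCEPTABLE_LABELS,
    GeneratorConfig,
    agreement_ceiling,
    generate_corpus,
    generate_mtl_pair,
    recover_entities,
    shuffle_syntax,
)
from syntagner.syntax_features import build_context_sequences, extract_dependency_context


class TestGenerateCorpus:
    def test_entity_probability_one_gives_entity_per_sentence(self):
        corpus = generate_corpus(
            GeneratorConfig(n_sentences=10, entity_probability=1.0, seed=4)
        )
        for sentence in corpus:
            assert len(extract_entities(sentence.labels)) >= 1

    def test_all_annotation_layers_consistent(self, cue_type):
        corpus = generate_corpus(GeneratorConfig(n_sentences=40, seed=9, cue_type=cue_type))
        for sentence in corpus:
            n = len(sentence)
            assert len(sentence.pos_tags) == n  # construction validates the rest
            assert sentence.tree.span == (1, n + 1)
            assert tuple(sentence.tree.words()) == sentence.tokens
            assert len(sentence) <= 20
            # every extractor runs without error on every position
            for ft in ("pos", "constituent", "dependency"):
                contexts = build_context_sequences(sentence, ft, SYNTHETIC_ACCEPTABLE_LABELS)
                assert len(contexts) == n

    def test_same_seed_identical(self):
        a = generate_corpus(GeneratorConfig(n_sentences=15, seed=5))
        b = generate_corpus(GeneratorConfig(n_sentences=15, seed=5))
        for sa, sb in zip(a, b):
            assert sa.tokens == sb.tokens
            assert sa.labels == sb.labels
            assert sa.dep_arcs == sb.dep_arcs

    def test_disjoint_seeds_differ(self):
        a = generate_corpus(GeneratorConfig(n_sentences=15, seed=5))
        b = generate_corpus(GeneratorConfig(n_sentences=15, seed=6))
        assert [s.tokens for s in a] != [s.tokens for s in b]

    def test_entity_adjective_governed_by_head_via_amod(self):
        """At an entity adjective, the dependency context contains its head
        noun, mirroring the amod pattern of the worked example."""
        corpus = generate_corpus(
            GeneratorConfig(n_sentences=30, seed=10, entity_probability=1.0)
        )
        checked = 0
        for sentence in corpus:
            for arc in sentence.dep_arcs:
                if arc.relation == "amod:ent":
                    ctx = extract_dependency_context(sentence, arc.dependent)
                    assert arc.head in ctx.context_positions
                    j = ctx.context_positions.index(arc.dependent)
                    assert ctx.syntactic_labels[j] == "amod:ent"
                    checked += 1
        assert checked > 0

    def test_degenerate_config_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(entity_probability=1.5)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_entity_heads=0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(cue_type="semantic")


class TestSeparability:
    @pytest.mark.parametrize("convention", ["full-span", "head-only"])
    def test_cue_rule_recovers_gold_exactly(self, cue_type, convention):
        corpus = generate_corpus(
            GeneratorConfig(n_sentences=60, seed=13, cue_type=cue_type, convention=convention)
        )
        preds = [recover_entities(s, cue_type, convention) for s in corpus]
        assert score_corpus(corpus, preds).macro_f1 == 1.0

    def test_surface_does_not_determine_entityhood(self):
        """The same head noun occurs both inside and outside entities."""
        corpus = generate_corpus(GeneratorConfig(n_sentences=200, seed=14))
        in_entity, outside = set(), set()
        for sentence in corpus:
            spans = extract_entities(sentence.labels)
            covered = {k for s in spans for k in range(s.start, s.end)}
            for k, (tok, pos) in enumerate(zip(sentence.tokens, sentence.pos_tags), start=1):
                if pos.startswith("NN"):
                    (in_entity if k in covered else outside).add(tok)
        assert in_entity & outside


class TestMtlPair:
    def test_same_sentences_different_labels(self):
        a, b = generate_mtl_pair(GeneratorConfig(n_sentences=40, seed=15))
        assert a.dataset_name != b.dataset_name
        diff = 0
        for sa, sb in zip(a, b):
            assert sa.tokens == sb.tokens
            assert sa.dep_arcs == sb.dep_arcs
            if sa.labels != sb.labels:
                diff += 1
        assert diff > 0

    def test_conventions_mark_same_entity_heads(self):
        a, b = generate_mtl_pair(GeneratorConfig(n_sentences=40, seed=16))
        for sa, sb in zip(a, b):
            spans_a = extract_entities(sa.labels)
            spans_b = extract_entities(sb.labels)
            assert len(spans_a) == len(spans_b)
            # every head-only span is the last token of some full span
            for span in spans_b:
                assert any(fa.end == span.end for fa in spans_a)


class TestAgreementCeiling:
    def test_formula_against_bruteforce_tradeoff(self):
        """The analytic ceiling matches a brute-force scan over strategies
        that resolve each ambiguous entity toward one convention."""
        a, b = generate_mtl_pair(GeneratorConfig(n_sentences=30, seed=17))
        ceiling = agreement_ceiling(a, b)

        # Enumerate: predict A's span for the first k ambiguous entities and
        # B's for the rest; compute actual min(F1_A, F1_B) for each k.
        ambiguous = []
        for idx, (sa, sb) in enumerate(zip(a, b)):
            if sa.labels != sb.labels:
                ambiguous.append(idx)
        best = 0.0
        for k in range(len(ambiguous) + 1):
            preds = []
            chosen_a = set(ambiguous[:k])
            for idx, (sa, sb) in enumerate(zip(a, b)):
                preds.append(list(sa.labels if idx in chosen_a else sb.labels))
            f1a = score([list(s.labels) for s in a], preds).macro_f1
            f1b = score([list(s.labels) for s in b], preds).macro_f1
            best = max(best, min(f1a, f1b))
        assert best <= ceiling + 1e-9
        assert best == pytest.approx(ceiling, abs=0.02)

    def test_identical_conventions_ceiling_is_one(self):
        a, _ = generate_mtl_pair(GeneratorConfig(n_sentences=10, seed=18))
        assert agreement_ceiling(a, a) == 1.0


class TestShuffleSyntax:
    def test_dependency_shuffle_preserves_structure_and_marginals(self):
        corpus = generate_corpus(GeneratorConfig(n_sentences=30, seed=19))
        shuffled = shuffle_syntax(corpus, seed=1, layer="dependency")
        orig_rels, new_rels = [], []
        for so, sn in zip(corpus, shuffled):
            assert so.tokens == sn.tokens
            assert [(a.head, a.dependent) for a in so.dep_arcs] == [
                (a.head, a.dependent) for a in sn.dep_arcs
            ]
            for ao, an in zip(so.dep_arcs, sn.dep_arcs):
                if ao.head == 0:
                    assert an.relation == "root"
                else:
                    orig_rels.append(ao.relation)
                    new_rels.append(an.relation)
        assert sorted(orig_rels) == sorted(new_rels)
        assert orig_rels != new_rels

    def test_pos_shuffle_preserves_marginals(self):
        corpus = generate_corpus(GeneratorConfig(n_sentences=30, seed=19, cue_type="pos"))
        shuffled = shuffle_syntax(corpus, seed=2, layer="pos")
        orig = [t for s in corpus for t in s.pos_tags]
        new = [t for s in shuffled for t in s.pos_tags]
        assert sorted(orig) == sorted(new)
        assert orig != new

    def test_constituent_shuffle_keeps_tree_shape(self):
        corpus = generate_corpus(GeneratorConfig(n_sentences=20, seed=19, cue_type="constituent"))
        shuffled = shuffle_syntax(corpus, seed=3, layer="constituent")
        for so, sn in zip(corpus, shuffled):
            assert so.tree.span == sn.tree.span
            assert tuple(sn.tree.words()) == so.tokens
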