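"""Combined Feature Attention: per-operation contracts and whole-module oracle."""

import numpy as np
import pytest

from syntagner.autodiff import Parameter, Tensor
from syntagner.cfa import (
    AttentionResult,
    CfaParameters,
    attend,
    cfa_forward,
    embed_context_features,
    embed_syntactic_labels,
    fuse_and_project,
)
from syntagner.errors import ConfigurationError
from syntagner.syntax_features import LabelVocabulary, SyntacticContext

from conftest import cfa_oracle, random_contexts


def make_params(n_labels=5, d1=4, d2=3, seed=0):
    return CfaParameters.create(n_labels=n_labels, d1=d1, d2=d2, seed=seed)


def make_vocab():
    return LabelVocabulary.from_labels(["amod", "root", "det", "nsubj"])


class TestEmbedContextFeatures:
    def test_dependency_case_of_worked_example(self):
        """Context positions {7, 9} select exactly [h7, h9]."""
        rng = np.random.default_rng(1)
        H = Tensor(rng.normal(size=(9, 4)))
        ctx = SyntacticContext(7, (7, 9), ("amod", "root"), "dependency")
        E_S = embed_context_features(H, ctx)
        assert np.array_equal(E_S.data[0], H.data[6])
        assert np.array_equal(E_S.data[1], H.data[8])

    def test_self_only_context(self):
        H = Tensor(np.arange(12.0).reshape(3, 4))
        ctx = SyntacticContext(2, (2,), ("root",), "dependency")
        assert np.array_equal(embed_context_features(H, ctx).data[0], H.data[1])

    def test_random_contexts_bit_equal(self):
        rng = np.random.default_rng(5)
        H = Tensor(rng.normal(size=(6, 4)))
        for ctx in random_contexts(rng, 6):
            E_S = embed_context_features(H, ctx)
            for j, k in enumerate(ctx.context_positions):
                assert np.array_equal(E_S.data[j], H.data[k - 1])

    def test_out_of_range_position(self):
        H = Tensor(np.zeros((3, 4)))
        ctx = SyntacticContext(1, (1, 4), ("a", "b"), "dependency")
        with pytest.raises(IndexError):
            embed_context_features(H, ctx)


class TestEmbedSyntacticLabels:
    def test_label_lookup_and_tied_embeddings(self):
        params = make_params()
        vocab = make_vocab()
        ctx = SyntacticContext(1, (1, 2, 3), ("amod", "root", "amod"), "dependency")
        E_L = embed_syntactic_labels(ctx, params, vocab)
        assert E_L.shape == (3, 3)
        assert np.array_equal(E_L.data[0], E_L.data[2])  # same label, same column
        assert np.array_equal(E_L.data[0], params.label_embeddings.data[vocab["amod"]])

    def test_unseen_label_gets_unk_column(self):
        params = make_params()
        vocab = make_vocab()
        ctx = SyntacticContext(1, (1,), ("xcomp-never-seen",), "dependency")
        E_L = embed_syntactic_labels(ctx, params, vocab)
        assert np.array_equal(E_L.data[0], params.label_embeddings.data[vocab.unk_id])


class TestFuseAndProject:
    def test_identity_on_context_projection(self):
        params = make_params(d1=4, d2=3)
        params.projection_weight.data = np.hstack([np.eye(4), np.zeros((4, 3))])
        params.projection_bias.data = np.zeros(4)
        rng = np.random.default_rng(2)
        E_S = Tensor(rng.normal(size=(2, 4)))
        E_L = Tensor(rng.normal(size=(2, 3)))
        E = fuse_and_project(E_S, E_L, params)
        assert np.allclose(E.data, E_S.data)

    def test_zero_weight_constant_bias(self):
        params = make_params(d1=4, d2=3)
        params.projection_weight.data[:] = 0.0
        params.projection_bias.data = np.full(4, 2.5)
        E = fuse_and_project(Tensor(np.ones((3, 4))), Tensor(np.ones((3, 3))), params)
        assert np.allclose(E.data, 2.5)

    def test_matches_per_column_computation(self):
        params = make_params(d1=4, d2=3, seed=9)
        rng = np.random.default_rng(9)
        E_S = Tensor(rng.normal(size=(2, 4)))
        E_L = Tensor(rng.normal(size=(2, 3)))
        E = fuse_and_project(E_S, E_L, params)
        for j in range(2):
            col = params.projection_weight.data @ np.concatenate(
                [E_S.data[j], E_L.data[j]]
            ) + params.projection_bias.data
            assert np.allclose(E.data[j], col, atol=1e-6)

    def test_shape_mismatch_raises(self):
        params = make_params(d1=4, d2=3)
        with pytest.raises(ConfigurationError):
            fuse_and_project(Tensor(np.ones((2, 4))), Tensor(np.ones((3, 3))), params)
        with pytest.raises(ConfigurationError):
            fuse_and_project(Tensor(np.ones((2, 5))), Tensor(np.ones((2, 3))), params)


class TestAttend:
    def test_singleton_softmax(self):
        rng = np.random.default_rng(3)
        h = Tensor(rng.normal(size=(4,)))
        E = Tensor(rng.normal(size=(1, 4)))
        result = attend(h, E, 4)
        assert np.isclose(result.weights[0], 1.0)
        assert np.allclose(result.summary.data[0], E.data[0])

    def test_identical_columns_split_evenly(self):
        h = Tensor(np.array([1.0, 0.0, 2.0, -1.0]))
        col = np.array([0.5, 1.0, -0.5, 0.25])
        E = Tensor(np.stack([col, col]))
        result = attend(h, E, 4)
        assert np.allclose(result.weights, [0.5, 0.5])
        assert np.allclose(result.summary.data[0], col)

    def test_matches_exp_normalize_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            h = rng.normal(size=4)
            E = rng.normal(size=(3, 4))
            result = attend(Tensor(h), Tensor(E), 4)
            logits = E @ h / np.sqrt(4)
            w = np.exp(logits)
            w /= w.sum()
            assert np.allclose(result.weights, w, atol=1e-6)
            assert np.isclose(result.weights.sum(), 1.0, atol=1e-6)
            assert np.allclose(result.summary.data[0], w @ E, atol=1e-6)
            assert np.allclose(result.output.data[0], np.concatenate([w @ E, h]))

    def test_output_is_summary_concat_hidden(self):
        rng = np.random.default_rng(12)
        h = Tensor(rng.normal(size=(4,)))
        E = Tensor(rng.normal(size=(2, 4)))
        result = attend(h, E, 4)
        assert result.output.shape == (1, 8)
        assert np.array_equal(result.output.data[0, 4:], h.data)


class TestCfaForward:
    def test_shapes(self):
        rng = np.random.default_rng(4)
        H = Tensor(rng.normal(size=(9, 4)))
        contexts = random_contexts(rng, 9)
        params = make_params(d1=4, d2=3)
        O = cfa_forward(H, contexts, params, make_vocab())
        assert O.shape == (9, 8)

    def test_matches_loop_oracle(self):
        vocab = make_vocab()
        for trial in range(10):
            rng = np.random.default_rng(100 + trial)
            n = int(rng.integers(1, 7))
            d1 = int(rng.integers(2, 9))
            d2 = int(rng.integers(2, 6))
            params = make_params(n_labels=len(vocab), d1=d1, d2=d2, seed=trial)
            H = Tensor(rng.normal(size=(n, d1)))
            contexts = random_contexts(rng, n)
            O = cfa_forward(H, contexts, params, vocab)
            expected = cfa_oracle(
                H.data,
                contexts,
                params.label_embeddings.data,
                params.projection_weight.data,
                params.projection_bias.data,
                vocab.to_dict(),
            )
            assert np.allclose(O.data, expected, atol=1e-6)

    def test_tagless_positions_get_zero_summary(self):
        rng = np.random.default_rng(6)
        H = Tensor(rng.normal(size=(5, 4)))
        contexts = [None] + random_contexts(rng, 5)[1:4] + [None]
        params = make_params(d1=4, d2=3)
        O = cfa_forward(H, contexts, params, make_vocab())
        assert np.allclose(O.data[0, :4], 0.0)
        assert np.allclose(O.data[4, :4], 0.0)
        assert np.array_equal(O.data[0, 4:], H.data[0])

    def test_summary_in_convex_hull_with_identity_projection(self):
        """With zero label table and identity projection, a_i is a convex
        combination of the context hidden vectors."""
        rng = np.random.default_rng(8)
        d1 = 4
        params = make_params(n_labels=4, d1=d1, d2=3)
        params.label_embeddings.data[:] = 0.0
        params.projection_weight.data = np.hstack([np.eye(d1), np.zeros((d1, 3))])
        params.projection_bias.data[:] = 0.0
        H = Tensor(rng.normal(size=(6, d1)))
        contexts = random_contexts(rng, 6)
        O = cfa_forward(H, contexts, params, make_vocab())
        for i, ctx in enumerate(contexts):
            cols = np.stack([H.data[k - 1] for k in ctx.context_positions])
            a = O.data[i, :d1]
            # solve for convex weights: must lie in span with weights summing to 1
            w, *_ = np.linalg.lstsq(cols.T, a, rcond=None)
            assert np.allclose(cols.T @ w, a, atol=1e-8)
            assert np.isclose(w.sum(), 1.0, atol=1e-6)
            assert np.all(w >= -1e-9)

    def test_temperature_sharpens_weights(self):
        """Scaling h_i moves the singleton's attention toward its argmax."""
        rng = np.random.default_rng(13)
        d1 = 4
        h = rng.normal(size=d1)
        E = rng.normal(size=(3, d1))
        def weights(c):
            logits = E @ (c * h) / np.sqrt(d1)
            w = np.exp(logits - logits.max())
            return w / w.sum()
        base = attend(Tensor(h), Tensor(E), d1).weights
        assert np.allclose(base, weights(1.0), atol=1e-9)
        top = int(np.argmax(weights(1.0)))
        last = weights(1.0)[top]
        for c in (2.0, 4.0, 8.0):
            cur = weights(c)[top]
            assert cur >= last - 1e-12
            last = cur

    def test_gradients_reach_all_parameter_groups(self):
        """One backward pass leaves nonzero gradients in the label table, the
        projection, and the hidden states (hence the encoder)."""
        rng = np.random.default_rng(14)
        params = make_params(d1=4, d2=3, seed=3)
        H = Parameter(rng.normal(size=(5, 4)))
        contexts = random_contexts(rng, 5)
        O = cfa_forward(H, contexts, params, make_vocab())
        (O * O).sum().backward()
        assert H.grad is not None and np.any(H.grad != 0)
        assert np.any(params.label_embeddings.grad != 0)
        assert np.any(params.projection_weight.grad != 0)
        assert np.any(params.projection_bias.grad != 0)
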