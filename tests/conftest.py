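import numpy as np
import pytest

from syntagner.examples import worked_example
from syntagner.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture
def worked():
    """The nine-word worked example with all annotation layers."""
    return worked_example()


@pytest.fixture
def small_corpus():
    """A small fully annotated synthetic corpus (dependency cue)."""
    return generate_corpus(GeneratorConfig(n_sentences=30, seed=7))


@pytest.fixture(params=["pos", "constituent", "dependency"])
def cue_type(request):
    return request.param


# ---------------------------------------------------------------------------
# Independent oracles, deliberately implemented with different algorithms
# than the package code they check.
# ---------------------------------------------------------------------------


def oracle_spans(labels):
    """Entity spans from an untyped BIO sequence via string-run splitting.

    Maximal [BI]+ runs are split before every B; an I-run opening a run (after
    O or at the start) counts as an entity of its own (lenient conversion).
    """
    text = "".join(labels)
    assert set(text) <= {"B", "I", "O"}
    spans = []
    i = 0
    n = len(text)
    while i < n:
        if text[i] == "O":
            i += 1
            continue
        j = i + 1
        while j < n and text[j] == "I":
            j += 1
        spans.append((i + 1, j + 1))
        i = j
    return set(spans)


def oracle_prf(gold_seqs, pred_seqs):
    """Entity-level P/R/F1 over untyped sequences, from raw TP/FP/FN counts."""
    tp = fp = fn = 0
    for g, p in zip(gold_seqs, pred_seqs):
        gs, ps = oracle_spans(g), oracle_spans(p)
        tp += len(gs & ps)
        fn += len(gs - ps)
        fp += len(ps - gs)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def cfa_oracle(H, contexts, label_table, W_e, b_e, label_ids):
    """Per-token, loop-based CFA forward (no batching, no shared code paths)."""
    n, d1 = H.shape
    outputs = []
    for i, ctx in enumerate(contexts):
        if ctx is None:
            a = np.zeros(d1)
        else:
            cols = []
            for k, lab in zip(ctx.context_positions, ctx.syntactic_labels):
                e_s = H[k - 1]
                e_l = label_table[label_ids.get(lab, 0)]
                cols.append(W_e @ np.concatenate([e_s, e_l]) + b_e)
            logits = np.array([H[i] @ c / np.sqrt(d1) for c in cols])
            w = np.exp(logits - logits.max())
            w = w / w.sum()
            a = sum(wj * c for wj, c in zip(w, cols))
        outputs.append(np.concatenate([a, H[i]]))
    return np.stack(outputs)


def random_contexts(rng, n, max_m=4):
    """Random well-formed syntactic contexts for an n-token sentence."""
    from syntagner.syntax_features import SyntacticContext

    labels_pool = ["amod", "root", "det", "nsubj", "obj", "advmod"]
    contexts = []
    for i in range(1, n + 1):
        m = int(rng.integers(1, min(max_m, n) + 1))
        others = [k for k in range(1, n + 1) if k != i]
        chosen = sorted(
            {i, *rng.choice(others, size=m - 1, replace=False)} if m > 1 else {i}
        )
        labs = [labels_pool[int(rng.integers(0, len(labels_pool)))] for _ in chosen]
        contexts.append(
            SyntacticContext(i, tuple(chosen), tuple(labs), "dependency")
        )
    return contexts
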