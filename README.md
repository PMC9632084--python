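# syntagner

Syntax-aware biomedical named entity recognition (BioNER) as a reusable,
desk-scale toolkit. It is aimed at people who want to study *how* syntactic
structure and multi-corpus training help a neural BIO tagger — researchers
prototyping sequence-labeling architectures, and students of biomedical text
mining — rather than at production annotation of PubMed.

Two mechanisms form the core:

1. **Combined Feature Attention (CFA).** For each word `x_i` with encoder
   hidden state `h_i`, a rule system extracts a syntactic context
   `S_i = [s_{i,1} .. s_{i,m_i}]` with labels `L_i` from one of three
   sources — a POS window, the covering constituent, or the dependency
   neighbourhood. Context words are embedded by their own hidden states
   (`e^S_{i,j} = h_k`), labels by a trainable table, and the pair is fused
   and attended:

       e_{i,j} = W_e (e^S_{i,j} ⊕ e^L_{i,j}) + b_e
       a_{i,j} = softmax(h_iᵀ e_{i,j} / √d1)
       a_i     = Σ_j a_{i,j} e_{i,j}
       o_i     = a_i ⊕ h_i

   A softmax head over `o_i` yields the BIO distribution
   `ŷ = softmax(W o_i + b)`; training minimizes cross-entropy.

2. **Fully-shared multi-task learning (MTL).** Several BIO corpora are
   mixed into one training stream by wrapping each sentence in dataset tag
   identifier tokens (`<T> … </T>`). No task-specific layers exist: the
   tag embeddings are the only extra parameters, and at inference the
   chosen tag conditions the shared model on a dataset's annotation
   convention.

Everything runs from plain text inputs (CoNLL-2003-style BIO files,
CoNLL-U, Penn bracketed trees) with a tiny seeded encoder, and a synthetic
corpus generator produces fully annotated, mutually consistent corpora so
every component is testable on one CPU with no downloads.

## Worked example

The running example sentence is *"This case is a paternally transmitted
congenital myotonic dystrophy"*, where positions 7–9 ("congenital myotonic
dystrophy") form a disease entity:

```python
>>> from syntagner.examples import worked_example
>>> from syntagner.syntax_features import (
...     extract_pos_context, extract_constituent_context, extract_dependency_context)
>>> s = worked_example()
>>> ctx = extract_pos_context(s, 7, window=1)
>>> [s.tokens[k - 1] for k in ctx.context_positions], list(ctx.syntactic_labels)
(['transmitted', 'congenital', 'myotonic'], ['VBN', 'JJ', 'JJ'])
>>> ctx.m
3
>>> ctx = extract_constituent_context(s, 7)
>>> [s.tokens[k - 1] for k in ctx.context_positions]
['a', 'paternally', 'transmitted', 'congenital', 'myotonic', 'dystrophy']
>>> list(ctx.syntactic_labels)
['NP', 'ADJP', 'ADJP', 'NP', 'NP', 'NP']
>>> ctx = extract_dependency_context(s, 7)
>>> [s.tokens[k - 1] for k in ctx.context_positions], list(ctx.syntactic_labels)
(['congenital', 'dystrophy'], ['amod', 'root'])
```

The POS rule selects the word and its neighbours (`m_7 = 3`); the
constituent rule selects the six words under the first acceptable ancestor
(the NP spanning positions 4–9), each labelled by its lowest phrasal
ancestor; the dependency rule selects the word and its single governor
"dystrophy", labelled by their incoming relations.

The desk-scale experiments train the full pipeline on synthetic corpora
whose entities are determined by a dependency cue invisible in the surface
string:

```python
>>> from syntagner.experiments import parameter_recovery, tag_conditioning
>>> r = parameter_recovery()          # ~40 s on one CPU core
>>> round(r["mean_f1_true"], 3), round(r["mean_f1_shuffled"], 3)
(1.0, 0.62)
>>> t = tag_conditioning(seed=1)      # ~25 s
>>> round(t["ceiling"], 3), t["DN"]["f1_A"], t["DN"]["f1_B"], round(t["NONE"]["min_f1"], 3)
(0.654, 1.0, 1.0, 0.308)
```

Reading: with real syntax the CFA tagger recovers every entity
(mean validation F1 1.0 over three seeds); with the dependency labels
globally permuted it collapses to 0.62 — the syntactic mechanism, not model
capacity, carries the signal. On the conflicting-convention corpus pair the
dataset-tag model reproduces either convention on the *same* sentences
(F1 1.0 under each tag), while direct mixing is capped by the analytic
agreement ceiling 0.654 and lands at 0.308 on its worse side.

## Command line

```bash
syntagner generate --n-sentences 200 --seed 1 --out-dir data   # BIO + CoNLL-U + trees
syntagner extract  --feature-type dependency --bio data/synthetic.bio \
                   --conllu data/synthetic.conllu --trees data/synthetic.trees
syntagner train    --config run.yaml --mtl-variant DN
syntagner predict  --checkpoint runs/demo/checkpoint --bio test.bio \
                   --conllu test.conllu --predict-tag synthA --out pred.tsv
syntagner evaluate --pred pred.tsv
```

Run directories are self-describing (resolved config, per-epoch JSON-lines
metrics, checkpoint, log); repeating a run with the same config and seed
reproduces the metrics file byte for byte. See `docs/methods.md` for the
model, the generator's scope, and all numerical choices.

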