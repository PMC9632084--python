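# Methods

## The tagging model

`syntagner` treats named entity recognition as BIO sequence labeling: a
sentence `X = [x_1 .. x_n]` is mapped to labels `y_i ∈ {B, I, O}` (typed
variants `B-T`/`I-T` are supported in I/O; the default head has three
outputs). The model has three stages.

**Encoder.** An encoder produces hidden vectors `H = [h_1 .. h_n]`,
`h_i ∈ R^{d1}`, one per word, fine-tuned with the rest of the model. The
shipped profile is a tiny self-contained encoder (token + learned position
embeddings, one single-head self-attention block with a two-layer
feed-forward, residual connections, and a final local bigram layer that adds
a learned projection of the left neighbour). The bigram layer exists because
single-head attention with absolute position embeddings generalizes poorly on
relative-neighbour patterns at this scale, and the B-vs-I decision at a span
boundary is exactly such a pattern. A `pretrained-transformer` profile
(12-layer, 768-wide, first-subtoken subword pooling) is declared in the
configuration surface for full-scale use but requires external pretrained
weights; constructing it in this build raises a configuration error. The
encoder refuses sequences longer than `max_seq_len` (default 128) rather
than truncating silently; truncation is handled explicitly by the wrapping
layer.

**Syntactic contexts.** For each word, one of three deterministic rule
systems selects a context sequence `S_i` (positions) and a parallel label
sequence `L_i` (syntactic labels), both of length `m_i ≥ 1`:

- *POS*: a symmetric 1-word window clipped at the boundary; labels are the
  POS tags of the selected words. `m_i ∈ {window+1 .. 2·window+1}`.
- *Constituent*: from the leaf of `x_i`, walk up to the first ancestor whose
  label is in an acceptable inventory (default: the CoNLL-2003 chunk labels
  NP, VP, PP, ADJP, ADVP, SBAR, PRT, INTJ, CONJP, LST); the context is every
  word under that node, and each context word is labelled with its own
  lowest non-pre-terminal ancestor. If no ancestor is acceptable the tree
  root is the covering node, which guarantees `m_i ≥ 1`.
- *Dependency*: the word itself, its governor (if any) and its dependents;
  each context word is labelled with the relation on its own incoming arc
  (the root-governed word is labelled `root`).

Contexts are emitted in surface order and always contain `x_i` itself.
Punctuation receives no special treatment. One feature type is used per run.

**Combined feature attention (CFA).** Context words are embedded by reusing
the encoder states, `e^S_{i,j} = h_k` where `k` is the context word's
sentence position — so context embeddings are contextual and there is no
out-of-vocabulary case. Labels get a trainable table `E^L` of width `d2`
(initialized uniformly in [-0.1, 0.1]). Each pair is fused by a learned
projection

    e_{i,j} = W_e · (e^S_{i,j} ⊕ e^L_{i,j}) + b_e ,   W_e ∈ R^{d1×(d1+d2)},

with `b_e` a single width-`d1` vector broadcast across the `m_i` columns (a
per-column bias would not be learnable consistently because `m_i` varies).
Scaled dot-product attention queried by `h_i` yields weights
`a_{i,j} = softmax(h_iᵀ e_{i,j} / √d1)` over `j = 1..m_i` and the summary
`a_i = Σ_j a_{i,j} e_{i,j}`; the module output is `o_i = a_i ⊕ h_i` of width
`2·d1`. Softmax uses max-subtraction; the batched implementation pads to the
longest context with a masked softmax and is verified against a per-token
loop oracle at 1e-6. Positions without a parse (tag identifiers, below)
bypass attention with `a_i = 0` so the output width stays uniform.

**Head and training.** A linear layer plus softmax maps `o_i` to the label
distribution; the loss is mean cross-entropy over unmasked positions, and
decoding is per-token argmax with ties broken toward the earlier label in
(B, I, O). No CRF is used; illegal transitions are left to the evaluator's
lenient span conversion. Training is plain Adam with seeded shuffling;
model selection keeps the epoch with the best validation macro-F1 (the
selection rule is a documented assumption). With a fixed seed the entire
run, including the metrics file, is bit-reproducible on one machine.

Defaults: the full-scale configuration is recorded as learning rate 5e-5,
batch 64, 30 epochs, `d1 = d2 = 768`. The desk-scale profile used by the
tests and experiments is `d1 = d2 = 32`, one attention block, Adam at 5e-3,
batch 16, at most 30 epochs — a model trained from random initialization
needs a far larger step size than a fine-tuned pretrained encoder.

## Fully-shared multi-task learning

To train one model on several BIO corpora without task-specific layers, each
training sentence is wrapped in tag identifier tokens naming its origin:
`<T> x_1 .. x_n </T>` for dataset `T` (variant `DN`), the entity type name
(`TN`, e.g. `<Species> .. </Species>`), both pairs (`TN_DN`), the leading
tag only (`DN_no_end`), or nothing (`NONE`, direct mixing — the degradation
baseline). Tags are atomic vocabulary entries with trainable embeddings,
labelled `O` internally and masked from loss and evaluation; their
positions carry no syntactic context. All wrapped corpora are pooled and
shuffled per epoch (no round-robin, no balancing — the simplest faithful
pooling). The only parameters the multi-task model adds over the
single-task model are the tag embedding rows, which the test suite asserts
by an exact parameter census. At inference the caller picks a tag; the
choice conditions the shared representation and can change the prediction
for the same sentence, which is the intended mechanism for serving several
annotation conventions from one model. Default variant is `DN`; tag
embeddings are randomly initialized (whether the original design derived
them from word pieces is unstated, so the simpler choice is made). If
wrapping exceeds `max_seq_len`, interior words are truncated and the end
tag retained, and the syntactic contexts of surviving words are clipped.

## Evaluation

Entity-level precision/recall/F1 with exact `(span, type)` matching.
BIO-to-span conversion is lenient: `B` opens a span; an `I` after `O`,
after a different type, or at the start also opens one (this matches the
default of the standard sequence-evaluation scorers). Macro-F1 averages
per-type F1 without weighting over the types present in gold; with one
entity type — the usual benchmark situation — macro equals that type's F1.
A degenerate gold standard with no entities scores 1.0 only if nothing was
predicted. The scorer is checked against an independently implemented
run-splitting scorer on random prediction sets with zero tolerated
discrepancies.

## Synthetic corpora

The generator emulates the three input layers jointly from a template
grammar `NP VERB NP (ADV)` with `NP = (DT)? (ADJ){0..2} HEAD`, producing
mutually consistent POS tags, a dependency tree (verb root, `nsubj`/`obj`
heads, `amod`/`det`/`advmod` internals) and a constituency tree, with
sentence length bounded by the grammar at 11 tokens (cap 20). Entity-hood
of each NP is an independent coin flip (default probability 0.5 per NP)
recorded **only** in the chosen cue layer: relation subtypes `nsubj:ent` /
`obj:ent` / `amod:ent` (dependency cue), tag variants `NN-E`/`JJ-E` (POS
cue), or the node label `NPE` (constituent cue). Entity-head nouns also
head non-entity NPs, so the surface form underdetermines the labels — a
tagger ignoring the syntax layer is capped well below perfect F1, while a
rule reading the cue recovers every entity exactly (asserted in the tests;
this certifies the learning experiments are well-posed). Gold spans cover
the adjectives and head (`full-span`) or just the head (`head-only`); the
determiner stays outside.

What the generator does **not** emulate: real biomedical vocabulary
statistics, parser noise (annotations are produced by the grammar, not a
parser), long sentences, discontinuous or nested entities, or
inter-annotator inconsistency beyond the two clean conventions. Passing the
desk-scale experiments therefore shows the architecture and training loop
implement the intended mechanisms — attention over syntactic cues, and
tag-conditioned convention switching — not that comparable F1 would be
reached on real corpora with a pretrained encoder.

## Desk-scale experiments

Two pre-registered protocols (`syntagner.experiments`):

- **Parameter recovery.** 200 training / 60 validation sentences
  (dependency cue), three seeds. The true-syntax condition must reach mean
  validation entity F1 ≥ 0.95 within 30 epochs; a control with the
  dependency relation labels globally permuted (structure intact, marginal
  label distribution preserved, root pinned) must lose ≥ 0.10 F1.
- **Tag conditioning.** Corpora A (full-span) and B (head-only) over
  identical 150-sentence training sets and a shared 50-sentence evaluation
  pair. The `DN`-tagged model must score F1 ≥ 0.9 under each tag on the
  same sentences. The `NONE` model is bounded by the agreement ceiling
  `1 − q/2`, where `q` is the fraction of entities whose two convention
  spans differ: a single BIO labeling cannot contain two nested spans, so
  each ambiguous entity can match at most one convention. The formula is
  cross-checked in the tests by brute-force enumeration of per-entity
  strategies.

## Numerical and degenerate-input choices

- All arithmetic is float64; gradients come from a small reverse-mode
  engine whose primitives are verified against central differences.
- Softmax rows are never empty (`m_i ≥ 1` is a hard invariant; fully masked
  rows are a contract violation upstream).
- Decoding ties break deterministically by label order; epoch shuffles are
  pure functions of (seed, epoch).
- Empty corpora, malformed lines, annotation/token mismatches, unknown
  tags and shape mismatches all raise typed errors (`ParseError`,
  `AlignmentError`, `ConfigurationError`); the CLI maps configuration
  errors to exit code 2 and data errors to 3. Tokenization mismatches are
  never repaired — alignment is positional and exact by design.

## Known limitations

- The tiny encoder is not a language model; it carries no pretrained
  knowledge and its results do not transfer to real text.
- The acceptable-ancestor inventory for constituent contexts is the
  CoNLL-2003 chunk label set; other inventories can be configured but the
  default is an informed convention, not a printed specification.
- Only basic (single-head) dependency trees are accepted; enhanced graphs
  are rejected.
- One syntactic feature type per run; combining types is out of scope.
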