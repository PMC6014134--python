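# Methods

## Task and model

`chemrel` treats chemical–gene relation extraction as sentence-level
classification of candidate mention pairs. A document is split into
sentences; every (chemical, gene) pair co-occurring in a sentence becomes a
candidate instance; the classifier assigns one of six labels — the five
evaluated CHEMPROT groups (CPR:3 activation, CPR:4 inhibition, CPR:5
agonist, CPR:6 antagonist, CPR:9 substrate/product) or `False`. Relations
whose two mentions sit in different sentences are out of scope and produce
no candidate.

Two classifiers share one composition cell, a child-sum binary tree-LSTM
with a separate forget gate per child (shared forget weights; only the
child state fed to the gate differs):

- the **tree-LSTM** model evaluates the cell bottom-up over a binary
  constituency parse and reads class scores from the root only;
- the **SPINN** model executes the parse's SHIFT/REDUCE transition program
  over a buffer and stack, with a tracking LSTM whose hidden state enters
  the cell as the auxiliary vector `e_j`. In the plain tree-LSTM, `e_j` is
  zero; the two models are numerically identical when the tracking weights
  are zero and the extra input features are disabled — a property the test
  suite asserts to 1e-6, which is also the correctness contract standing in
  for dynamic-batching execution strategies: any evaluation order over the
  graph must reproduce naive per-node recursion.

Recurrent dropout multiplies the candidate update `u_j` by a
Bernoulli(keep_p) mask during training only (`drop(x) = mask*x` in train,
`x` in eval — note: no 1/keep_p rescaling, matching the update rule as
published). The mask is sampled once per tree per forward pass and shared
across that tree's nodes, the variational reading of recurrent dropout;
per-node resampling was the open alternative, but a per-tree mask keeps
train-time forward passes cheaper and is the standard choice for recurrent
cells. l2 regularization is intentionally absent — recurrent dropout
replaces it.

## Input features

A node input is `[word ∥ position ∥ subtree]`, 200 + 20 + 10 = 230
dimensions by default:

- **Word**: a 200-d embedding looked up per leaf token; internal nodes get
  a zero word block. Embeddings are fixed during training. Tokens below the
  vocabulary threshold (`min_count`, default 3) and unknown tokens share a
  single rare vector drawn once from uniform(−0.05, 0.05) with a stored
  seed, so it is identical across lookups and runs.
- **Position** (leaves only): two signed distances
  `d_i = token_index − entity_index` to the first- and second-appearing
  target entity, each mapped to a fixed 10-bit code: a sign bit plus a
  bottom-up thermometer — |d| ones for |d| ≤ 5, then 6/7/8/9 ones for the
  bands 6–10, 11–15, 16–20, ≥ 21. Distance 0 (the entity token itself) is
  the all-zero column. The published table elides the far-negative columns;
  they mirror the positive bands with the sign bit clear. Internal nodes
  get a zero position block.
- **Subtree containment** (every node): 1 if a target-entity token occurs
  among the node's leaves, else 0, widened to 10 copies so a single bit is
  not drowned out by the 200-d word block. Width is configurable
  (`subtree_size`).

The SPINN uses the word block only; its position and subtree blocks are
zero (the features have no natural sequential formulation).

## Preprocessing

Sentence splitting is rule-based: terminal punctuation followed by
whitespace, an abbreviation guard (e.g., single capital initials as in
"S. aureus"), and a repair step that discards any boundary falling inside
an annotated mention span — the only property downstream code relies on.
Tokenization is whitespace plus punctuation splitting, applied **after**
placeholder substitution so placeholders stay atomic.

Anonymization schemes:

- *challenge*: the two targets become `BC6ENT1`/`BC6ENT2` in order of
  appearance in the sentence (not chem-before-gene); optionally, chemical
  surfaces from a user-supplied lexicon become `CHEM`. The lexicon replaces
  an external chemical tagger; without one the `CHEM` step is skipped.
- *postchallenge*: target chemical → `BC6ENTC`, target gene → `BC6ENTG`,
  every other annotated entity → `BC6OTHER`.

Instances whose two target spans overlap, and pairs carrying two or more
distinct gold groups ("confusing"), are filtered from training data; the
filters are switchable off for dev/test-style preparation, since the
published corpus statistics filter the training split only. Pairs whose
only gold relation belongs to a non-evaluated group (e.g. CPR:10) default
to `False` instances (switchable), because the evaluation scores five
groups only and the method has no other class to give them.

## Parse trees and transition programs

Trees arrive as bracketed S-expressions, one per instance. The dialect is
unlabeled: every atom is a leaf; a two-element group is a binary node;
wider groups fold right-branching (strict mode rejects them instead).
Constituent labels cannot be distinguished from leaves in this dialect and
are therefore not produced by the reader — the models consume only words
and structure, so nothing downstream changes.

The canonical transition program is the strict post-order linearization:
SHIFT per leaf, REDUCE per internal node once both children are complete,
giving exactly `n` SHIFTs and `n − 1` REDUCEs for `n` leaves — the only
counts for which the stack can end at size 1. (A widely reproduced worked
example of this construction prints one REDUCE too few for its six-leaf
tree; the package implements the count-consistent program.) REDUCE pops
the top two stack states with the earlier-pushed one as left child. The
SHIFT operation composes the new leaf through the same cell with zero
child states, matching the recursive model's leaf handling, and a tracking
step precedes every transition (shift or reduce). The tracking input is
the buffer-top's plain word vector plus the top two stack hidden states,
zero-padded when absent; tracking hidden size defaults to the cell hidden
size.

## Training and ensembling

Mini-batch Adam (β1 = 0.9, β2 = 0.999, ε = 1e-8 — the standard published
defaults) on mean softmax cross-entropy, computed via log-sum-exp. Weights
initialize uniform(−0.1, 0.1) from a seeded generator; everything
downstream of the seed is deterministic. Reference hyperparameters
(`Hyperparams` defaults): batch 256, hidden 256, learning rate 0.001,
keep_p 0.5, subtree width 10, 1000 epochs, 10 ensemble members.

Ensembling sums the members' pre-softmax logits element-wise and takes the
argmax ("logits" mode; summing softmax probabilities is available as
`mode="proba"`). Members are replicas of one architecture trained from
different seeds. Multi-sentence duplicates of the same (pmid, chem, gene)
pair deduplicate to the occurrence with the highest class score when
predictions are written out.

Evaluation pools TP/FP/FN over the five CPR groups; `False` is the absence
of a relation (predicting it never contributes TP or FP). Micro-F1 =
2PR/(P+R), reported in percent. File-level scoring
(`micro_prf_relations`) matches predictions to gold on exact
(pmid, group, chem, gene) keys.

## Numerical implementation

Because every sentence induces its own computation graph, the models run on
a small tape-based reverse-mode autodiff over float64 numpy arrays
(`chemrel._autodiff`) — elementwise arithmetic, fused affine maps,
sigmoid/tanh, concatenation, and a fused softmax cross-entropy; the
backward sweep is iterative (no recursion limits on deep right-branching
parses). Correctness is guarded by a central-finite-difference gradient
check (max relative error below 1e-4 on a small tree; the relative-error
denominator is floored at 1e-6 because an O(1) float64 loss carries ~1e-11
differencing noise). Argmax ties break toward the lowest class index, so
all-equal scores predict `False`.

## Synthetic data

The generator emulates the CHEMPROT corpus structure: abstracts with
character-offset entity annotations and gold relations. Sentences come
from templates; relation-bearing sentences plant a group-specific cue verb
between a chemical and a gene (activation words for CPR:3, inhibition
words for CPR:4, "agonist"/"antagonist" for CPR:5/6, substrate/product
words for CPR:9), negatives use neutral verbs disjoint from every cue set.
Defaults: 50 abstracts, 2–4 sentences each, class priors 0.5 `False` and
0.1 per CPR group, distractor entity rate 0.3 (extra mentions inserted
into negative sentences, exercising bystander anonymization and extra
False pairs), and 10% of planted relations crossing a sentence boundary
(these must yield no candidate). Entity pools include multi-token names to
exercise placeholder collapsing. Parses are right-branching — the models
accept any binary tree, and learnability of the planted signal, not
linguistic realism, is what the tests need. Byte-identical output is
guaranteed per seed.

What the generator does **not** emulate: real syntactic variety, realistic
class imbalance (the real corpus is ~3:1 negative:positive), discourse
phenomena, or cue words that appear detached from the related pair.
Passing the learnability tests therefore shows the models can fit a
recoverable signal through their full pipelines — not that they reach any
particular accuracy on real text, which additionally requires the external
corpus, pretrained embeddings and full-scale training.

## Desk-scale test conditions

The learnability checks train on 200 instances with hidden size 32, batch
16 (≈13 Adam steps per epoch), learning rate 0.001, early-stopping once
training micro-F1 reaches 0.95 (checked every 5 epochs), capped at 300
epochs for the tree-LSTM and 400 for the SPINN. These sizes are the
package's desk-scale configuration: large enough that both models must
actually learn the planted cues through their full feature pipelines,
small enough to run on one CPU alongside the rest of the suite. The
reference configuration (hidden 256, 1000 epochs, 10 members) is shipped
as the `Hyperparams` defaults.

## Known limitations

- No cross-sentence relation extraction; cross-sentence gold is dropped by
  construction.
- No named-entity recognition: mentions come from annotations; the `CHEM`
  substitution needs a user lexicon.
- No constituency parser: trees are consumed as input; only a
  right-branching fallback is generated.
- No hyperparameter search harness; the shipped defaults are the selected
  values of the published two-round search.
- Embeddings are fixed (not fine-tuned) during training.
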