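# chemrel

Chemical–gene relation extraction from biomedical abstracts with recursive
neural networks.

Curated pharmacology knowledgebases lag far behind the literature; text
mining systems that propose chemical–gene relation candidates to human
curators help close the gap. `chemrel` classifies every co-occurring
(chemical mention, gene mention) pair inside a sentence into one of the five
evaluated CHEMPROT relation groups — CPR:3 (up-regulator/activator), CPR:4
(down-regulator/inhibitor), CPR:5 (agonist), CPR:6 (antagonist), CPR:9
(substrate/product) — or "False" (no relation). Two classifiers are
provided, both built from the same composition cell:

* **Tree-LSTM** — a child-sum binary tree-LSTM over a constituency parse.
  For node *j* with children *k* ∈ *B*(*j*), |*B*(*j*)| = 2:

  ```
  h̃_j  = Σ_k h_k
  i_j  = σ(W_i [x_j, h̃_j, e_j] + b_i)
  f_jk = σ(W_f [x_j, h_k, e_j] + b_f)        (one forget gate per child)
  o_j  = σ(W_o [x_j, h̃_j, e_j] + b_o)
  u_j  = tanh(W_u [x_j, h̃_j, e_j] + b_u)
  c_j  = i_j ⊙ drop(u_j) + Σ_k f_jk ⊙ c_k
  h_j  = o_j ⊙ tanh(c_j)
  ```

  The node input `x_j = [word(200) ∥ position(2×10) ∥ subtree(10)]` is 230
  dimensional: a word embedding, two thermometer-coded signed distances to
  the target entities (exact for |d| ≤ 5, banded 6–10 / 11–15 / 16–20 / ≥21),
  and a 10-wide subtree-containment flag. Class scores are read from the
  root: `p(y|x) = W_fc h_root + b_fc` (6 classes), trained with softmax
  cross-entropy and Adam; `drop` is recurrent dropout on the candidate
  update.

* **SPINN** — a shift-reduce executor over the same cell. A buffer holds
  the sentence, a stack holds partial subtrees; SHIFT composes the next word
  as a leaf, REDUCE composes the top two stack states. A tracking LSTM reads
  `[buffer top ∥ stack top-1 ∥ stack top-2]` before every transition and its
  hidden state enters the cell as `e_j`. Position/subtree features are not
  used here.

Replicas trained from different random initializations are ensembled by
summing their pre-softmax logits before the argmax. Evaluation is
micro-averaged precision/recall/F1 pooled over the five CPR groups
("False" is the absence of a relation, never a scored class).

Target entities are anonymized before parsing: either `BC6ENT1`/`BC6ENT2`
by order of appearance (challenge scheme, with optional `CHEM` substitution
of lexicon chemicals), or `BC6ENTC`/`BC6ENTG` with bystander entities as
`BC6OTHER` (post-challenge scheme). Words seen fewer than three times map
to a single fixed random "rare" vector.

The models and their training loop are implemented on a small tape-based
reverse-mode autodiff over numpy (`chemrel._autodiff`), since every
sentence induces its own computation graph.

## Worked example

No external corpus is needed; the synthetic generator emits CHEMPROT-format
abstracts with planted relation cues:

```bash
chemrel synth --n-abstracts 12 --seed 3 --out corpus/
# wrote 12 abstracts, 34 instances (0 overlap / 0 confusing removed) to corpus/

printf 'hidden_size: 32\nbatch_size: 16\nepochs: 60\n' > cfg.yaml
chemrel train --model treelstm --instances corpus/instances.tsv \
    --parses corpus/parses.txt --embeddings corpus/embeddings.txt \
    --config cfg.yaml --seed 1 --min-count 1 --out model.npz
```

Training prints a results summary such as:

```
Tree-LSTM chemical-gene relation classifier
======================================================
Instances:      34         Hidden size:    4
Input dim:      230        Parameters:     3854
Epochs run:     2          Final loss:     1.7826
Seed:           1          Keep prob:      0.5
------------------------------------------------------
Training-set performance (micro-averaged over CPR groups):
class      TP    FP    FN
CPR:3       0     0     5
CPR:4       5    29     0
...
micro_f = 19.23
```

(the block above is the 2-epoch smoke configuration; with the 60-epoch
config the same corpus is fit to micro_f = 100). `Input dim: 230` is the
word+position+subtree node input; `micro_f` is the pooled F1 over the five
CPR groups. Predict and score:

```bash
chemrel predict --model treelstm --instances corpus/instances.tsv \
    --parses corpus/parses.txt --embeddings corpus/embeddings.txt \
    --ensemble model.npz --min-count 1 --out pred.tsv
chemrel evaluate --gold corpus/relations.tsv --pred pred.tsv
```

The same flow is available as a library, statsmodels-style:

```python
from chemrel import TreeLSTMModel, Hyperparams
model = TreeLSTMModel(instances, trees, embeddings, vocab,
                      Hyperparams(hidden_size=32, batch_size=16))
res = model.fit(seed=7, epochs=300, early_stop_f1=0.95)
print(res.summary())
labels = res.predict()
```

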