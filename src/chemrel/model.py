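"""Model / Results interface for the two relation classifiers.

A model object is built from prepared data — anonymized candidate instances,
their binary parse trees, and an embedding table — and ``fit()`` runs
mini-batch Adam on the softmax cross-entropy, returning a
:class:`RelationResults` carrying the fitted parameters, the loss history
and evaluation helpers::

    model = TreeLSTMModel(instances, trees, embeddings, vocab, hp)
    res = model.fit(seed=0)
    print(res.summary())
    labels = res.predict()

Ensembling follows the logit-sum rule: replicas of the same architecture are
trained from different random initializations and their pre-softmax class
scores are summed before the argmax (``fit_ensemble`` /
``ensemble_predict``).  Summing softmax probabilities instead is available
via ``mode="proba"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _autodiff as ad
from .corpus import CLASSES, Prediction
from .evaluate import EvalReport, micro_prf
from .features import EmbeddingTable, POSITION_SIZE, instance_node_inputs
from .parsetree import BinaryParseTree, to_transitions
from .preprocess import CandidateInstance, Vocabulary
from .spinn import TrackingParams, run as spinn_run
from .treelstm import (
    DropoutSpec,
    TreeLSTMParams,
    forward as treelstm_forward,
    loss as ce_loss,
    predict as argmax_label,
)


@dataclass
class Hyperparams:
    """Training hyperparameters; defaults are the selected values of the
    published configuration (batch 256, hidden 256, lr 0.001, keep
    probability 0.5, subtree vector size 10, 1000 epochs, 10 ensemble
    members)."""

    batch_size: int = 256
    hidden_size: int = 256
    learning_rate: float = 0.001
    keep_p: float = 0.5
    subtree_size: int = 10
    epochs: int = 1000
    ensemble_k: int = 10
    tracking_size: Optional[int] = None  # None -> hidden_size
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.hidden_size < 1 or self.epochs < 0:
            raise ValueError("batch_size/hidden_size/epochs must be positive")
        if not (0.0 < self.keep_p <= 1.0):
            raise ValueError("keep_p must lie in (0, 1]")
        if self.subtree_size < 1:
            raise ValueError("subtree_size must be >= 1")


class Adam:
    """Adam with the standard published defaults (b1=0.9, b2=0.999,
    eps=1e-8)."""

    def __init__(self, tensors: Dict[str, ad.Tensor], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.tensors = tensors
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v.value) for k, v in tensors.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in tensors.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.tensors.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class _RelationModel:
    """Shared construction / training machinery of the two classifiers."""

    model_type = ""

    def __init__(self,
                 instances: Sequence[CandidateInstance],
                 trees: Sequence[BinaryParseTree],
                 embeddings: EmbeddingTable,
                 vocab: Optional[Vocabulary] = None,
                 hp: Optional[Hyperparams] = None):
        if len(instances) != len(trees):
            raise ValueError("instances and trees misaligned")
        self.hp = hp or Hyperparams()
        self.hp.validate()
        self.instances = list(instances)
        self.trees = list(trees)
        self.embeddings = embeddings
        self.vocab = vocab
        for inst, tree in zip(self.instances, self.trees):
            if tree.tokens() != inst.tokens:
                raise ValueError(
                    f"tree leaves do not match tokens for instance "
                    f"{inst.pmid}/{inst.chem_id}/{inst.gene_id}")
        self.labels = [inst.label for inst in self.instances]
        self._compiled = [self._compile(i, t)
                          for i, t in zip(self.instances, self.trees)]

    @property
    def input_dim(self) -> int:
        return self.embeddings.dim + 2 * POSITION_SIZE + self.hp.subtree_size

    # subclass hooks ---------------------------------------------------
    def _compile(self, inst, tree):  # pragma: no cover - abstract
        raise NotImplementedError

    def _init_params(self, seed: int):
        raise NotImplementedError

    def _forward(self, compiled, bundle, dropout):
        raise NotImplementedError

    # ------------------------------------------------------------------
    def fit(self, seed: Optional[int] = None, epochs: Optional[int] = None,
            early_stop_f1: Optional[float] = None, eval_every: int = 10,
            verbose: bool = False) -> "RelationResults":
        """Train with mini-batch Adam; deterministic given ``seed``.

        ``early_stop_f1`` stops once the training-set micro-F1 (checked
        every ``eval_every`` epochs, evaluation mode) reaches the given
        level.  NaN loss aborts with a diagnostic.
        """
        if not self.instances:
            raise ValueError("empty training set")
        seed = self.hp.seed if seed is None else seed
        epochs = self.hp.epochs if epochs is None else epochs
        bundle = self._init_params(seed)
        tensors = _bundle_tensors(bundle)
        opt = Adam(tensors, self.hp.learning_rate)
        rng = np.random.default_rng(seed)
        dropout = DropoutSpec(keep_p=self.hp.keep_p, train_mode=True,
                              rng=np.random.default_rng(seed + 1))
        n = len(self.instances)
        loss_history: List[float] = []
        epochs_run = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for lo in range(0, n, self.hp.batch_size):
                batch = order[lo:lo + self.hp.batch_size]
                logits = [self._forward(self._compiled[i], bundle, dropout)
                          for i in batch]
                L = ce_loss(logits, [self.labels[i] for i in batch])
                if not np.isfinite(L.value):
                    raise FloatingPointError(
                        f"training diverged: loss={L.value} at epoch {epoch}")
                for t in tensors.values():
                    t.grad = None
                ad.backward(L)
                opt.step()
                epoch_losses.append(float(L.value))
            loss_history.append(float(np.mean(epoch_losses)))
            epochs_run = epoch + 1
            if verbose:
                print(f"epoch {epoch + 1:4d}  loss {loss_history[-1]:.4f}")
            if early_stop_f1 is not None and (epoch + 1) % eval_every == 0:
                rep = self._evaluate_train(bundle)
                if rep.micro_f1 >= 100.0 * early_stop_f1:
                    break
        return RelationResults(model=self, bundle=bundle, seed=seed,
                               loss_history=loss_history,
                               epochs_run=epochs_run)

    def _predict_logits(self, bundle,
                        compiled: Optional[list] = None) -> np.ndarray:
        compiled = self._compiled if compiled is None else compiled
        out = np.empty((len(compiled), len(CLASSES)))
        for i, comp in enumerate(compiled):
            out[i] = self._forward(comp, bundle, None).value
        return out

    def _evaluate_train(self, bundle) -> EvalReport:
        logits = self._predict_logits(bundle)
        preds = [CLASSES[j] for j in logits.argmax(axis=1)]
        return micro_prf(self.labels, preds)


class TreeLSTMModel(_RelationModel):
    """Child-sum tree-LSTM classifier with position and subtree features."""

    model_type = "treelstm"

    def __init__(self, *args, use_features: bool = True, **kwargs):
        self.use_features = use_features
        super().__init__(*args, **kwargs)

    def _compile(self, inst, tree):
        inputs = instance_node_inputs(
            tree, inst.tokens, inst.e1_index, inst.e2_index,
            self.embeddings, self.vocab, use_features=self.use_features,
            subtree_size=self.hp.subtree_size)
        return tree, inputs

    def _init_params(self, seed: int):
        params = TreeLSTMParams.init(
            self.input_dim, self.hp.hidden_size,
            tracking_size=self.hp.tracking_size, seed=seed)
        return {"cell": params}

    def _forward(self, compiled, bundle, dropout):
        tree, inputs = compiled
        return treelstm_forward(tree, inputs, bundle["cell"], dropout)


class SPINNModel(_RelationModel):
    """Shift-reduce executor sharing the tree-LSTM cell, with a tracking
    LSTM; word vectors only (no position / subtree features)."""

    model_type = "spinn"

    def _compile(self, inst, tree):
        program = to_transitions(tree)
        vecs = [self.embeddings.lookup(tok, self.vocab) for tok in inst.tokens]
        return program, vecs

    def _init_params(self, seed: int):
        T = self.hp.tracking_size or self.hp.hidden_size
        params = TreeLSTMParams.init(
            self.input_dim, self.hp.hidden_size, tracking_size=T, seed=seed)
        tracking = TrackingParams.init(
            self.embeddings.dim, self.hp.hidden_size, T, seed=seed + 10_000)
        return {"cell": params, "tracking": tracking}

    def _forward(self, compiled, bundle, dropout):
        program, vecs = compiled
        return spinn_run(program, vecs, bundle["cell"], bundle["tracking"],
                         dropout)


def _bundle_tensors(bundle) -> Dict[str, ad.Tensor]:
    out: Dict[str, ad.Tensor] = {}
    for prefix, part in bundle.items():
        for name, t in part.tensors().items():
            out[f"{prefix}.{name}"] = t
    return out


@dataclass
class RelationResults:
    """Fitted parameters plus diagnostics; the return value of ``fit``."""

    model: _RelationModel
    bundle: dict
    seed: int
    loss_history: List[float]
    epochs_run: int
    classes: Tuple[str, ...] = CLASSES

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1] if self.loss_history else float("nan")

    def predict_logits(self, instances=None, trees=None) -> np.ndarray:
        """Root class scores, evaluation mode (deterministic)."""
        if instances is None:
            return self.model._predict_logits(self.bundle)
        compiled = [self.model._compile(i, t) for i, t in zip(instances, trees)]
        return self.model._predict_logits(self.bundle, compiled)

    def predict(self, instances=None, trees=None) -> List[str]:
        logits = self.predict_logits(instances, trees)
        return [CLASSES[j] for j in logits.argmax(axis=1)]

    def evaluate(self, gold: Optional[Sequence[str]] = None) -> EvalReport:
        gold = self.model.labels if gold is None else gold
        return micro_prf(list(gold), self.predict())

    def n_parameters(self) -> int:
        return sum(t.value.size for t in _bundle_tensors(self.bundle).values())

    def summary(self) -> str:
        rep = self.evaluate()
        hp = self.model.hp
        name = {"treelstm": "Tree-LSTM", "spinn": "SPINN"}[self.model.model_type]
        lines = [
            f"{name} chemical-gene relation classifier",
            "=" * 54,
            f"Instances:      {len(self.model.instances):<10d} "
            f"Hidden size:    {hp.hidden_size}",
            f"Input dim:      {self.model.input_dim:<10d} "
            f"Parameters:     {self.n_parameters()}",
            f"Epochs run:     {self.epochs_run:<10d} "
            f"Final loss:     {self.final_loss:.4f}",
            f"Seed:           {self.seed:<10d} "
            f"Keep prob:      {hp.keep_p}",
            "-" * 54,
            "Training-set performance (micro-averaged over CPR groups):",
            rep.summary(),
        ]
        return "\n".join(lines)

    # persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: every parameter tensor, plus hyperparameters, seed,
        class order and model type in a versioned JSON header."""
        arrays = {k.replace(".", "__"): t.value
                  for k, t in _bundle_tensors(self.bundle).items()}
        meta = {
            "format_version": 1,
            "model_type": self.model.model_type,
            "classes": list(self.classes),
            "seed": self.seed,
            "epochs_run": self.epochs_run,
            "loss_history": self.loss_history,
            "hyperparams": asdict(self.model.hp),
        }
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @staticmethod
    def load_arrays(path) -> Tuple[dict, Dict[str, np.ndarray]]:
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            arrays = {k.replace("__", "."): data[k]
                      for k in data.files if k != "__meta__"}
        return meta, arrays


def load_results(path, model: _RelationModel) -> RelationResults:
    """Rebuild a :class:`RelationResults` from a checkpoint, attached to a
    model holding the data to predict on."""
    meta, arrays = RelationResults.load_arrays(path)
    if meta["model_type"] != model.model_type:
        raise ValueError(
            f"checkpoint is a {meta['model_type']} model, not {model.model_type}")
    if tuple(meta["classes"]) != CLASSES:
        raise ValueError("checkpoint class order does not match this build")
    bundle = model._init_params(meta["seed"])
    for key, tensor in _bundle_tensors(bundle).items():
        if key not in arrays:
            raise ValueError(f"checkpoint missing tensor {key}")
        if arrays[key].shape != tensor.value.shape:
            raise ValueError(f"checkpoint tensor {key} has shape "
                             f"{arrays[key].shape}, expected {tensor.value.shape}")
        tensor.value = arrays[key]
    return RelationResults(model=model, bundle=bundle, seed=meta["seed"],
                           loss_history=list(meta["loss_history"]),
                           epochs_run=meta["epochs_run"])


def fit_ensemble(model: _RelationModel, k: Optional[int] = None,
                 base_seed: Optional[int] = None,
                 **fit_kwargs) -> List[RelationResults]:
    """Train ``k`` replicas differing only in random initialization."""
    k = model.hp.ensemble_k if k is None else k
    base_seed = model.hp.seed if base_seed is None else base_seed
    if k < 1:
        raise ValueError("ensemble needs k >= 1")
    return [model.fit(seed=base_seed + i, **fit_kwargs) for i in range(k)]


def ensemble_predict(results: Sequence[RelationResults],
                     instances=None, trees=None,
                     mode: str = "logits") -> Tuple[List[str], np.ndarray]:
    """Sum member class scores element-wise, then argmax.

    ``mode="logits"`` (default) sums pre-softmax scores; ``mode="proba"``
    sums softmax probabilities.  Members must share the class ordering.
    """
    if not results:
        raise ValueError("ensemble needs at least one member")
    orders = {r.classes for r in results}
    if len(orders) != 1:
        raise ValueError("ensemble members disagree on class ordering")
    total = None
    for r in results:
        logits = r.predict_logits(instances, trees)
        if mode == "proba":
            z = logits - logits.max(axis=1, keepdims=True)
            logits = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        elif mode != "logits":
            raise ValueError(f"unknown ensemble mode {mode!r}")
        total = logits if total is None else total + logits
    labels = [CLASSES[j] for j in total.argmax(axis=1)]
    return labels, total


def predictions_from_labels(instances: Sequence[CandidateInstance],
                            labels: Sequence[str],
                            scores: Optional[np.ndarray] = None,
                            ) -> List[Prediction]:
    """Turn per-instance labels into deduplicated relation predictions.

    False-class instances emit nothing.  When the same (pmid, chem, gene)
    pair was classified in several sentences, the occurrence with the
    highest class score wins.
    """
    best: Dict[Tuple[str, str, str], Prediction] = {}
    for i, (inst, lab) in enumerate(zip(instances, labels)):
        if lab == "False":
            continue
        score = float(scores[i].max()) if scores is not None else 0.0
        key = (inst.pmid, inst.chem_id, inst.gene_id)
        if key not in best or best[key].score < score:
            best[key] = Prediction(inst.pmid, lab, inst.chem_id,
                                   inst.gene_id, score)
    return list(best.values())
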