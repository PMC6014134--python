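"""Micro-averaged precision / recall / F1 over the five evaluated relation
groups.

"False" means *no relation*: predicting it never creates a true or false
positive.  Pooled over the five CPR classes, a gold-False instance predicted
as some CPR class adds one false positive; a gold-CPR instance predicted
False adds one false negative; a gold-CPR instance predicted as the wrong
CPR class adds one of each.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

from .corpus import CLASSES, EVALUATED_GROUPS


@dataclass
class EvalReport:
    """Per-class contingency counts and pooled micro scores (percent)."""

    tp: Dict[str, int]
    fp: Dict[str, int]
    fn: Dict[str, int]

    @property
    def total_tp(self) -> int:
        return sum(self.tp.values())

    @property
    def total_fp(self) -> int:
        return sum(self.fp.values())

    @property
    def total_fn(self) -> int:
        return sum(self.fn.values())

    @property
    def micro_precision(self) -> float:
        denom = self.total_tp + self.total_fp
        return 100.0 * self.total_tp / denom if denom else 0.0

    @property
    def micro_recall(self) -> float:
        denom = self.total_tp + self.total_fn
        return 100.0 * self.total_tp / denom if denom else 0.0

    @property
    def micro_f1(self) -> float:
        p, r = self.micro_precision, self.micro_recall
        return 2 * p * r / (p + r) if p + r > 0 else 0.0

    def summary(self) -> str:
        lines = ["class      TP    FP    FN"]
        for g in EVALUATED_GROUPS:
            lines.append(f"{g:<8} {self.tp[g]:>4}  {self.fp[g]:>4}  {self.fn[g]:>4}")
        lines.append(f"micro_p = {self.micro_precision:.2f}")
        lines.append(f"micro_r = {self.micro_recall:.2f}")
        lines.append(f"micro_f = {self.micro_f1:.2f}")
        return "\n".join(lines)


def micro_prf(gold: Sequence[str], predicted: Sequence[str]) -> EvalReport:
    """Pooled contingency over the five CPR groups.

    Both sequences hold class labels from
    ``{"False", "CPR:3", ..., "CPR:9"}`` and must be aligned and of equal
    length.
    """
    if len(gold) != len(predicted):
        raise ValueError("gold and predicted label sequences differ in length")
    for lab in list(gold) + list(predicted):
        if lab not in CLASSES:
            raise ValueError(f"unknown label {lab!r}")
    tp = {g: 0 for g in EVALUATED_GROUPS}
    fp = {g: 0 for g in EVALUATED_GROUPS}
    fn = {g: 0 for g in EVALUATED_GROUPS}
    for y, yhat in zip(gold, predicted):
        if y == yhat:
            if y != "False":
                tp[y] += 1
        else:
            if yhat != "False":
                fp[yhat] += 1
            if y != "False":
                fn[y] += 1
    return EvalReport(tp=tp, fp=fp, fn=fn)


def micro_prf_relations(gold_relations, predictions) -> EvalReport:
    """Challenge-style file-level scoring on (pmid, group, chem, gene) keys.

    A prediction is a true positive iff the identical annotated relation
    exists in the gold set; unmatched predictions are false positives and
    unmatched gold relations false negatives.
    """
    gold_keys = {(r.pmid, r.group, r.chem_id, r.gene_id) for r in gold_relations}
    pred_keys = {(p.pmid, p.group, p.chem_id, p.gene_id) for p in predictions}
    tp = {g: 0 for g in EVALUATED_GROUPS}
    fp = {g: 0 for g in EVALUATED_GROUPS}
    fn = {g: 0 for g in EVALUATED_GROUPS}
    for key in pred_keys:
        if key[1] not in EVALUATED_GROUPS:
            raise ValueError(f"prediction with non-evaluated group {key[1]!r}")
        if key in gold_keys:
            tp[key[1]] += 1
        else:
            fp[key[1]] += 1
    for key in gold_keys - pred_keys:
        fn[key[1]] += 1
    return EvalReport(tp=tp, fp=fp, fn=fn)
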