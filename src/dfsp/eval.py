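"""Point-wise instance segmentation scoring.

Predicted instances are matched one-to-one to ground-truth instances greedily
by descending point overlap; per-organ precision/recall/F1 come from the
matched confusion counts, and plant-level scores are the per-organ means with
the F1 of the means (not the mean of F1s). Pooled micro metrics over points are
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .errors import ValidationError

__all__ = ["OrganScore", "PlantScore", "match_instances", "score_plant"]


@dataclass
class OrganScore:
    organ_id: int          # ground-truth id, or -pred_id-1 for unmatched predictions
    tp: int
    fp: int
    fn: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.precision = self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0
        self.recall = self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0
        pr = self.precision + self.recall
        self.f1 = 2 * self.precision * self.recall / pr if pr else 0.0


@dataclass
class PlantScore:
    per_organ: List[OrganScore]
    p_p: float
    r_p: float
    f_p: float
    n_o: int
    pooled_precision: float
    pooled_recall: float
    pooled_f1: float

    def to_dict(self) -> dict:
        return {
            "precision": self.p_p,
            "recall": self.r_p,
            "f1": self.f_p,
            "n_organs": self.n_o,
            "pooled": {
                "precision": self.pooled_precision,
                "recall": self.pooled_recall,
                "f1": self.pooled_f1,
            },
            "organs": [
                {"organ": s.organ_id, "tp": s.tp, "fp": s.fp, "fn": s.fn,
                 "precision": s.precision, "recall": s.recall, "f1": s.f1}
                for s in self.per_organ
            ],
        }


def _as_labels(a) -> np.ndarray:
    arr = np.asarray(a, dtype=np.int64).ravel()
    return arr


def match_instances(pred, truth) -> Dict[int, int]:
    """Greedy one-to-one matching of predicted to truth instances by overlap.

    Ties are broken by (pred id, truth id). Unmatched predicted ids are absent
    from the mapping.
    """
    pred = _as_labels(pred)
    truth = _as_labels(truth)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth label arrays differ in length")
    pairs, counts = np.unique(np.column_stack([pred, truth]), axis=0,
                              return_counts=True)
    order = np.lexsort((pairs[:, 1], pairs[:, 0], -counts))
    mapping: Dict[int, int] = {}
    used_truth = set()
    for oi in order:
        p, t = int(pairs[oi, 0]), int(pairs[oi, 1])
        if p in mapping or t in used_truth:
            continue
        mapping[p] = t
        used_truth.add(t)
    return mapping


def score_plant(pred, truth) -> PlantScore:
    """Per-organ and plant-level precision/recall/F1 against ground truth."""
    pred = _as_labels(pred)
    truth = _as_labels(truth)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth label arrays differ in length")
    truth_ids = np.unique(truth)
    if truth_ids.size == 0:
        raise ValidationError("ground truth has no instances")
    mapping = match_instances(pred, truth)
    inverse = {t: p for p, t in mapping.items()}
    scores: List[OrganScore] = []
    for t in truth_ids:
        t = int(t)
        t_mask = truth == t
        if t in inverse:
            p_mask = pred == inverse[t]
            tp = int(np.sum(t_mask & p_mask))
            fp = int(np.sum(p_mask) - tp)
            fn = int(np.sum(t_mask) - tp)
        else:
            tp, fp, fn = 0, 0, int(np.sum(t_mask))
        scores.append(OrganScore(t, tp, fp, fn))
    for p in np.unique(pred):
        p = int(p)
        if p not in mapping:  # spurious prediction: scores against empty truth
            scores.append(OrganScore(-p - 1, 0, int(np.sum(pred == p)), 0))
    p_p = float(np.mean([s.precision for s in scores]))
    r_p = float(np.mean([s.recall for s in scores]))
    f_p = 2 * p_p * r_p / (p_p + r_p) if p_p + r_p else 0.0
    tp_sum = sum(s.tp for s in scores)
    fp_sum = sum(s.fp for s in scores)
    fn_sum = sum(s.fn for s in scores)
    pooled_p = tp_sum / (tp_sum + fp_sum) if tp_sum + fp_sum else 0.0
    pooled_r = tp_sum / (tp_sum + fn_sum) if tp_sum + fn_sum else 0.0
    pooled_f = (2 * pooled_p * pooled_r / (pooled_p + pooled_r)
                if pooled_p + pooled_r else 0.0)
    return PlantScore(scores, p_p, r_p, f_p, len(scores),
                      pooled_p, pooled_r, pooled_f)
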