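"""Scoring predictions: surface masks, confusion counts, MCC and friends.

Evaluation is restricted to surface residues by a RASA rule (``ge_0.05``:
RASA >= 0.05; ``gt_0``: RASA > 0 — different benchmark datasets use
different rules). The headline metric is the Matthews correlation
coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

computed with exact integer arithmetic under the radical; any zero factor
in the denominator yields MCC = 0, the standard random-prediction
convention. Confusion counts are pooled over all evaluated residues by
default; per-protein aggregation is available because the two modes are
not comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import pandas as pd

from .predictor import ResiduePrediction, call_from_probability
from .structures import ResidueId

__all__ = [
    "ConfusionCounts",
    "surface_mask",
    "confusion",
    "mcc",
    "secondary_metrics",
    "sweep",
    "SURFACE_RULES",
]

SURFACE_RULES: dict[str, Callable[[float], bool]] = {
    "ge_0.05": lambda r: r >= 0.05,
    "gt_0": lambda r: r > 0.0,
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)


def surface_mask(
    rasa: Mapping[ResidueId, float],
    rule: str | Callable[[float], bool] = "ge_0.05",
) -> dict[ResidueId, bool]:
    """Which residues count as surface and therefore enter the scoring."""
    fn = SURFACE_RULES[rule] if isinstance(rule, str) else rule
    return {rid: bool(fn(v)) for rid, v in rasa.items()}


def confusion(
    calls: Mapping[ResidueId, bool],
    truth: Mapping[ResidueId, bool],
    mask: Optional[Mapping[ResidueId, bool]] = None,
) -> ConfusionCounts:
    """Exact confusion counts over masked residues.

    ``calls`` and ``truth`` must cover the same residues; a mismatch is an
    alignment error listing the offenders.
    """
    if set(calls) != set(truth):
        missing = set(truth) ^ set(calls)
        raise ValueError(
            f"prediction/truth residue sets differ; offenders: {sorted(missing)[:10]}"
        )
    tp = fn = fp = tn = 0
    for rid, label in truth.items():
        if mask is not None and not mask.get(rid, False):
            continue
        call = calls[rid]
        if label and call:
            tp += 1
        elif label and not call:
            fn += 1
        elif call:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1]; 0 on zero denominator."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


def secondary_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Precision, recall, accuracy and F1 with 0/0 reported as 0."""
    precision = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
    recall = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
    accuracy = (c.tp + c.tn) / c.total if c.total else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return {"precision": precision, "recall": recall,
            "accuracy": accuracy, "f1": f1}


def sweep(
    predictions: Sequence[ResiduePrediction],
    truth: Mapping[ResidueId, bool],
    thresholds: Sequence[float],
    mask: Optional[Mapping[ResidueId, bool]] = None,
) -> pd.DataFrame:
    """Re-threshold retained probabilities without re-querying the KB.

    One row per threshold: confusion counts, interface-call count, MCC and
    the secondary metrics. A sweep row at threshold t equals a fresh
    prediction run at t because the probabilities are threshold-free.
    """
    rows = []
    probs = {p.rid: p.probability for p in predictions}
    for t in thresholds:
        calls = {rid: call_from_probability(p, t) for rid, p in probs.items()}
        c = confusion(calls, truth, mask=mask)
        row = {"threshold": t, "n_calls": sum(calls.values()),
               "tp": c.tp, "fn": c.fn, "fp": c.fp, "tn": c.tn,
               "mcc": mcc(c)}
        row.update(secondary_metrics(c))
        rows.append(row)
    return pd.DataFrame(rows)
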