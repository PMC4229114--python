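"""ROC / precision-recall scoring of a predicted network against a gold
standard.

Every unordered gene pair off the diagonal is a binary instance (label:
is the pair an edge of the gold standard), scored by the absolute
predicted weight so that signed and unsigned reconstructions are
comparable.  Thresholds sweep the distinct score values, with tied
scores entering together; the ROC area therefore equals the midrank
Mann-Whitney statistic, and a constant (uninformative) prediction scores
exactly 0.5.  The precision-recall area is the step-wise integral
(average precision).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .netio import TrueNetwork, ValidationError, WeightedNetwork

__all__ = ["EvaluationResult", "evaluate"]


@dataclass(frozen=True)
class EvaluationResult:
    """ROC and PR curves plus their areas for one prediction/truth pair."""

    roc_points: np.ndarray  # (k, 2) columns FPR, TPR; (0,0) .. (1,1)
    pr_points: np.ndarray   # (k, 2) columns recall, precision
    auc: float
    aupr: float
    n_true_edges: int
    n_pairs: int


def evaluate(pred: WeightedNetwork, truth: TrueNetwork) -> EvaluationResult:
    """Score ``pred`` against ``truth`` over their (identical) gene set.

    Callers integrating different gene universes must restrict both to
    the intersection first; a gene-set mismatch raises.
    """
    if set(pred.gene_ids) != set(truth.gene_ids):
        diff = sorted(set(pred.gene_ids) ^ set(truth.gene_ids))
        raise ValidationError(f"prediction and truth gene sets differ: {diff}")
    if truth.gene_ids != pred.gene_ids:
        truth = TrueNetwork(pred.gene_ids, truth.edges)
    y_true = truth.tri_labels()
    y_score = np.abs(pred.tri_values())
    n_pos = int(y_true.sum())
    if n_pos == 0 or n_pos == y_true.size:
        raise ValidationError(
            "truth must contain at least one edge and one non-edge over the gene set"
        )

    fpr, tpr, _ = roc_curve(y_true, y_score, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(y_true, y_score)
    aupr = float(average_precision_score(y_true, y_score))
    pr = np.column_stack([recall[::-1], precision[::-1]])  # recall increasing
    return EvaluationResult(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=pr,
        auc=auc,
        aupr=aupr,
        n_true_edges=n_pos,
        n_pairs=int(y_true.size),
    )
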