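"""Tie-aware ROC curves, truncated AUC, E-value sweeps and congruence.

When many pairs share one bit score (notably the proxy-scored pairs at 0
bits), ordering within the tie is arbitrary and a naive step curve would
introduce artifacts.  Here each maximal run of equal scores is rendered as
a single straight ROC segment — the exact expectation of the step curve
over random orderings of the tie — so positives and negatives are evenly
distributed within tied stretches.

The headline statistic is AUCn: the area under the cumulative TP-vs-FP
polyline truncated at the first ``n`` false positives (default 1000),
normalized by ``n_eff * P`` so that perfect separation scores 1 and a
label-independent constant scorer scores 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .architectures import SCHEMES
from .sampling import UNCOVERED, PairLabel
from .scoring import ScoredPair

__all__ = [
    "RocResult",
    "ConfusionAtCutoff",
    "roc_curve",
    "auc_n",
    "evaluate_scored_pairs",
    "confusion_at_cutoffs",
    "congruence_table",
    "EvaluationError",
]


class EvaluationError(ValueError):
    pass


@dataclass
class RocResult:
    """Tie-resolved ROC polyline plus its truncated AUC.

    ``points`` is an (k, 2) float array of cumulative (FP, TP) vertices
    starting at (0, 0) and ending at (N, P); both coordinates are
    non-decreasing.
    """

    points: np.ndarray
    auc_n: float
    n_cutoff: int
    total_positives: int
    total_negatives: int


@dataclass
class ConfusionAtCutoff:
    e_value_cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")


def _scores_and_flags(scored: Sequence[ScoredPair]) -> tuple[np.ndarray, np.ndarray]:
    scores = np.array([sp.bit_score for sp in scored], dtype=float)
    positive = np.array([sp.pair.role == "positive" for sp in scored], dtype=bool)
    if not np.isfinite(scores).all():
        raise EvaluationError("non-finite bit score encountered")
    return scores, positive


def roc_curve(scored: Sequence[ScoredPair]) -> np.ndarray:
    """Vertices of the tie-resolved ROC polyline.

    Pairs are sorted by bit score descending; each maximal run of equal
    scores containing p positives and n negatives contributes one straight
    segment to (FP + n, TP + p).  Proxy-scored pairs all sit at 0 bits and
    therefore form (part of) the final tie run.
    """
    scores, positive = _scores_and_flags(scored)
    total_p = int(positive.sum())
    total_n = int((~positive).sum())
    if total_p == 0 or total_n == 0:
        raise EvaluationError(
            f"ROC undefined: need both positives and negatives (P={total_p}, N={total_n})"
        )
    order = np.argsort(-scores, kind="stable")
    scores = scores[order]
    positive = positive[order]

    vertices = [(0.0, 0.0)]
    fp = tp = 0
    i = 0
    while i < len(scores):
        j = i
        while j < len(scores) and scores[j] == scores[i]:
            j += 1
        run_p = int(positive[i:j].sum())
        run_n = (j - i) - run_p
        fp += run_n
        tp += run_p
        vertices.append((float(fp), float(tp)))
        i = j
    return np.array(vertices, dtype=float)


def auc_n(
    points: np.ndarray,
    n_cutoff: int,
    total_positives: int,
    total_negatives: int,
) -> float:
    """Truncated, normalized area under the ROC polyline.

    Exact trapezoid integration of TP over FP in [0, n_eff] with
    n_eff = min(n_cutoff, N), normalized by n_eff * P.
    """
    if n_cutoff < 1:
        raise EvaluationError("n_cutoff must be >= 1")
    n_eff = min(n_cutoff, total_negatives)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        if x0 >= n_eff:
            break
        if x1 <= n_eff:
            area += (x1 - x0) * (y0 + y1) / 2.0
        else:  # segment straddles the cutoff: integrate the clipped part
            t = (n_eff - x0) / (x1 - x0)
            y_cut = y0 + t * (y1 - y0)
            area += (n_eff - x0) * (y0 + y_cut) / 2.0
            break
    return area / (n_eff * total_positives)


def evaluate_scored_pairs(
    scored: Sequence[ScoredPair], n_cutoff: int = 1000
) -> RocResult:
    """ROC polyline and AUCn for one tool's scored benchmark."""
    points = roc_curve(scored)
    _, positive = _scores_and_flags(scored)
    total_p = int(positive.sum())
    total_n = len(scored) - total_p
    value = auc_n(points, n_cutoff, total_p, total_n)
    return RocResult(
        points=points,
        auc_n=value,
        n_cutoff=n_cutoff,
        total_positives=total_p,
        total_negatives=total_n,
    )


def confusion_at_cutoffs(
    scored: Sequence[ScoredPair], cutoffs: Sequence[float]
) -> list[ConfusionAtCutoff]:
    """Confusion counts predicting homology at each E-value cutoff.

    A pair is predicted homologous iff the tool found an alignment and its
    E-value is <= the cutoff; proxy-scored pairs are always predicted
    non-homologous.
    """
    if len(cutoffs) == 0:
        raise ValueError("cutoff list must be non-empty")
    results = []
    for cutoff in cutoffs:
        tp = fp = tn = fn = 0
        for sp in scored:
            predicted = sp.found and sp.e_value is not None and sp.e_value <= cutoff
            actual_pos = sp.pair.role == "positive"
            if predicted and actual_pos:
                tp += 1
            elif predicted:
                fp += 1
            elif actual_pos:
                fn += 1
            else:
                tn += 1
        results.append(ConfusionAtCutoff(float(cutoff), tp, fp, tn, fn))
    return results


_CONGRUENCE_LABELS = (
    PairLabel.HOMOLOGOUS.value,
    PairLabel.AMBIGUOUS.value,
    PairLabel.NON_HOMOLOGOUS.value,
)


def congruence_table(
    labels: pd.DataFrame, schemes: Sequence[str] = SCHEMES
) -> pd.DataFrame:
    """Cross-scheme agreement on homology status.

    For each ordered scheme pair (A, B): restrict to pairs covered by both
    schemes, take the pairs homologous under A, and tabulate their labels
    under B as counts and percentages (rounded to two decimals).  Requires
    at least one pair covered by every scheme.
    """
    covered_all = np.ones(len(labels), dtype=bool)
    for scheme in schemes:
        covered_all &= (labels[scheme] != UNCOVERED).to_numpy()
    if not covered_all.any():
        raise EvaluationError("no pair is covered by all schemes")

    rows = []
    for scheme_a in schemes:
        total_hom_a = int((labels[scheme_a] == PairLabel.HOMOLOGOUS.value).sum())
        for scheme_b in schemes:
            if scheme_b == scheme_a:
                continue
            both = labels[
                (labels[scheme_a] != UNCOVERED) & (labels[scheme_b] != UNCOVERED)
            ]
            hom_a = both[both[scheme_a] == PairLabel.HOMOLOGOUS.value]
            n = len(hom_a)
            row: dict[str, object] = {
                "scheme_a": scheme_a,
                "scheme_b": scheme_b,
                "homologous_in_a": n,
                "homologous_in_a_total": total_hom_a,
            }
            for label in _CONGRUENCE_LABELS:
                count = int((hom_a[scheme_b] == label).sum())
                row[f"{label}_in_b"] = count
                row[f"{label}_in_b_pct"] = round(100.0 * count / n, 2) if n else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
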