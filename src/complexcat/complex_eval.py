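"""Evaluation of predicted protein-complex sets against a reference catalogue.

Two complementary views are computed.  Match-based metrics treat a
prediction as correct when its neighborhood affinity with some reference
complex — |P∩B|²/(|P||B|) — reaches a threshold ω, yielding precision,
recall and the F-measure.  Clustering-wise metrics (sensitivity, positive
predictive value and their geometric mean, the accuracy) are computed from
the full reference-by-prediction overlap matrix T and reward coverage and
purity without any threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "EvalMetrics",
    "neighborhood_affinity",
    "match_counts",
    "precision_recall_f",
    "sn_ppv_acc",
    "evaluate",
]

log = logging.getLogger(__name__)

MemberSet = frozenset[str]


def neighborhood_affinity(p: MemberSet | set[str], b: MemberSet | set[str]) -> float:
    """|p∩b|² / (|p|·|b|); 1 iff the sets are identical, 0 iff disjoint."""
    if not p or not b:
        raise ValueError("neighborhood affinity of an empty set is undefined")
    inter = len(p & b)
    return inter * inter / (len(p) * len(b))


def match_counts(
    predicted: Sequence[MemberSet],
    reference: Sequence[MemberSet],
    omega: float = 0.2,
) -> tuple[int, int]:
    """(N_cp, N_cb): predictions matching ≥1 reference and references matched.

    A match is an affinity of at least ``omega``.
    """
    if not 0.0 < omega <= 1.0:
        raise ValueError("omega must lie in (0,1]")
    n_cp = sum(
        1
        for p in predicted
        if any(neighborhood_affinity(p, b) >= omega for b in reference)
    )
    n_cb = sum(
        1
        for b in reference
        if any(neighborhood_affinity(p, b) >= omega for p in predicted)
    )
    return n_cp, n_cb


def precision_recall_f(
    predicted: Sequence[MemberSet],
    reference: Sequence[MemberSet],
    omega: float = 0.2,
) -> tuple[float, float, float]:
    """Match-based precision N_cp/|P|, recall N_cb/|B| and their harmonic mean."""
    if not predicted or not reference:
        raise ValueError("need non-empty predicted and reference sets")
    n_cp, n_cb = match_counts(predicted, reference, omega)
    precision = n_cp / len(predicted)
    recall = n_cb / len(reference)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f


def sn_ppv_acc(
    predicted: Sequence[MemberSet],
    reference: Sequence[MemberSet],
) -> tuple[float, float, float]:
    """Clustering-wise sensitivity, PPV and accuracy from the overlap matrix.

    With T_ij = |reference_i ∩ predicted_j|:
    Sn = Σ_i max_j T_ij / Σ_i |reference_i|, PPV = Σ_j max_i T_ij / Σ_ij T_ij,
    Acc = sqrt(Sn·PPV).  If no prediction overlaps any reference the PPV
    denominator is zero; all three metrics are then reported as 0 with a
    warning.
    """
    if not predicted or not reference:
        raise ValueError("need non-empty predicted and reference sets")
    t = [[len(b & p) for p in predicted] for b in reference]
    sn = sum(max(row) for row in t) / sum(len(b) for b in reference)
    denom = sum(sum(row) for row in t)
    if denom == 0:
        log.warning("no prediction overlaps any reference complex; Sn/PPV/Acc = 0")
        return 0.0, 0.0, 0.0
    ppv = sum(max(t[i][j] for i in range(len(reference))) for j in range(len(predicted))) / denom
    return sn, ppv, math.sqrt(sn * ppv)


@dataclass(frozen=True)
class EvalMetrics:
    n_predicted: int
    n_covered_proteins: int
    n_cp: int
    n_cb: int
    precision: float
    recall: float
    f_measure: float
    sensitivity: float
    ppv: float
    accuracy: float
    omega: float


def evaluate(
    predicted: Sequence[MemberSet],
    reference: Sequence[MemberSet],
    omega: float = 0.2,
    min_predicted_size: int = 2,
) -> EvalMetrics:
    """Full evaluation of a predicted complex set against a reference.

    Predictions smaller than ``min_predicted_size`` (singletons by default,
    whose affinity with any reference is degenerate) are excluded before
    any metric is computed; covered proteins count distinct proteins over
    the retained predictions.
    """
    kept = [p for p in predicted if len(p) >= min_predicted_size]
    if not kept or not reference:
        raise ValueError("no usable predicted complexes or empty reference")
    n_cp, n_cb = match_counts(kept, reference, omega)
    precision, recall, f = precision_recall_f(kept, reference, omega)
    sn, ppv, acc = sn_ppv_acc(kept, reference)
    return EvalMetrics(
        n_predicted=len(kept),
        n_covered_proteins=len(set().union(*kept)),
        n_cp=n_cp,
        n_cb=n_cb,
        precision=precision,
        recall=recall,
        f_measure=f,
        sensitivity=sn,
        ppv=ppv,
        accuracy=acc,
        omega=omega,
    )
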