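"""Evaluation of predicted against reference domain assignments.

Three complementary views are computed:

* **CDO (correct domain overlap)** — a binary per-target verdict: the
  prediction is correct iff it has the same number of domains as the
  reference and, under the optimal one-to-one matching of predicted to
  reference domains, every matched pair overlaps by more than a threshold
  ``t`` (fraction of the reference domain covered; the field convention is
  t = 0.85).  The CDO *score* of a benchmark is the fraction of correct
  targets, optionally swept over t to produce a threshold curve.

* **NDO (normalized domain overlap)** — a continuous [0, 1] score, less
  brittle than the binary CDO.  With O the pred×ref matrix of shared residue
  counts, NDO = (Σ_i max_j O_ij + Σ_j max_i O_ij) / (2·L): 1 exactly when
  the two partitions are identical, decreasing with boundary displacement.

* **single- vs multi-domain classification** — each target is labeled by
  whether its assignment has more than one domain; MCC (0 by convention when
  a confusion-matrix margin vanishes), precision on the multi-domain class
  and accuracy summarize the 2×2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import accuracy_score, matthews_corrcoef, precision_score

from .fragments import DomainAssignment

DEFAULT_OVERLAP_THRESHOLD = 0.85


def parse_domain_string(
    s: str, length: int, allow_gaps: bool = False
) -> DomainAssignment:
    """Parse ``"1-50,151-200;51-150"`` into a validated assignment."""
    return DomainAssignment.from_string(s, length, allow_gaps=allow_gaps)


def _overlap_matrix(pred: DomainAssignment, ref: DomainAssignment) -> np.ndarray:
    """Shared residue counts, shape (n_pred_domains, n_ref_domains)."""
    if pred.length != ref.length:
        raise ValueError("assignments have different lengths")
    lp, lr = pred.labels(), ref.labels()
    overlap = np.zeros((pred.n_domains, ref.n_domains), dtype=int)
    both = (lp >= 0) & (lr >= 0)
    np.add.at(overlap, (lp[both], lr[both]), 1)
    return overlap


def match_domains(
    pred: DomainAssignment, ref: DomainAssignment, method: str = "optimal"
) -> list[tuple[int, int]]:
    """One-to-one matching of predicted to reference domains.

    ``"optimal"`` maximizes total shared residues (Hungarian algorithm);
    ``"greedy"`` repeatedly takes the largest remaining overlap.  Returns
    (pred_index, ref_index) pairs; with unequal counts, surplus domains stay
    unmatched.
    """
    overlap = _overlap_matrix(pred, ref)
    if method == "optimal":
        rows, cols = linear_sum_assignment(-overlap)
        return list(zip(rows.tolist(), cols.tolist()))
    if method == "greedy":
        o = overlap.astype(float).copy()
        pairs = []
        for _ in range(min(o.shape)):
            i, j = np.unravel_index(np.argmax(o), o.shape)
            pairs.append((int(i), int(j)))
            o[i, :] = -1
            o[:, j] = -1
        return pairs
    raise ValueError(f"unknown matching method: {method}")


def cdo_correct(
    pred: DomainAssignment,
    ref: DomainAssignment,
    t: float = DEFAULT_OVERLAP_THRESHOLD,
    matching: str = "optimal",
) -> bool:
    """Binary verdict: same domain count and every matched overlap > t.

    The overlap fraction is |pred ∩ ref| / |ref domain|.
    """
    if pred.n_domains != ref.n_domains:
        return False
    overlap = _overlap_matrix(pred, ref)
    ref_sizes = np.array([d.size for d in ref.domains], dtype=float)
    for i, j in match_domains(pred, ref, method=matching):
        if overlap[i, j] / ref_sizes[j] <= t:
            return False
    return True


def cdo_score(
    pairs: list[tuple[DomainAssignment, DomainAssignment]],
    t: float = DEFAULT_OVERLAP_THRESHOLD,
    matching: str = "optimal",
) -> float:
    """Fraction of targets whose assignment is correct at threshold t."""
    if not pairs:
        raise ValueError("no targets to score")
    return float(
        np.mean([cdo_correct(p, r, t=t, matching=matching) for p, r in pairs])
    )


def cdo_sweep(
    pairs: list[tuple[DomainAssignment, DomainAssignment]],
    step: float = 0.01,
    matching: str = "optimal",
) -> list[tuple[float, float]]:
    """(t, CDO) curve over t ∈ [0, 1]; non-increasing in t by construction."""
    ts = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    return [(float(t), cdo_score(pairs, t=t, matching=matching)) for t in ts]


def ndo(pred: DomainAssignment, ref: DomainAssignment) -> float:
    """Normalized domain overlap in [0, 1]; 1 iff identical partitions."""
    overlap = _overlap_matrix(pred, ref)
    n_assigned_pred = int((pred.labels() >= 0).sum())
    n_assigned_ref = int((ref.labels() >= 0).sum())
    norm = n_assigned_pred + n_assigned_ref
    if norm == 0:
        raise ValueError("no assigned residues")
    score = overlap.max(axis=1).sum() + overlap.max(axis=0).sum()
    return float(score / norm)


@dataclass
class EvalResult:
    """Per-target and aggregate evaluation of a set of predictions."""

    target_ids: list[str]
    correct: list[bool]
    ndo_scores: list[float]
    overlap_per_domain: list[list[float]]
    threshold: float
    mcc: float = 0.0
    precision: float = 0.0
    accuracy: float = 0.0
    sweep: list[tuple[float, float]] | None = field(default=None, repr=False)

    @property
    def cdo(self) -> float:
        return float(np.mean(self.correct))

    @property
    def mean_ndo(self) -> float:
        return float(np.mean(self.ndo_scores))


def classification_metrics(
    pairs: list[tuple[DomainAssignment, DomainAssignment]],
) -> tuple[float, float, float]:
    """MCC, precision and accuracy of the single/multi-domain call.

    Multi-domain (>1 domain) is the positive class; MCC is 0 by convention
    when a confusion-matrix margin is zero.
    """
    if not pairs:
        raise ValueError("no targets to score")
    y_pred = [p.n_domains > 1 for p, _ in pairs]
    y_true = [r.n_domains > 1 for _, r in pairs]
    with warnings.catch_warnings():
        # single-label degenerate inputs are handled by the 0-convention
        warnings.simplefilter("ignore")
        mcc = float(matthews_corrcoef(y_true, y_pred))
    prec = float(precision_score(y_true, y_pred, zero_division=0))
    acc = float(accuracy_score(y_true, y_pred))
    return mcc, prec, acc


def evaluate(
    pairs: list[tuple[DomainAssignment, DomainAssignment]],
    target_ids: list[str] | None = None,
    t: float = DEFAULT_OVERLAP_THRESHOLD,
    matching: str = "optimal",
    sweep: bool = False,
) -> EvalResult:
    """Full evaluation: per-target CDO/NDO plus aggregate classification."""
    if target_ids is None:
        target_ids = [f"target{i + 1}" for i in range(len(pairs))]
    correct, ndos, overlaps = [], [], []
    for pred, ref in pairs:
        correct.append(cdo_correct(pred, ref, t=t, matching=matching))
        ndos.append(ndo(pred, ref))
        omat = _overlap_matrix(pred, ref)
        ref_sizes = np.array([d.size for d in ref.domains], dtype=float)
        overlaps.append(
            [
                float(omat[i, j] / ref_sizes[j])
                for i, j in match_domains(pred, ref, method=matching)
            ]
        )
    mcc, prec, acc = classification_metrics(pairs)
    return EvalResult(
        target_ids=target_ids,
        correct=correct,
        ndo_scores=ndos,
        overlap_per_domain=overlaps,
        threshold=t,
        mcc=mcc,
        precision=prec,
        accuracy=acc,
        sweep=cdo_sweep(pairs, matching=matching) if sweep else None,
    )
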