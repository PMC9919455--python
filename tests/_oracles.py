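"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's prefix-sum/vectorized code paths:
scores are accumulated by explicit double loops over residue pairs, and the
split oracles enumerate every candidate cut exhaustively.
"""

from __future__ import annotations

import numpy as np

from domaincut.fragments import DomainAssignment, Fragment
from domaincut.params import ScoringParams


def brute_dis_inter(f1: Fragment, f2: Fragment, p: np.ndarray,
                    params: ScoringParams) -> float:
    total = 0.0
    for i in f1.indices():
        for j in f2.indices():
            total += p[i - 1, j - 1]
    return total / (f1.size**params.alpha * f2.size**params.alpha)


def brute_dis_intra(frag: Fragment, p: np.ndarray,
                    params: ScoringParams) -> float:
    idx = frag.indices()
    total = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if idx[b] - idx[a] > 2:
                total += p[idx[a] - 1, idx[b] - 1]
    if params.pair_counting == "twice":
        total *= 2.0
    return total / frag.size**params.beta


def _cut_ok(ss: str, k: int) -> bool:
    """Cut after residue k: both flanks outside H/E."""
    return ss[k - 1] not in "HE" and ss[k] not in "HE"


def scan_continuous(frag: Fragment, p: np.ndarray, ss: str,
                    params: ScoringParams):
    """Exhaustive scan over all single-cut splits; (k, children, score)."""
    idx = frag.indices()
    best = None
    for m in range(len(idx) - 1):
        if idx[m + 1] != idx[m] + 1 or not _cut_ok(ss, int(idx[m])):
            continue
        if m + 1 < params.min_fragment or len(idx) - m - 1 < params.min_fragment:
            continue
        c1 = Fragment.from_indices(idx[: m + 1])
        c2 = Fragment.from_indices(idx[m + 1:])
        score = float(p[np.ix_(c1.indices0(), c2.indices0())].sum()
                      / (c1.size**params.alpha * c2.size**params.alpha))
        if best is None or score < best[2] - 1e-12:
            best = (int(idx[m]), (c1, c2), score)
    return best


def scan_discontinuous(frag: Fragment, p: np.ndarray, d: np.ndarray, ss: str,
                       params: ScoringParams):
    """Exhaustive O(L^2) scan over two-cut excisions; ((t, s), children, score)."""
    if not frag.is_continuous:
        return None
    a, b = frag.segments[0]
    best = None
    for t in range(a, b):
        if not _cut_ok(ss, t):
            continue
        for s in range(t + params.min_loop_sep + 1, b):
            if not _cut_ok(ss, s):
                continue
            mid = s - t
            if mid < params.min_fragment or (b - a + 1) - mid < params.min_fragment:
                continue
            if d[t - 1, s - 1] >= params.max_spatial_gap:
                continue
            outer = Fragment(((a, t), (s + 1, b)))
            middle = Fragment.continuous(t + 1, s)
            score = float(p[np.ix_(outer.indices0(), middle.indices0())].sum()
                          / (outer.size**params.alpha * middle.size**params.alpha))
            if best is None or score < best[2] - 1e-12:
                best = ((t, s), (outer, middle), score)
    return best


def ndo_oracle(pred: DomainAssignment, ref: DomainAssignment) -> float:
    """Normalized domain overlap computed by explicit counting."""
    lp, lr = pred.labels(), ref.labels()
    overlap = np.zeros((pred.n_domains, ref.n_domains))
    for i in range(pred.length):
        if lp[i] >= 0 and lr[i] >= 0:
            overlap[lp[i], lr[i]] += 1
    score = sum(overlap[i].max() for i in range(pred.n_domains))
    score += sum(overlap[:, j].max() for j in range(ref.n_domains))
    return score / ((lp >= 0).sum() + (lr >= 0).sum())


def random_contact_map(length: int, rng: np.random.Generator,
                       band: bool = True) -> np.ndarray:
    """Symmetric random map in (0, 1), optional backbone-like band."""
    p = rng.uniform(0.005, 0.995, size=(length, length))
    p = np.triu(p, 1)
    p = p + p.T
    if band:
        mask = np.abs(np.subtract.outer(range(length), range(length))) <= 2
        p[mask] = 0.97
    np.fill_diagonal(p, 0.5)
    return p
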