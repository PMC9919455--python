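"""Domain interaction scores.

The decomposition is driven by two normalized sums of contact probabilities:

* the inter-fragment score between disjoint fragments D1 and D2,

      DIS_inter(D1, D2) = (1 / (l1^α · l2^α)) · Σ_{i∈D1} Σ_{j∈D2} p_ij,

  with each cross pair counted once (the sets are disjoint);

* the intra-fragment score of a fragment D of size l,

      DIS_intra(D) = (1 / l^β) · Σ_{i,j∈D, |i−j|>2} p_ij,

  excluding near-diagonal pairs, which are contacts of the covalent backbone
  rather than of the fold.  By default the double sum is read as unordered
  pairs counted once (i<j); set ``ScoringParams.pair_counting="twice"`` for
  the ordered-pair reading (exactly double).

The merge criterion combines the two:

      S(i, j) = DIS_inter(Di, Dj) − min{DIS_intra(Di), DIS_intra(Dj)},

positive when two fragments interact more strongly with each other than the
looser of the two coheres internally — i.e. when they belong to one domain.

Separation |i−j| is always measured in sequence positions of the full chain,
not in a fragment's internal order, so a discontinuous fragment excludes only
genuinely backbone-adjacent pairs.
"""

from __future__ import annotations

import numpy as np

from .distmat import ContactMap
from .fragments import Fragment
from .params import ScoringParams

MIN_INTRA_SEPARATION = 2  # pairs with |i-j| <= 2 are backbone, not fold, contacts


def dis_inter(
    f1: Fragment, f2: Fragment, cmap: ContactMap, params: ScoringParams | None = None
) -> float:
    """Inter-fragment interaction score between disjoint fragments."""
    params = params or ScoringParams()
    if f1.overlaps(f2):
        raise ValueError("fragments overlap")
    i1, i2 = f1.indices0(), f2.indices0()
    total = cmap.p[np.ix_(i1, i2)].sum()
    return float(total / (f1.size**params.alpha * f2.size**params.alpha))


def dis_intra(
    frag: Fragment, cmap: ContactMap, params: ScoringParams | None = None
) -> float:
    """Intra-fragment interaction score, excluding |i−j| ≤ 2 pairs."""
    params = params or ScoringParams()
    idx = frag.indices0()
    sub = cmap.p[np.ix_(idx, idx)]
    sep = np.abs(idx[:, None] - idx[None, :])
    mask = np.triu(sep > MIN_INTRA_SEPARATION)
    total = sub[mask].sum()
    if params.pair_counting == "twice":
        total *= 2.0
    return float(total / frag.size**params.beta)


def merge_score(
    fi: Fragment, fj: Fragment, cmap: ContactMap, params: ScoringParams | None = None
) -> float:
    """Merge criterion S(i,j); positive ⇒ the pair behaves like one domain."""
    params = params or ScoringParams()
    return dis_inter(fi, fj, cmap, params) - min(
        dis_intra(fi, cmap, params), dis_intra(fj, cmap, params)
    )
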