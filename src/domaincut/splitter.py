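"""Top-down splitting.

Starting from the whole chain as a single continuous fragment, each fragment
is recursively offered two kinds of split and keeps the one whose children
interact least:

* a **continuous split** cuts after one position k, giving two continuous
  children (for an already-discontinuous parent the cut is placed at an
  intra-segment position of its concatenated order);
* a **discontinuous split** cuts a continuous parent after two positions
  t < s, excising the middle ``t+1..s`` as a continuous child and leaving the
  two flanks as one discontinuous child — the inserted-domain case.

Hard constraints on every candidate cut:

* both residues flanking a cut lie outside regular secondary-structure
  elements (H/E), so no helix or strand is ever bisected;
* each child has at least ``min_fragment`` residues;
* for a discontinuous split, the cut points are more than ``min_loop_sep``
  apart in sequence but closer than ``max_spatial_gap`` Å in space (an
  insertion's entry and exit sites are necessarily adjacent in 3D).

A winning split is accepted only when its inter-child score is below
``oversplit_factor`` times the parent's intra score; otherwise the fragment
is final.  Ties are broken toward the smallest cut position, making the
decomposition deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distmat import ContactMap, DistanceMatrix
from .fragments import Fragment
from .params import ScoringParams
from .scoring import dis_intra

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SplitCandidate:
    kind: str  # "continuous" | "discontinuous"
    cuts: tuple[int, ...]  # (k,) or (t, s), residue indices (cut after)
    children: tuple[Fragment, Fragment]
    score: float  # DIS_inter of the children


def _order_cuts(
    frag: Fragment, ss: str, params: ScoringParams, enforce_min: bool
) -> np.ndarray:
    """Valid cut positions as 0-based indices into the fragment's order.

    A cut after order position m requires the two flanking residues to be
    sequence-adjacent (same segment) and both outside H/E; with
    ``enforce_min``, both children of the continuous split must reach
    ``min_fragment`` residues.
    """
    idx = frag.indices()  # 1-based
    f = idx.size
    if f < 2:
        return np.empty(0, dtype=int)
    adjacent = idx[1:] == idx[:-1] + 1
    ssa = np.frombuffer(ss.encode(), dtype="S1")
    loop = ~np.isin(ssa, [b"H", b"E"])
    ok = adjacent & loop[idx[:-1] - 1] & loop[idx[1:] - 1]
    ms = np.nonzero(ok)[0]
    if enforce_min:
        ms = ms[(ms + 1 >= params.min_fragment) & (f - ms - 1 >= params.min_fragment)]
    return ms


def valid_cut_positions(
    frag: Fragment, ss: str, params: ScoringParams | None = None
) -> list[int]:
    """Residue indices k such that a continuous cut after k is legal."""
    params = params or ScoringParams()
    idx = frag.indices()
    return [int(idx[m]) for m in _order_cuts(frag, ss, params, enforce_min=True)]


def _pick_tied_min(scores: np.ndarray) -> int:
    """Index of the minimum score; near-ties resolve to the earliest entry."""
    smin = scores.min()
    tol = _TIE_TOL * (1.0 + abs(smin))
    return int(np.nonzero(scores <= smin + tol)[0][0])


def best_continuous_split(
    frag: Fragment,
    cmap: ContactMap,
    ss: str,
    params: ScoringParams | None = None,
) -> SplitCandidate | None:
    """Minimize DIS_inter over single-cut splits; None when no cut is legal."""
    params = params or ScoringParams()
    if frag.size < 2 * params.min_fragment:
        return None
    ms = _order_cuts(frag, ss, params, enforce_min=True)
    if ms.size == 0:
        return None
    idx0 = frag.indices0()
    f = idx0.size
    upper = np.triu(cmap.p[np.ix_(idx0, idx0)], 1)
    total = upper.sum()
    # prefix[m]: pair sum inside the first m+1 order positions;
    # suffix[m]: pair sum inside order positions m..f-1
    prefix = np.cumsum(upper.sum(axis=0))
    suffix = np.concatenate((np.cumsum(upper.sum(axis=1)[::-1])[::-1], [0.0]))
    cross = total - prefix[ms] - suffix[ms + 1]
    l1 = (ms + 1).astype(float)
    l2 = f - l1
    scores = cross / (l1**params.alpha * l2**params.alpha)
    j = _pick_tied_min(scores)  # ms ascending <=> cut residue ascending
    m = int(ms[j])
    children = (
        Fragment.from_indices(idx0[: m + 1] + 1),
        Fragment.from_indices(idx0[m + 1:] + 1),
    )
    return SplitCandidate(
        kind="continuous",
        cuts=(int(idx0[m] + 1),),
        children=children,
        score=float(scores[j]),
    )


def best_discontinuous_split(
    frag: Fragment,
    cmap: ContactMap,
    dmat: DistanceMatrix,
    ss: str,
    params: ScoringParams | None = None,
) -> SplitCandidate | None:
    """Minimize DIS_inter over two-cut excisions of a continuous parent.

    Cutting after t and after s (t < s) excises the continuous middle
    ``t+1..s`` and leaves the flanks ``..t`` and ``s+1..`` as one
    discontinuous child.  Only continuous parents are considered; nested
    discontinuity is not attempted.
    """
    params = params or ScoringParams()
    if not frag.is_continuous:
        return None
    a, b = frag.segments[0]
    l = b - a + 1
    mid_min = max(params.min_fragment, params.min_loop_sep + 1)
    if l < mid_min + params.min_fragment:
        return None
    cuts = _order_cuts(frag, ss, params, enforce_min=False)
    # Exclude the last position: cutting after b-? keeps the C-flank nonempty
    cuts = cuts[cuts <= l - 2]
    if cuts.size < 2:
        return None

    sub = cmap.p[a - 1 : b, a - 1 : b]
    col_tot = np.concatenate(([0.0], np.cumsum(sub.sum(axis=0))))
    integral = np.zeros((l + 1, l + 1))
    integral[1:, 1:] = sub.cumsum(axis=0).cumsum(axis=1)

    p, q = np.meshgrid(cuts, cuts, indexing="ij")  # cut after local p and q
    mid = q - p
    valid = (
        (mid > params.min_loop_sep)
        & (mid >= params.min_fragment)
        & (l - mid >= params.min_fragment)
    )
    t_res = a + p  # residue index of first cut (cut after t_res)
    s_res = a + q
    valid &= dmat.d[t_res - 1, s_res - 1] < params.max_spatial_gap
    if not valid.any():
        return None

    pi, qi = np.nonzero(valid)
    pv, qv = cuts[pi], cuts[qi]
    # column sums over the middle minus the middle's own block = cross pairs,
    # each counted once (outer rows x middle columns)
    col_mid = col_tot[qv + 1] - col_tot[pv + 1]
    block = (
        integral[qv + 1, qv + 1]
        - integral[pv + 1, qv + 1]
        - integral[qv + 1, pv + 1]
        + integral[pv + 1, pv + 1]
    )
    cross = col_mid - block
    l2 = (qv - pv).astype(float)  # middle (continuous child)
    l1 = l - l2  # flanks (discontinuous child)
    scores = cross / (l1**params.alpha * l2**params.alpha)

    # lexicographic (t, s) tie-break
    order = np.lexsort((qv, pv))
    scores, pv, qv = scores[order], pv[order], qv[order]
    j = _pick_tied_min(scores)
    t, s = int(a + pv[j]), int(a + qv[j])
    outer = Fragment(((a, t), (s + 1, b)))
    middle = Fragment.continuous(t + 1, s)
    return SplitCandidate(
        kind="discontinuous",
        cuts=(t, s),
        children=(outer, middle),
        score=float(scores[j]),
    )


def try_split(
    frag: Fragment,
    cmap: ContactMap,
    dmat: DistanceMatrix,
    ss: str,
    params: ScoringParams | None = None,
) -> SplitCandidate | None:
    """Best split of either kind, subject to the over-split guard.

    The global minimizer over both kinds is selected first; it is accepted
    only when its score is below ``oversplit_factor`` × DIS_intra(parent).
    Ties between kinds resolve to the continuous split.
    """
    params = params or ScoringParams()
    cont = best_continuous_split(frag, cmap, ss, params)
    disc = best_discontinuous_split(frag, cmap, dmat, ss, params)
    if cont is None and disc is None:
        return None
    if cont is None:
        best = disc
    elif disc is None:
        best = cont
    else:
        best = disc if disc.score < cont.score - _TIE_TOL else cont
    if best.score < params.oversplit_factor * dis_intra(frag, cmap, params):
        return best
    return None


def top_down(
    length: int,
    cmap: ContactMap,
    dmat: DistanceMatrix,
    ss: str,
    params: ScoringParams | None = None,
) -> list[Fragment]:
    """Recursively split ``1..length`` until no fragment accepts a split.

    Fragments are processed largest-first; the result is independent of the
    order because each fragment's split decision depends only on itself.
    Returns final fragments ordered by first residue; they partition 1..L.
    """
    params = params or ScoringParams()
    if not (cmap.length == dmat.length == len(ss) == length):
        raise ValueError("contact map, distance matrix and SS length mismatch")
    work = [Fragment.continuous(1, length)]
    final: list[Fragment] = []
    while work:
        work.sort(key=lambda f: f.size)
        frag = work.pop()
        cand = try_split(frag, cmap, dmat, ss, params)
        if cand is None:
            final.append(frag)
        else:
            work.extend(cand.children)
    return sorted(final, key=lambda f: f.start)
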