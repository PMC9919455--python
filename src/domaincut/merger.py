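"""Bottom-up merging and the full two-stage parse.

Top-down splitting minimizes the interaction between the two children of
each individual split, but not among fragments produced in different steps;
fragments of one domain can end up separated.  The bottom-up stage repairs
this: at each iteration the fragment pair maximizing

    S(i, j) = DIS_inter(Di, Dj) − min{DIS_intra(Di), DIS_intra(Dj)}

is merged while S is positive — i.e. while some pair interacts more strongly
across than the looser member coheres internally.

A post-processing pass then absorbs fragments with weak internal contact
(DIS_intra below ``weak_intra``) into whichever remaining fragment interacts
with them most strongly, iterating to a fixed point, weakest fragment first.

:func:`parse_domains` chains the three stages and numbers the resulting
domains by first residue.
"""

from __future__ import annotations

import numpy as np

from .distmat import ContactMap, DistanceMatrix
from .fragments import DomainAssignment, Fragment
from .params import ScoringParams
from .scoring import dis_inter, dis_intra
from .splitter import top_down


def _check_partition(fragments: list[Fragment]) -> int:
    idx = np.concatenate([f.indices() for f in fragments])
    length = idx.max()
    expected = np.arange(1, length + 1)
    if idx.size != length or not np.array_equal(np.sort(idx), expected):
        raise ValueError("fragments do not partition 1..L")
    return int(length)


def bottom_up(
    fragments: list[Fragment],
    cmap: ContactMap,
    params: ScoringParams | None = None,
) -> list[Fragment]:
    """Greedily merge the pair maximizing S while S > 0.

    Pair scores are recomputed after every merge; ties resolve to the
    smallest pair of fragment positions in first-residue order.  Terminates
    in at most n−1 merges.
    """
    params = params or ScoringParams()
    _check_partition(fragments)
    frags = sorted(fragments, key=lambda f: f.start)
    while len(frags) > 1:
        intra = [dis_intra(f, cmap, params) for f in frags]
        best_score = -np.inf
        best_pair: tuple[int, int] | None = None
        for i in range(len(frags)):
            for j in range(i + 1, len(frags)):
                s = dis_inter(frags[i], frags[j], cmap, params) - min(
                    intra[i], intra[j]
                )
                if s > best_score + 1e-12:
                    best_score, best_pair = s, (i, j)
        if best_pair is None or best_score <= 0:
            break
        i, j = best_pair
        merged = frags[i].union(frags[j])
        frags = [f for k, f in enumerate(frags) if k not in (i, j)]
        frags.append(merged)
        frags.sort(key=lambda f: f.start)
    return frags


def post_process(
    fragments: list[Fragment],
    cmap: ContactMap,
    params: ScoringParams | None = None,
) -> list[Fragment]:
    """Absorb weakly-connected fragments into their strongest partner.

    While any fragment has DIS_intra below ``weak_intra`` and at least two
    fragments remain, the weakest such fragment is merged with the fragment
    it interacts with most strongly (highest DIS_inter).  Iterates to a
    fixed point; a single remaining fragment is returned as-is.
    """
    params = params or ScoringParams()
    frags = sorted(fragments, key=lambda f: f.start)
    while len(frags) > 1:
        intra = np.array([dis_intra(f, cmap, params) for f in frags])
        weak = np.nonzero(intra < params.weak_intra)[0]
        if weak.size == 0:
            break
        w = int(weak[np.argmin(intra[weak])])
        inter = [
            dis_inter(frags[w], f, cmap, params) if k != w else -np.inf
            for k, f in enumerate(frags)
        ]
        partner = int(np.argmax(inter))
        merged = frags[w].union(frags[partner])
        frags = [f for k, f in enumerate(frags) if k not in (w, partner)]
        frags.append(merged)
        frags.sort(key=lambda f: f.start)
    return frags


def parse_domains(
    cmap: ContactMap,
    dmat: DistanceMatrix,
    ss: str,
    params: ScoringParams | None = None,
    index_to_author: dict[int, str] | None = None,
) -> DomainAssignment:
    """Full parse: top-down split, bottom-up merge, weak-fragment cleanup."""
    params = params or ScoringParams()
    length = cmap.length
    if not (dmat.length == length == len(ss)):
        raise ValueError("contact map, distance matrix and SS length mismatch")
    fragments = top_down(length, cmap, dmat, ss, params)
    fragments = bottom_up(fragments, cmap, params)
    fragments = post_process(fragments, cmap, params)
    assignment = DomainAssignment(
        domains=fragments, length=length, index_to_author=index_to_author
    )
    assignment.validate()
    return assignment
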