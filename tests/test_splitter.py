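"""Top-down splitting: cut constraints, oracle equivalence, recursion."""

from __future__ import annotations

import numpy as np
import pytest

from domaincut.fragments import Fragment
from domaincut.params import ScoringParams
from domaincut.splitter import (
    best_continuous_split,
    best_discontinuous_split,
    top_down,
    try_split,
    valid_cut_positions,
)
from domaincut.synthetic import SyntheticSpec, make_block_contact_map

from _oracles import random_contact_map, scan_continuous, scan_discontinuous
from conftest import as_cmap, dist_from_p


def _random_instance(seed, length=None, band=True):
    rng = np.random.default_rng(seed)
    if length is None:
        length = int(rng.integers(62, 81))
    p = random_contact_map(length, rng, band=band)
    return p, as_cmap(p), dist_from_p(p), length


class TestValidCutPositions:
    def test_all_coil_80mer(self, params):
        frag = Fragment.continuous(1, 80)
        cuts = valid_cut_positions(frag, "C" * 80, params)
        assert cuts == list(range(30, 51))  # both children >= 30

    def test_all_helix_has_none(self, params):
        frag = Fragment.continuous(1, 80)
        assert valid_cut_positions(frag, "H" * 80, params) == []

    def test_59mer_too_short(self, params):
        frag = Fragment.continuous(1, 59)
        assert valid_cut_positions(frag, "C" * 59, params) == []

    def test_cut_needs_both_flanks_outside_sse(self, params):
        # helix covering residues 36..44 removes cuts 35..44
        ss = list("C" * 80)
        ss[35:44] = "H" * 9
        cuts = valid_cut_positions(Fragment.continuous(1, 80), "".join(ss), params)
        assert cuts == [30, 31, 32, 33, 34] + list(range(45, 51))

    def test_segment_boundary_is_not_cuttable(self, params):
        # discontinuous fragment: order-adjacent but not sequence-adjacent
        frag = Fragment(((1, 40), (61, 100)))
        cuts = valid_cut_positions(frag, "C" * 100, params)
        assert 40 not in cuts
        assert cuts == list(range(30, 40)) + list(range(61, 71))


class TestBestContinuousSplit:
    def test_two_block_map_cuts_at_boundary(self, params):
        spec = SyntheticSpec((40, 40), seed=11)
        cmap, _, _ = make_block_contact_map(spec)
        cand = best_continuous_split(Fragment.continuous(1, 80), cmap,
                                     "C" * 80, params)
        assert cand is not None and cand.cuts == (40,)
        assert cand.children[0].segments == ((1, 40),)

    def test_constant_map_prefers_balanced_cut(self, params):
        p = np.full((100, 100), 0.3)
        np.fill_diagonal(p, 0.3)
        cand = best_continuous_split(Fragment.continuous(1, 100), as_cmap(p),
                                     "C" * 100, params)
        # q*l1*l2/(l1*l2)^alpha is minimized where l1*l2 is smallest... the
        # exponent 1-alpha > 0 makes the product grow with balance, so the
        # minimizer is the most *unbalanced* allowed cut; ties at the two
        # extremes resolve to the smallest k
        assert cand.cuts == (30,)

    def test_no_valid_positions_returns_none(self, params):
        p = np.full((80, 80), 0.5)
        assert best_continuous_split(Fragment.continuous(1, 80), as_cmap(p),
                                     "H" * 80, params) is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_scan(self, params, seed):
        p, cmap, _, length = _random_instance(seed)
        frag = Fragment.continuous(1, length)
        cand = best_continuous_split(frag, cmap, "C" * length, params)
        want = scan_continuous(frag, p, "C" * length, params)
        assert (cand is None) == (want is None)
        if cand is not None:
            assert cand.score == pytest.approx(want[2], abs=1e-9)
            if _unique_min_continuous(frag, p, "C" * length, params, want[2]):
                assert cand.cuts == (want[0],)


def _unique_min_continuous(frag, p, ss, params, best, margin=1e-6):
    """True when the exhaustive scan's optimum is unique by a clear margin."""
    scores = []
    idx = frag.indices()
    for m in range(len(idx) - 1):
        if m + 1 < params.min_fragment or len(idx) - m - 1 < params.min_fragment:
            continue
        c1 = Fragment.from_indices(idx[:m + 1])
        c2 = Fragment.from_indices(idx[m + 1:])
        scores.append(p[np.ix_(c1.indices0(), c2.indices0())].sum()
                      / (c1.size**params.alpha * c2.size**params.alpha))
    scores = np.sort(np.asarray(scores))
    return len(scores) < 2 or scores[1] - scores[0] > margin


class TestBestDiscontinuousSplit:
    def _inserted(self, seed=21, junction_d=None):
        spec = SyntheticSpec((70, 70), architecture="inserted", seed=seed)
        cmap, dmat, truth = make_block_contact_map(spec)
        if junction_d is not None:
            d = dmat.d.copy()
            # push all host-seg1 x insert distances beyond the gate
            d[:36, 36:106] = np.maximum(d[:36, 36:106], junction_d)
            d[36:106, :36] = d[:36, 36:106].T
            dmat = type(dmat)(d=d, source=dmat.source)
        return cmap, dmat, truth

    def test_inserted_domain_fixture(self, params):
        cmap, dmat, _ = self._inserted()
        cand = best_discontinuous_split(Fragment.continuous(1, 140), cmap, dmat,
                                        "C" * 140, params)
        assert cand is not None
        assert cand.cuts == (35, 105)
        assert cand.children[0].segments == ((1, 35), (106, 140))
        assert cand.children[1].segments == ((36, 105),)

    def test_spatial_gate_vetoes_distant_cuts(self, params):
        cmap, dmat, _ = self._inserted(junction_d=12.0)
        cand = best_discontinuous_split(Fragment.continuous(1, 140), cmap, dmat,
                                        "C" * 140, params)
        # every candidate pair straddles host and insert, all now >= 8 A apart
        assert cand is None or dmat.d[cand.cuts[0] - 1, cand.cuts[1] - 1] < 8.0

    def test_size_60_infeasible(self, params):
        p = np.full((60, 60), 0.4)
        cand = best_discontinuous_split(Fragment.continuous(1, 60), as_cmap(p),
                                        dist_from_p(p), "C" * 60, params)
        assert cand is None

    def test_discontinuous_parent_not_attempted(self, params):
        p = np.full((150, 150), 0.4)
        frag = Fragment(((1, 70), (81, 150)))
        cand = best_discontinuous_split(frag, as_cmap(p), dist_from_p(p),
                                        "C" * 150, params)
        assert cand is None

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_scan(self, params, seed):
        # widen the gate so random maps admit candidates
        loose = params.replace(max_spatial_gap=30.0)
        p, cmap, dmat, length = _random_instance(1000 + seed, length=80)
        frag = Fragment.continuous(1, 80)
        cand = best_discontinuous_split(frag, cmap, dmat, "C" * 80, loose)
        want = scan_discontinuous(frag, p, dmat.d, "C" * 80, loose)
        assert (cand is None) == (want is None)
        if cand is not None:
            assert cand.score == pytest.approx(want[2], abs=1e-9)


class TestTrySplit:
    def test_uniform_block_guard_rejects(self, params):
        p = np.full((80, 80), 0.8)
        cand = try_split(Fragment.continuous(1, 80), as_cmap(p),
                         dist_from_p(p), "C" * 80, params)
        assert cand is None

    def test_two_block_map_accepted_continuous(self, params):
        cmap, dmat, _ = make_block_contact_map(SyntheticSpec((40, 40), seed=31))
        cand = try_split(Fragment.continuous(1, 80), cmap, dmat, "C" * 80, params)
        assert cand is not None and cand.kind == "continuous"
        assert cand.cuts == (40,)

    def test_both_candidates_none(self, params):
        p = np.full((40, 40), 0.5)
        cand = try_split(Fragment.continuous(1, 40), as_cmap(p),
                         dist_from_p(p), "C" * 40, params)
        assert cand is None


class TestTopDown:
    def test_three_block_map(self, params):
        cmap, dmat, _ = make_block_contact_map(SyntheticSpec((40, 40, 40), seed=41))
        frags = top_down(120, cmap, dmat, "C" * 120, params)
        assert [f.segments for f in frags] == [((1, 40),), ((41, 80),),
                                               ((81, 120),)]

    def test_uniform_single_domain(self, params):
        p = np.full((80, 80), 0.8)
        frags = top_down(80, as_cmap(p), dist_from_p(p), "C" * 80, params)
        assert len(frags) == 1

    def test_short_chain_single_fragment(self, params):
        p = np.full((25, 25), 0.5)
        frags = top_down(25, as_cmap(p), dist_from_p(p), "C" * 25, params)
        assert len(frags) == 1 and frags[0].size == 25

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_size_invariants(self, params, seed):
        p, cmap, dmat, length = _random_instance(2000 + seed)
        frags = top_down(length, cmap, dmat, "C" * length, params)
        idx = np.sort(np.concatenate([f.indices() for f in frags]))
        assert np.array_equal(idx, np.arange(1, length + 1))
        if len(frags) > 1:
            assert min(f.size for f in frags) >= params.min_fragment

    def test_no_cut_inside_sse(self, params):
        rng = np.random.default_rng(7)
        length = 120
        p = random_contact_map(length, rng)
        ss = "".join(rng.choice(list("HEC"), size=length, p=[0.3, 0.2, 0.5]))
        frags = top_down(length, as_cmap(p), dist_from_p(p), ss, params)
        # every boundary between adjacent residues of different fragments
        # must be flanked by non-H/E residues on both sides
        lab = np.zeros(length, dtype=int)
        for k, f in enumerate(frags):
            lab[f.indices0()] = k
        for i in range(length - 1):
            if lab[i] != lab[i + 1]:
                assert ss[i] not in "HE" and ss[i + 1] not in "HE"

    def test_determinism(self, params):
        p, cmap, dmat, length = _random_instance(4242)
        a = top_down(length, cmap, dmat, "C" * length, params)
        b = top_down(length, cmap, dmat, "C" * length, params)
        assert [f.segments for f in a] == [f.segments for f in b]
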