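# Methods

## The parsing model

A protein domain, seen through an inter-residue distance matrix, is a set
of residues that contact each other much more than they contact the rest of
the chain. `domaincut` operationalizes this with a contact probability
`p_ij = 1/(1 + exp((d_ij − d0)/δ))` on the representative-atom distance
matrix (Cβ, Cα for glycine) and two normalized interaction scores:
`DIS_inter` between two disjoint fragments, normalized by `l1^α l2^α`, and
`DIS_intra` within a fragment, normalized by `l^β`, with near-diagonal
pairs (|i−j| ≤ 2) excluded as covalent-backbone rather than fold contacts.
Sequence separation is always measured in chain numbering, so a
discontinuous fragment excludes only genuinely backbone-adjacent pairs.

The parse is a top-down/bottom-up pair. Top-down, each fragment is split at
the cut (single cut, or a two-cut excision producing one discontinuous
child) minimizing `DIS_inter` between the children, subject to hard
constraints listed below; the winning split must additionally pass the
over-split guard `DIS_inter < oversplit_factor × DIS_intra(parent)`.
Bottom-up, the fragment pair maximizing
`S(i,j) = DIS_inter − min(DIS_intra)` is merged while `S > 0`, repairing
the top-down stage's inability to see interactions across split steps;
finally, fragments with `DIS_intra < weak_intra` are absorbed into their
strongest `DIS_inter` partner, weakest first, iterating to a fixed point
(a cascade — a merge creating a new weak fragment — is therefore handled).

Because both input routes (structure → distances, predictor → distances)
meet at the same matrix, structure-based and sequence-based parsing are the
same computation; the tests assert bit-identical parses between a structure
and its exported matrix.

## Parameters

All constants live in `ScoringParams`:

| name | default | unit | role |
|---|---|---|---|
| `d0` | 8.0 | Å | logistic midpoint: p(d0) = 0.5 |
| `delta` | 1.5 | Å | logistic softness |
| `alpha` | 0.43 | – | inter-score size normalization |
| `beta` | 0.95 | – | intra-score size normalization |
| `min_fragment` | 30 | residues | minimum child size of any split |
| `min_loop_sep` | 35 | residues | minimum sequence gap (exclusive) between the two cuts of an excision |
| `max_spatial_gap` | 8.0 | Å | the two excision cut sites must be this close in 3D |
| `oversplit_factor` | 0.5 | – | split accepted iff inter < factor × parent intra |
| `weak_intra` | 1.0 | – | post-processing absorption threshold |
| `pair_counting` | `"once"` | – | intra double-sum read as unordered pairs once; `"twice"` doubles it |

`min_fragment` is enforced as ≥ 30 on every child ("longer than 30" read
inclusively; configurable). The intra pair-counting convention is exposed
because the double-sum notation admits both readings and the absolute
threshold `weak_intra` is convention-dependent; the relative over-split
guard is unaffected as long as one convention is used throughout, which
this implementation guarantees.

## Numerical and algorithmic choices

* **Cut semantics.** A cut sits "after residue k" and is legal only when
  residues k and k+1 are sequence-adjacent, in the same segment, and both
  outside H/E. This forbids bisecting a secondary-structure element while
  permitting cuts in loops immediately flanking one. 3-10 helices (DSSP/
  STRIDE code G) reduce to H and are therefore cut-forbidden.
* **Tie-breaking.** Equal-scoring cuts (within 1e-12, relative) resolve to
  the smallest k, or lexicographically smallest (t, s); equal-scoring merge
  pairs to the smallest pair in first-residue order. The parse is fully
  deterministic.
* **Split selection vs guard order.** The global minimizer over both split
  kinds is chosen first; the over-split guard is applied to that single
  candidate, not per kind.
* **Discontinuous nesting.** Two-cut excisions are attempted only on
  continuous parents. A discontinuous fragment can still be subdivided by
  continuous cuts at intra-segment positions of its concatenated order;
  nesting discontinuity inside a discontinuous parent is not attempted.
* **Efficiency.** The continuous-cut scan uses prefix sums of the
  fragment-ordered contact submatrix (O(f²) for all cuts); the two-cut scan
  uses a 2D integral image (O(1) per candidate pair after O(l²) setup).
  The tests verify both against exhaustive brute-force scans. Bottom-up
  pair scores are recomputed after every merge — with ≤ L/30 fragments this
  is never the bottleneck and avoids cache-invalidation subtleties.
* **Degenerate inputs.** Chains shorter than `2·min_fragment` are returned
  as a single domain; fragments of ≤ 3 residues have `DIS_intra = 0` (empty
  eligible-pair set); the logistic transform is clipped away from exact 0/1
  at float saturation. Matrix input must be square, finite and symmetric to
  0.5 Å (then symmetrized as (M+Mᵀ)/2).
* **Structure input.** One chain per run, first model by default, first
  altloc conformer kept. Non-glycine residues missing Cβ fall back to Cα
  with a warning (keeps L stable on imperfect files); residues with neither
  atom are dropped with a warning. Residues are renumbered densely 1..L;
  the author numbering is retained for output.

## Evaluation metrics

CDO judges a target correct iff predicted and reference domain counts match
and, under the maximum-weight one-to-one matching of domains (Hungarian
algorithm on shared-residue counts; a greedy matcher is available), every
matched pair overlaps the reference domain by more than t (default 0.85,
sweepable). The overlap denominator is the reference domain size. NDO is
the normalized domain overlap: with O the pred×ref shared-residue matrix,
`NDO = (Σ row maxima + Σ column maxima) / 2L`, which is 1 exactly when the
partitions coincide and degrades smoothly with boundary displacement; the
per-target mean is reported (a dataset-level normalization would weight
targets by length). MCC/precision/accuracy summarize the single- vs
multi-domain call with multi as the positive class and MCC defined as 0
when a confusion margin vanishes.

## What the synthetic generator emulates — and what it does not

The generator produces what the algorithm actually consumes: block contact
maps (within-domain density around `p_in` = 0.9, cross-domain around
`p_out` = 0.01, backbone band |i−j| ≤ 2 near 1), with distances recovered
by inverting the logistic transform so scoring and the spatial gate see one
consistent geometry; and toy 3D structures (compact ~3.8 Å-spaced chains
packed in spheres, one per domain, written as valid PDB). For inserted
architectures the map carries a small high-contact patch joining the two
cut sites, reflecting that a real insertion's entry and exit points are
spatially adjacent — precisely the property the 8 Å gate tests for; without
it the gate correctly vetoes the excision.

These fixtures have sharp, noise-controlled block boundaries, no missing
residues, no register errors, and no ambiguous linkers, so passing the
recovery tests demonstrates the algorithm's correctness and determinism,
not its accuracy on real proteins — real distance maps have blurred
boundaries, predicted maps have correlated errors, and real domain
annotations (SCOP/CATH) disagree with each other on a sizeable fraction of
multi-domain proteins. The `perturb_map` helper supports robustness checks
but uncorrelated Gaussian noise is a mild stand-in for predictor error.
Problem sizes used by the tests and the acceptance script — chains of
60–140 residues, 50 seeded targets per architecture, 100 random maps for
the exhaustive-scan comparisons, 20 structures for mode equivalence — were
chosen to exercise every code path with comfortable margins.

## Known limitations

* One decomposition per protein; no enumeration of alternative parses even
  when boundaries are genuinely ambiguous.
* Single chain per run; no multi-chain assemblies, no NMR-model averaging.
* Secondary structure must come from external tools (STRIDE/DSSP/PSIPRED)
  or the constraint is disabled; there is no geometric SS assignment.
* Raw sequence is not accepted: distance prediction is upstream of this
  tool by design.
* The discontinuous search considers one excision at a time, so domains
  with three or more segments can only arise through merges.
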