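# domaincut

Protein domain decomposition from inter-residue distance matrices, for
structural bioinformaticians who need to cut a chain into domains whether
they hold an experimental structure or only a predicted distance map.

Multi-domain proteins must be decomposed into individual domains before
precise domain-level structural and functional analysis. `domaincut`
implements a unified parser driven entirely by the L×L inter-residue
distance matrix **D** — derived from a PDB/mmCIF chain via Cβ atoms (Cα for
glycine), or read from the output of an external distance predictor — so
structure-based and sequence-based parsing share one algorithm. It also
ships the standard evaluation metrics for domain assignments (CDO, NDO,
single/multi-domain MCC) and a synthetic fixture generator with known
ground truth.

## Model

Distances become contact probabilities by a logistic transform

```
p_ij = 1 / (1 + exp((d_ij − d0) / δ)),        d0 = 8.0 Å, δ = 1.5 Å
```

and two normalized interaction scores drive the parse (α = 0.43, β = 0.95):

```
DIS_inter(D1, D2) = (1 / l1^α l2^α) Σ_{i∈D1} Σ_{j∈D2} p_ij
DIS_intra(D)      = (1 / l^β)       Σ_{i,j∈D, |i−j|>2} p_ij
```

**Top-down split.** The chain starts as one fragment. Each fragment is
offered the continuous cut `k = argmin_k DIS_inter(D1^k, D2^k)` and, for
continuous fragments, the discontinuous cut pair
`(t, s) = argmin DIS_inter` subject to `s > t + 35` and `d_ts < 8 Å`, which
excises an inserted domain and leaves a two-segment host. Cuts may not
bisect helices or strands, children must keep ≥ 30 residues, and the
winning split is accepted only if its `DIS_inter` is below half the
parent's `DIS_intra` (over-split guard).

**Bottom-up merge.** While the best fragment pair has positive

```
S(i, j) = DIS_inter(Di, Dj) − min{DIS_intra(Di), DIS_intra(Dj)}
```

it is merged; a final pass absorbs weak fragments (`DIS_intra < 1.0`) into
their strongest-interacting partner. The result is a partition of `1..L`
serialized as a domain string, e.g. `1-35,106-140;36-105` (domains split by
`;`, segments of a discontinuous domain by `,`).

## Worked example

Generate a toy two-domain structure and parse it, from the shell:

```
$ domaincut simulate --kind structure --sizes 35,35 --seed 11 --outdir sim
1-35;36-70
$ domaincut parse-structure --pdb sim/target.pdb --out report.json --export-matrix dist.txt
1-35;36-70
$ domaincut parse-matrix --dist dist.txt     # sequence mode, same matrix
1-35;36-70
```

The first line of each parse is the domain string: two domains, residues
1–35 and 36–70, matching the simulated ground truth; structure mode and
matrix mode agree exactly. The JSON report carries the diagnostics — here
`dis_intra` 4.59 and 7.26 for the two domains against a cross-domain
`dis_inter` of ~0.00, which is why the split was accepted and the merge
declined. Evaluating a prediction against a reference annotation:

```
$ domaincut evaluate --pred pred.tsv --ref ref.tsv --lengths len.tsv
{"n_targets": 1, "threshold": 0.85, "cdo": 1.0, "mean_ndo": 0.9714, ...}
```

Both files are `target-ID <tab> domain-string` TSVs: a prediction
`1-35;36-70` against reference `1-33;34-70` overlaps every reference domain
by more than 85 %, so CDO counts it correct, while NDO (0.97) registers the
two-residue boundary displacement.

The same pipeline is available as a scikit-learn-style estimator:

```python
>>> from domaincut import DomainParser
>>> from domaincut.synthetic import SyntheticSpec, make_block_contact_map
>>> cmap, dmat, truth = make_block_contact_map(SyntheticSpec((40, 40)))
>>> DomainParser().fit(dmat.d).domain_string_
'1-40;41-80'
```

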