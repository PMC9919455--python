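"""Synthetic fixtures with known domain ground truth.

Real benchmark structures are not needed to exercise the parser: a domain,
as far as the algorithm can see, is a dense diagonal block of the contact
map, and an inserted domain is a block that interrupts another.  This module
generates

* **block contact maps** — within-domain entries drawn around a high density
  ``p_in``, cross-domain entries around a low ``p_out``, a near-diagonal
  band close to 1 to mimic backbone adjacency, in sequential or inserted
  architectures, together with the ground-truth assignment;
* **toy structures** — compact 3D clusters of residue-representative points
  with ~3.8 Å consecutive spacing, one cluster per domain, written as a
  syntactically valid single-chain PDB;
* **perturbed maps** — clipped symmetric noise on an existing map, for
  robustness checks of the parse against degraded (predicted-like) input.

For inserted architectures the generated map also carries a small
high-probability patch joining the two cut sites (the end of the host's
N-terminal segment and the end of the insert).  In a real inserted domain
these sites are spatially adjacent — the chain leaves and re-enters the host
at essentially the same place — and the parser's spatial gate relies on it.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distmat import ContactMap, DistanceMatrix, ResidueChain
from .fragments import DomainAssignment, Fragment
from .params import ScoringParams

_BAND_P = 0.98  # backbone-adjacent (|i-j| <= 2) contact probability
_P_EPS = 1e-4  # keep all probabilities strictly inside (0, 1)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic target."""

    domain_sizes: tuple[int, ...] = (40, 40)
    architecture: str = "sequential"  # or "inserted"
    p_in: float = 0.9
    p_out: float = 0.01
    linker_length: int = 0
    ss_pattern: str | None = None
    seed: int = 0
    params: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        if not self.domain_sizes:
            raise ValueError("at least one domain size required")
        if not (0 < self.p_out < self.p_in < 1):
            raise ValueError("need 0 < p_out < p_in < 1")
        if self.architecture not in ("sequential", "inserted"):
            raise ValueError(f"unknown architecture: {self.architecture}")
        if self.architecture == "inserted" and len(self.domain_sizes) != 2:
            raise ValueError("inserted architecture takes exactly two domains")

    @property
    def length(self) -> int:
        return sum(self.domain_sizes)


def _ground_truth(spec: SyntheticSpec) -> DomainAssignment:
    if spec.architecture == "sequential":
        domains, pos = [], 1
        for size in spec.domain_sizes:
            domains.append(Fragment.continuous(pos, pos + size - 1))
            pos += size
    else:  # inserted: host A split around insert B
        a, b = spec.domain_sizes
        half = (a + 1) // 2
        domains = [
            Fragment(((1, half), (half + b + 1, a + b))),
            Fragment.continuous(half + 1, half + b),
        ]
    return DomainAssignment(domains=domains, length=spec.length)


def make_block_contact_map(
    spec: SyntheticSpec,
) -> tuple[ContactMap, DistanceMatrix, DomainAssignment]:
    """Block-structured contact map, consistent distances and ground truth.

    The distance matrix is the exact inverse of the contact transform,
    ``d = d0 + δ·ln(1/p − 1)``, so scoring and the discontinuous split's
    spatial gate see one consistent geometry.
    """
    rng = np.random.default_rng(spec.seed)
    truth = _ground_truth(spec)
    length = spec.length
    labels = truth.labels()

    p = rng.normal(spec.p_out, spec.p_out / 3, size=(length, length))
    same = labels[:, None] == labels[None, :]
    p[same] = rng.normal(spec.p_in, 0.02, size=int(same.sum()))

    if spec.architecture == "inserted":
        # junction patch: the host's exit and the insert's end are close in 3D
        a, b = spec.domain_sizes
        t0, s0 = (a + 1) // 2, (a + 1) // 2 + b  # the two cut sites
        lo_t, hi_t = max(t0 - 2, 1), min(t0 + 1, length)
        lo_s, hi_s = max(s0 - 2, 1), min(s0 + 1, length)
        p[lo_t - 1 : hi_t, lo_s - 1 : hi_s] = spec.p_in

    p = np.triu(p, 1)
    p = p + p.T
    band = np.abs(np.arange(length)[:, None] - np.arange(length)[None, :]) <= 2
    p[band] = _BAND_P
    p = np.clip(p, _P_EPS, 1 - _P_EPS)

    prm = spec.params
    d = prm.d0 + prm.delta * np.log(1.0 / p - 1.0)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    cmap = ContactMap(p=p, params_used=prm)
    dmat = DistanceMatrix(d=d, source="derived")
    return cmap, dmat, truth


# ---------------------------------------------------------------------------
# toy 3D structures

_MAX_ATTEMPTS = 20000


def _packed_cluster(
    n: int, center: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Chain of n points, ~3.8 Å consecutive spacing, confined to a sphere.

    Rejection sampling with a fixed attempt budget; raises rather than
    looping forever on infeasible geometry.
    """
    pts = [center + rng.normal(0, 1, 3) * 0.1]
    attempts = 0
    while len(pts) < n:
        step = rng.normal(0, 1, 3)
        step *= 3.8 / np.linalg.norm(step)
        cand = pts[-1] + step
        attempts += 1
        if attempts > _MAX_ATTEMPTS:
            raise RuntimeError(
                f"cluster packing failed after {_MAX_ATTEMPTS} attempts "
                f"(n={n}, radius={radius})"
            )
        if np.linalg.norm(cand - center) > radius:
            continue
        if len(pts) > 1:
            d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
            if (d < 3.0).any():
                continue
        pts.append(cand)
    return np.asarray(pts)


def _pdb_text(coords: np.ndarray) -> str:
    """Single-chain poly-alanine PDB with CA and CB per residue.

    CB carries the representative coordinate; CA sits 1.5 Å away so the
    record is geometrically plausible.
    """
    lines = []
    serial = 1
    for i, xyz in enumerate(coords, start=1):
        ca = xyz + np.array([1.5, 0.0, 0.0])
        for name, pos in (("CA", ca), ("CB", xyz)):
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{i:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           C"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_two_cluster_structure(
    spec: SyntheticSpec, path: str | Path | None = None
) -> tuple[ResidueChain, str]:
    """Toy structure: one compact cluster per domain along a chain.

    Cluster radius scales with domain size so most intra-domain pairs fall
    within contact range (< d0 + 2δ); consecutive cluster centers sit far
    enough apart (> d0 + 4δ surface gap) that cross-domain contact is
    negligible.  Optional linker residues interpolate between clusters and
    are attributed to the preceding domain.  Returns the chain and the PDB
    text; ``path`` additionally writes the file.
    """
    if spec.architecture != "sequential":
        raise ValueError("structure generator supports sequential architecture only")
    rng = np.random.default_rng(spec.seed)
    prm = spec.params
    coords_parts = []
    center = np.zeros(3)
    prev_end: np.ndarray | None = None
    for size in spec.domain_sizes:
        radius = max(6.0, 2.2 * size ** (1 / 3) + 3.0)
        if prev_end is not None:
            gap = prm.d0 + 4 * prm.delta  # surface-to-surface clearance
            center = center + np.array([prev_radius + radius + gap + 1.0, 0.0, 0.0])
            if spec.linker_length:
                start_hint = center - np.array([radius, 0.0, 0.0])
                steps = np.linspace(0, 1, spec.linker_length + 2)[1:-1]
                coords_parts.append(
                    prev_end[None, :] + steps[:, None] * (start_hint - prev_end)
                )
        cluster = _packed_cluster(size, center, radius, rng)
        coords_parts.append(cluster)
        prev_end = cluster[-1]
        prev_radius = radius
    coords = np.vstack(coords_parts)
    chain = ResidueChain(
        author_ids=[str(i) for i in range(1, len(coords) + 1)],
        residue_names=["ALA"] * len(coords),
        coords=coords,
    )
    text = _pdb_text(coords)
    if path is not None:
        Path(path).write_text(text)
    return chain, text


def structure_ground_truth(spec: SyntheticSpec) -> DomainAssignment:
    """Ground truth for :func:`make_two_cluster_structure` (linker residues
    join the preceding domain)."""
    domains, pos = [], 1
    for k, size in enumerate(spec.domain_sizes):
        extent = size + (spec.linker_length if k < len(spec.domain_sizes) - 1 else 0)
        domains.append(Fragment.continuous(pos, pos + extent - 1))
        pos += extent
    return DomainAssignment(
        domains=domains,
        length=spec.length + spec.linker_length * (len(spec.domain_sizes) - 1),
    )


def perturb_map(
    cmap: ContactMap, noise_sd: float, seed: int = 0
) -> ContactMap:
    """Add clipped symmetric Gaussian noise; noise_sd = 0 is the identity."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return ContactMap(p=cmap.p.copy(), params_used=cmap.params_used)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=cmap.p.shape)
    noise = np.triu(noise, 1)
    noise = noise + noise.T
    p = np.clip(cmap.p + noise, _P_EPS, 1 - _P_EPS)
    return ContactMap(p=p, params_used=cmap.params_used)
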