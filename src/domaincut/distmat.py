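"""Distance matrices and contact maps.

The parser is driven entirely by an L×L inter-residue distance matrix, which
can come from two places:

* **structure mode** — the matrix is computed from a PDB/mmCIF chain using the
  Cβ atom of each residue (Cα for glycine) as the representative atom;
* **sequence mode** — the matrix is read from a file produced by an external
  distance predictor (the expected-distance reduction of a distogram).

Distances are mapped to contact probabilities with a logistic transform

    p_ij = 1 / (1 + exp((d_ij - d0) / delta)),

so that a pair at the reference distance d0 (default 8 Å) scores exactly 0.5
and probability decays smoothly for more distant pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .params import ScoringParams


class StructureError(ValueError):
    """Problems locating or interpreting a structure file."""


class ChainNotFoundError(StructureError):
    pass


class EmptyChainError(StructureError):
    pass


@dataclass
class ResidueChain:
    """One polymer chain with representative-atom coordinates.

    Residues are renumbered sequentially ``1..L`` regardless of author
    numbering; ``index_to_author`` retains the original labels for output.
    """

    author_ids: list[str]
    residue_names: list[str]
    coords: np.ndarray  # (L, 3), Å

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (L, 3)")
        if len(self.author_ids) != len(self.coords):
            raise ValueError("author_ids and coords length mismatch")

    @property
    def length(self) -> int:
        return len(self.coords)

    @property
    def index_to_author(self) -> dict[int, str]:
        return {i + 1: a for i, a in enumerate(self.author_ids)}


@dataclass
class DistanceMatrix:
    """Symmetric L×L matrix of inter-residue distances in Å."""

    d: np.ndarray
    source: str = "derived"  # "derived" (from structure) or "predicted"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.ndim != 2 or self.d.shape[0] != self.d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.isfinite(self.d).all():
            raise ValueError("distance matrix contains non-finite entries")
        if (self.d < 0).any():
            raise ValueError("distances must be non-negative")

    @property
    def length(self) -> int:
        return self.d.shape[0]


@dataclass
class ContactMap:
    """L×L matrix of contact probabilities in (0, 1)."""

    p: np.ndarray
    params_used: ScoringParams = field(default_factory=ScoringParams)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 2 or self.p.shape[0] != self.p.shape[1]:
            raise ValueError("contact map must be square")
        if (self.p <= 0).any() or (self.p >= 1).any():
            raise ValueError("contact probabilities must lie strictly in (0, 1)")

    @property
    def length(self) -> int:
        return self.p.shape[0]


# ---------------------------------------------------------------------------
# structure input


def read_structure(
    path: str | Path,
    chain_id: str | None = None,
    model_index: int = 0,
) -> ResidueChain:
    """Read one chain of a PDB or mmCIF file into a :class:`ResidueChain`.

    The representative atom of each residue is Cβ, falling back to Cα for
    glycine (which has no Cβ) and, with a warning, for any other residue whose
    Cβ is missing from the file.  Residues with neither atom are dropped with
    a warning.  When ``chain_id`` is None the first chain of the model is
    used.  Altlocs keep the first conformer encountered.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    if model_index >= len(structure):
        raise StructureError(
            f"model index {model_index} out of range ({len(structure)} models)"
        )
    model = structure[model_index]
    if len(model) == 0:
        raise EmptyChainError(f"no chains in {path}")
    if chain_id is None:
        chain = model[0]
    else:
        chain = model.find_chain(chain_id)
        if chain is None:
            available = ",".join(ch.name for ch in model)
            raise ChainNotFoundError(
                f"chain {chain_id!r} not found in {path} (available: {available})"
            )

    author_ids: list[str] = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    n_cb_fallback = 0
    n_dropped = 0
    for residue in chain:
        if residue.is_water():
            continue
        # Skip non-polymer heteroatoms that carry no Cα at all (ligands, ions).
        ca = residue.find_atom("CA", "*")
        cb = residue.find_atom("CB", "*")
        if cb is not None:
            pos = cb.pos
        elif ca is not None:
            pos = ca.pos
            if residue.name != "GLY":
                n_cb_fallback += 1
        else:
            n_dropped += 1
            continue
        author_ids.append(str(residue.seqid.num) + (residue.seqid.icode or "").strip())
        names.append(residue.name)
        coords.append(np.array([pos.x, pos.y, pos.z]))

    if n_cb_fallback:
        warnings.warn(
            f"{n_cb_fallback} non-glycine residue(s) missing CB; used CA instead",
            stacklevel=2,
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} residue(s) with neither CB nor CA", stacklevel=2
        )
    if not coords:
        raise EmptyChainError(f"no usable residues in chain {chain.name!r} of {path}")
    return ResidueChain(author_ids=author_ids, residue_names=names,
                        coords=np.vstack(coords))


def compute_distance_matrix(chain: ResidueChain) -> DistanceMatrix:
    """Pairwise Euclidean distances between representative atoms."""
    x = chain.coords
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=-1))
    return DistanceMatrix(d=d, source="derived")


# ---------------------------------------------------------------------------
# contact transform


def contact_probability(d_ij, params: ScoringParams | None = None):
    """Logistic distance→contact transform; 0.5 exactly at ``d0``."""
    params = params or ScoringParams()
    d_ij = np.asarray(d_ij, dtype=float)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp((d_ij - params.d0) / params.delta))


def contact_map(D: DistanceMatrix, params: ScoringParams | None = None) -> ContactMap:
    """Apply the contact transform entrywise.

    Diagonal and near-diagonal entries are present but never consumed by the
    interaction scores (the intra score excludes pairs with |i-j| <= 2).
    """
    params = params or ScoringParams()
    p = contact_probability(D.d, params)
    # Keep entries strictly inside (0,1): the transform saturates in float64
    # for very large distances.
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - 1e-16)
    return ContactMap(p=p, params_used=params)


# ---------------------------------------------------------------------------
# predicted-matrix input / export

_ASYMMETRY_TOL = 0.5  # Å, max-abs


def read_distance_matrix(
    path: str | Path, length_hint: int | None = None
) -> DistanceMatrix:
    """Read an L×L matrix from whitespace-delimited text or ``.npy``.

    The matrix is symmetrized as (M + Mᵀ)/2 provided the asymmetry is at most
    0.5 Å max-abs; larger asymmetry, non-square shape or NaNs are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        m = np.load(path)
    else:
        m = np.loadtxt(path, ndmin=2)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix in {path} is not square: shape {m.shape}")
    if np.isnan(m).any():
        raise ValueError(f"matrix in {path} contains NaN entries")
    if length_hint is not None and m.shape[0] != length_hint:
        raise ValueError(
            f"matrix length {m.shape[0]} does not match expected {length_hint}"
        )
    asym = np.abs(m - m.T).max()
    if asym > _ASYMMETRY_TOL:
        raise ValueError(
            f"matrix asymmetry {asym:.3f} Å exceeds tolerance {_ASYMMETRY_TOL} Å"
        )
    d = 0.5 * (m + m.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d, source="predicted")


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    """Plain-text export (``%.6f``), re-readable by :func:`read_distance_matrix`."""
    np.savetxt(path, D.d, fmt="%.6f")
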