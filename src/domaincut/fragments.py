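"""Fragments and domain assignments.

A :class:`Fragment` is an ordered set of sequential residue indices stored as
disjoint inclusive segments, which lets a single object represent both
continuous fragments and discontinuous ones (e.g. the two flanks of a host
domain around an insertion).  A :class:`DomainAssignment` is a partition of
``1..L`` into named domains, serializable as a domain string of the form
``"1-50,151-200;51-150"`` (domains separated by ``;``, segments by ``,``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Fragment:
    """An ordered set of 1-based residue indices as disjoint segments."""

    segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((int(a), int(b)) for a, b in self.segments)
        if not segs:
            raise ValueError("fragment must contain at least one segment")
        for a, b in segs:
            if a < 1 or b < a:
                raise ValueError(f"invalid segment ({a}, {b})")
        for (_, b0), (a1, _) in zip(segs, segs[1:]):
            if a1 <= b0:
                raise ValueError("segments must be sorted and non-overlapping")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def from_indices(cls, indices) -> "Fragment":
        """Build from any iterable of 1-based indices, coalescing runs."""
        idx = np.unique(np.asarray(list(indices), dtype=int))
        if idx.size == 0:
            raise ValueError("fragment must contain at least one residue")
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [idx.size - 1]))
        return cls(tuple((int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)))

    @classmethod
    def continuous(cls, start: int, end: int) -> "Fragment":
        return cls(((start, end),))

    @property
    def size(self) -> int:
        return sum(b - a + 1 for a, b in self.segments)

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def is_continuous(self) -> bool:
        return len(self.segments) == 1

    def indices(self) -> np.ndarray:
        """All residue indices, 1-based, ascending."""
        return np.concatenate(
            [np.arange(a, b + 1) for a, b in self.segments]
        ).astype(int)

    def indices0(self) -> np.ndarray:
        """All residue indices, 0-based, for matrix slicing."""
        return self.indices() - 1

    def __contains__(self, i: int) -> bool:
        return any(a <= i <= b for a, b in self.segments)

    def overlaps(self, other: "Fragment") -> bool:
        for a, b in self.segments:
            for c, d in other.segments:
                if a <= d and c <= b:
                    return True
        return False

    def union(self, other: "Fragment") -> "Fragment":
        if self.overlaps(other):
            raise ValueError("cannot union overlapping fragments")
        return Fragment.from_indices(
            np.concatenate([self.indices(), other.indices()])
        )

    def to_string(self, index_to_author: dict[int, str] | None = None) -> str:
        if index_to_author is None:
            return ",".join(f"{a}-{b}" for a, b in self.segments)
        return ",".join(
            f"{index_to_author[a]}-{index_to_author[b]}" for a, b in self.segments
        )


@dataclass
class DomainAssignment:
    """A partition of residues ``1..L`` into domains ordered by first residue."""

    domains: list[Fragment]
    length: int
    index_to_author: dict[int, str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda f: f.start)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def labels(self) -> np.ndarray:
        """Per-residue domain index (0-based); -1 marks unassigned residues."""
        lab = np.full(self.length, -1, dtype=int)
        for k, dom in enumerate(self.domains):
            lab[dom.indices0()] = k
        return lab

    def validate(self, allow_gaps: bool = False) -> None:
        lab = np.full(self.length, -1, dtype=int)
        for k, dom in enumerate(self.domains):
            idx = dom.indices0()
            if idx.min() < 0 or idx.max() >= self.length:
                raise ValueError("domain indices outside 1..L")
            if (lab[idx] != -1).any():
                raise ValueError("domains overlap")
            lab[idx] = k
        if not allow_gaps and (lab == -1).any():
            missing = np.nonzero(lab == -1)[0] + 1
            raise ValueError(f"unassigned residues: {missing[:5].tolist()}...")

    def to_string(self, author_numbering: bool = False) -> str:
        mapping = self.index_to_author if author_numbering else None
        if author_numbering and mapping is None:
            raise ValueError("no author-numbering map available")
        return ";".join(d.to_string(mapping) for d in self.domains)

    @classmethod
    def from_string(
        cls, s: str, length: int, allow_gaps: bool = False
    ) -> "DomainAssignment":
        """Parse a domain string like ``"1-50,151-200;51-150"``.

        Every residue of ``1..length`` must be assigned unless ``allow_gaps``;
        gap residues are then simply left out of all domains (a null domain
        excluded from scoring).
        """
        domains: list[Fragment] = []
        for dom_s in s.strip().split(";"):
            segs: list[tuple[int, int]] = []
            for seg_s in dom_s.strip().split(","):
                parts = seg_s.strip().split("-")
                if len(parts) != 2:
                    raise ValueError(f"malformed segment: {seg_s!r}")
                try:
                    a, b = int(parts[0]), int(parts[1])
                except ValueError as exc:
                    raise ValueError(f"malformed segment: {seg_s!r}") from exc
                segs.append((a, b))
            domains.append(Fragment.from_indices(
                np.concatenate([np.arange(a, b + 1) for a, b in segs])
            ))
        out = cls(domains=domains, length=length)
        out.validate(allow_gaps=allow_gaps)
        return out
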