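"""Algorithm constants for domain decomposition.

All tunables of the parser live in one frozen-by-convention dataclass so that
every stage (contact transform, splitting, merging) sees the same values and a
run can be reproduced from a flat ``key=value`` config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class ScoringParams:
    """Constants of the interaction-score model and the split/merge rules.

    Attributes
    ----------
    d0 : float
        Midpoint of the logistic distance-to-contact transform, in Å.  A
        residue pair at exactly ``d0`` has contact probability 0.5.
    delta : float
        Softness of the logistic transform, in Å.
    alpha : float
        Size-normalization exponent of the inter-fragment interaction score.
    beta : float
        Size-normalization exponent of the intra-fragment interaction score.
    min_fragment : int
        Minimum number of residues in any fragment produced by a split.
    min_loop_sep : int
        Minimum sequence separation (exclusive) between the two cut points of
        a discontinuous split; keeps the excised continuous fragment from
        being trivially small.
    max_spatial_gap : float
        Maximum representative-atom distance, in Å, between the two cut
        points of a discontinuous split; the sequentially distant cut sites
        must be spatially close for the excision to be meaningful.
    oversplit_factor : float
        A split is accepted only when its inter-fragment score is below
        ``oversplit_factor`` times the parent's intra score.
    weak_intra : float
        Post-processing threshold: a fragment whose intra score falls below
        this is merged into its strongest-interacting partner.
    pair_counting : str
        ``"once"`` counts each unordered intra-fragment residue pair once
        (i<j); ``"twice"`` counts ordered pairs, doubling the intra score.
        The absolute thresholds ``oversplit_factor`` (relative, invariant)
        and ``weak_intra`` (absolute, convention-dependent) interact with
        this choice; the default is the common contact-energy convention.
    """

    d0: float = 8.0
    delta: float = 1.5
    alpha: float = 0.43
    beta: float = 0.95
    min_fragment: int = 30
    min_loop_sep: int = 35
    max_spatial_gap: float = 8.0
    oversplit_factor: float = 0.5
    weak_intra: float = 1.0
    pair_counting: str = "once"

    def __post_init__(self) -> None:
        if self.d0 <= 0 or self.delta <= 0:
            raise ValueError("d0 and delta must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.min_fragment < 1 or self.min_loop_sep < 1:
            raise ValueError("size/separation bounds must be positive integers")
        if not 0.0 < self.oversplit_factor < 1.0:
            raise ValueError("oversplit_factor must lie in (0, 1)")
        if self.max_spatial_gap <= 0 or self.weak_intra <= 0:
            raise ValueError("max_spatial_gap and weak_intra must be positive")
        if self.pair_counting not in ("once", "twice"):
            raise ValueError("pair_counting must be 'once' or 'twice'")

    # -- flat key=value (de)serialization ---------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ScoringParams":
        kwargs: dict = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in types:
                raise ValueError(f"unknown parameter: {key}")
            if key == "pair_counting":
                kwargs[key] = value
            elif key in ("min_fragment", "min_loop_sep"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ScoringParams":
        return dataclasses.replace(self, **kwargs)
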