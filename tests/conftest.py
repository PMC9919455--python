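from __future__ import annotations

import numpy as np
import pytest

from domaincut.distmat import ContactMap, DistanceMatrix
from domaincut.params import ScoringParams


@pytest.fixture
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230203)


def as_cmap(p: np.ndarray) -> ContactMap:
    return ContactMap(p=p)


def dist_from_p(p: np.ndarray, params: ScoringParams | None = None) -> DistanceMatrix:
    """Distance matrix consistent with a contact map (inverse transform)."""
    params = params or ScoringParams()
    d = params.d0 + params.delta * np.log(1.0 / p - 1.0)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d=d)
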