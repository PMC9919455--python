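"""Scikit-learn-style estimator wrapping the domain parser.

:class:`DomainParser` treats domain decomposition as clustering of residues:
``fit`` takes an L×L inter-residue distance matrix (structure-derived or
predicted) and produces per-residue domain labels.  It follows the sklearn
estimator contract — constructor stores hyperparameters verbatim,
``get_params``/``set_params``/``clone`` work, fitted state carries trailing
underscores — so it composes with sklearn model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .distmat import ContactMap, DistanceMatrix, contact_map
from .fragments import DomainAssignment
from .merger import parse_domains
from .params import ScoringParams
from .ss import all_coil


class DomainParser(BaseEstimator, ClusterMixin):
    """Decompose a protein chain into domains from its distance matrix.

    Parameters mirror :class:`~domaincut.params.ScoringParams`; see there for
    units and meaning.

    Attributes
    ----------
    labels_ : ndarray of shape (L,)
        0-based domain index per residue.
    assignment_ : DomainAssignment
        The full parse, including discontinuous domains.
    domains_ : list of Fragment
        Domains ordered by first residue.
    n_domains_ : int
    domain_string_ : str
        Serialized parse, e.g. ``"1-50,151-200;51-150"``.

    Examples
    --------
    >>> from domaincut.synthetic import SyntheticSpec, make_block_contact_map
    >>> cmap, dmat, truth = make_block_contact_map(SyntheticSpec((40, 40)))
    >>> DomainParser().fit(dmat.d).domain_string_
    '1-40;41-80'
    """

    def __init__(
        self,
        d0: float = 8.0,
        delta: float = 1.5,
        alpha: float = 0.43,
        beta: float = 0.95,
        min_fragment: int = 30,
        min_loop_sep: int = 35,
        max_spatial_gap: float = 8.0,
        oversplit_factor: float = 0.5,
        weak_intra: float = 1.0,
        pair_counting: str = "once",
    ):
        self.d0 = d0
        self.delta = delta
        self.alpha = alpha
        self.beta = beta
        self.min_fragment = min_fragment
        self.min_loop_sep = min_loop_sep
        self.max_spatial_gap = max_spatial_gap
        self.oversplit_factor = oversplit_factor
        self.weak_intra = weak_intra
        self.pair_counting = pair_counting

    def _params(self) -> ScoringParams:
        return ScoringParams(
            d0=self.d0,
            delta=self.delta,
            alpha=self.alpha,
            beta=self.beta,
            min_fragment=self.min_fragment,
            min_loop_sep=self.min_loop_sep,
            max_spatial_gap=self.max_spatial_gap,
            oversplit_factor=self.oversplit_factor,
            weak_intra=self.weak_intra,
            pair_counting=self.pair_counting,
        )

    def fit(self, X, y=None, ss: str | None = None):
        """Parse the chain whose distance matrix is ``X``.

        Parameters
        ----------
        X : array-like of shape (L, L)
            Symmetric inter-residue distance matrix in Å.
        y : ignored
        ss : str, optional
            Per-residue H/E/C secondary structure; without it every position
            is a legal cut site (all-coil).
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError(f"X must be a square distance matrix, got {X.shape}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        params = self._params()
        dmat = DistanceMatrix(d=0.5 * (X + X.T))
        if ss is None:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ss = all_coil(dmat.length)
        cmap = contact_map(dmat, params)
        self.assignment_ = parse_domains(cmap, dmat, ss, params)
        self.labels_ = self.assignment_.labels()
        self.domains_ = self.assignment_.domains
        self.n_domains_ = self.assignment_.n_domains
        self.domain_string_ = self.assignment_.to_string()
        return self

    def fit_contact_map(
        self,
        cmap: ContactMap,
        dmat: DistanceMatrix,
        ss: str | None = None,
    ):
        """Parse from a pre-built contact map plus the distances used for the
        discontinuous split's spatial gate."""
        params = self._params()
        if ss is None:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ss = all_coil(cmap.length)
        self.assignment_ = parse_domains(cmap, dmat, ss, params)
        self.labels_ = self.assignment_.labels()
        self.domains_ = self.assignment_.domains
        self.n_domains_ = self.assignment_.n_domains
        self.domain_string_ = self.assignment_.to_string()
        return self

    def fit_predict(self, X, y=None, **fit_params):
        """Fit and return per-residue domain labels."""
        return self.fit(X, **fit_params).labels_


def parse_distance_matrix(
    X, ss: str | None = None, params: ScoringParams | None = None
) -> DomainAssignment:
    """Functional one-shot wrapper over :class:`DomainParser`."""
    params = params or ScoringParams()
    est = DomainParser(**{
        "d0": params.d0,
        "delta": params.delta,
        "alpha": params.alpha,
        "beta": params.beta,
        "min_fragment": params.min_fragment,
        "min_loop_sep": params.min_loop_sep,
        "max_spatial_gap": params.max_spatial_gap,
        "oversplit_factor": params.oversplit_factor,
        "weak_intra": params.weak_intra,
        "pair_counting": params.pair_counting,
    })
    return est.fit(X, ss=ss).assignment_
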