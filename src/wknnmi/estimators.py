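"""Scikit-learn-style estimator facade over the imputation engine.

``WKNNImputer`` follows the fit/transform contract: ``fit`` freezes a donor
pool (and, for MI weighting, estimates the mutual-information matrix from
it); ``transform`` imputes a dataset's missing window entries using only the
fitted donors. Fitting and transforming on the same dataset reproduces
self-mode imputation exactly, because each query subject is excluded from
its own donor set by id.

The estimator operates on :class:`~wknnmi.data_model.LongitudinalDataset`
objects rather than 2-D arrays — the register's visit structure cannot be
flattened losslessly — but exposes ``get_params``/``set_params`` and clones
cleanly, so it composes with scikit-learn model selection over its
hyper-parameters.
"""

from __future__ import annotations

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import LongitudinalDataset
from .imputer import ImputationConfig, ImputationResult, impute_dataset
from .mutual_info import compute_mi_matrix
from .sample_builder import DEFAULT_TOLERANCE, DEFAULT_WINDOW_END

__all__ = ["WKNNImputer"]

_WEIGHTINGS = {"uniform": "wknn", "mutual_info": "wknn_mi", "random": "krn"}


class WKNNImputer(TransformerMixin, BaseEstimator):
    """Adaptive weighted k-nearest-neighbour imputer for clinical registers.

    Parameters
    ----------
    k : int, default=20
        Number of donor neighbours.
    weighting : {"mutual_info", "uniform", "random"}, default="mutual_info"
        Distance weighting: MI-matrix row of the target feature, unit
        weights, or the seeded random-neighbour baseline.
    window_end : float, default=2.0
        End of the query window in months (visits in ``[0, window_end]``).
    tolerance : float, default=1.0
        Visit-matching tolerance in months.
    comparability_threshold : float, default=0.9
        Minimum shared fraction of the query's non-missing (visit-adjusted)
        entries a donor must reach.
    distance_epsilon : float, default=1e-9
        Floor for distances in inverse-distance aggregation weights.
    round_ordinal : bool, default=True
        Round ordinal imputations to the nearest admissible level.
    random_state : int or None
        Seed for the random-neighbour baseline.

    Attributes
    ----------
    donor_pool_ : LongitudinalDataset
        The fitted donor pool.
    mi_matrix_ : MIMatrix or None
        Pairwise MI between base features (``weighting="mutual_info"``).
    schema_ : RegisterSchema

    Examples
    --------
    >>> imputer = WKNNImputer(k=20).fit(train)
    >>> imputed_test = imputer.transform(test)
    """

    def __init__(
        self,
        k: int = 20,
        weighting: str = "mutual_info",
        window_end: float = DEFAULT_WINDOW_END,
        tolerance: float = DEFAULT_TOLERANCE,
        comparability_threshold: float = 0.9,
        distance_epsilon: float = 1e-9,
        round_ordinal: bool = True,
        random_state: int | None = None,
    ):
        self.k = k
        self.weighting = weighting
        self.window_end = window_end
        self.tolerance = tolerance
        self.comparability_threshold = comparability_threshold
        self.distance_epsilon = distance_epsilon
        self.round_ordinal = round_ordinal
        self.random_state = random_state

    def _config(self) -> ImputationConfig:
        if self.weighting not in _WEIGHTINGS:
            raise ValueError(f"unknown weighting {self.weighting!r}")
        return ImputationConfig(
            k=self.k,
            method=_WEIGHTINGS[self.weighting],
            tolerance=self.tolerance,
            window_end=self.window_end,
            comparability_threshold=self.comparability_threshold,
            distance_epsilon=self.distance_epsilon,
            round_ordinal=self.round_ordinal,
            seed=self.random_state,
        )

    def fit(self, X: LongitudinalDataset, y=None):
        """Freeze ``X`` as the donor pool; estimate the MI matrix if the
        weighting needs one."""
        if not isinstance(X, LongitudinalDataset):
            raise TypeError("X must be a LongitudinalDataset")
        if not X.patients:
            raise ValueError("empty donor pool")
        self._config()  # validate parameters early
        self.donor_pool_ = X
        self.schema_ = X.schema
        self.mi_matrix_ = (
            compute_mi_matrix(X, self.window_end) if self.weighting == "mutual_info" else None
        )
        return self

    def transform(self, X: LongitudinalDataset) -> LongitudinalDataset:
        """Impute every patient of ``X`` from the fitted donors.

        Query subjects never donate to each other; a query subject present in
        the fitted pool is excluded from its own donor set (so
        ``fit(ds).transform(ds)`` is self-mode imputation).
        """
        return self.transform_result(X).dataset

    def transform_result(self, X: LongitudinalDataset) -> ImputationResult:
        """Like :meth:`transform` but returns the full result with the
        per-cell provenance log."""
        check_is_fitted(self, "donor_pool_")
        if X.schema.feature_names != self.schema_.feature_names:
            raise ValueError("schema mismatch between fit and transform data")
        return impute_dataset(X, self.donor_pool_, self._config(), self.mi_matrix_)

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.non_deterministic = self.weighting == "random" and self.random_state is None
        return tags
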