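"""Plug-in mutual-information estimation between register features.

MI between every pair of base features is estimated empirically (frequentist
plug-in, natural logarithm, so values are in nats) and collected in a
symmetric matrix whose row for the target feature weights the k-NN distance.
Continuous features are first discretised into ``i = N**(1/3)`` equal-width
intervals; ordinal and categorical features use their levels directly.

Missing data are handled by pairwise-complete deletion per feature pair: a
row contributes to MI(X, Y) only when both X and Y are observed in it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MISSING, LongitudinalDataset, is_missing
from .sample_builder import DEFAULT_WINDOW_END

__all__ = [
    "MIMatrix",
    "discretise_equal_width",
    "mutual_information",
    "compute_mi_matrix",
]

logger = logging.getLogger(__name__)


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise mutual information (nats) between base
    features, in schema order. The diagonal entry for feature ``f`` is its
    empirical entropy H(f) = MI(f, f)."""

    values: np.ndarray
    feature_names: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.feature_names)
        if self.values.shape != (n, n):
            raise ValueError("MI matrix shape does not match feature names")

    def row(self, feature_name: str) -> np.ndarray:
        return self.values[self.feature_names.index(feature_name)]

    def __getitem__(self, pair) -> float:
        a, b = pair
        return float(self.values[self.feature_names.index(a), self.feature_names.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_names, columns=self.feature_names)

    def save(self, path):
        """Plain matrix file with a feature-name header (CSV)."""
        self.to_dataframe().to_csv(path)

    @classmethod
    def load(cls, path) -> "MIMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), list(df.columns))


def _n_bins(n: int) -> int:
    # cube-root rule with banker's rounding (numpy's round), floored at 2
    return max(2, int(np.round(n ** (1.0 / 3.0))))


def discretise_equal_width(x) -> np.ndarray:
    """Equal-width discretisation of a continuous vector.

    The number of intervals is the cube root of the number of non-missing
    values (rounded, never below 2); bin width is ``(max - min)/i``; the
    maximum falls in the last bin; missing entries stay missing (NaN).

    Returns a float array of bin indices with NaN for missing.
    """
    arr = np.array([np.nan if is_missing(v) else float(v) for v in x], dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size == 0:
        raise ValueError("all-missing input")
    lo, hi = obs.min(), obs.max()
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if hi == lo:
        out[mask] = 0.0
        return out
    bins = _n_bins(obs.size)
    idx = np.floor((arr[mask] - lo) / (hi - lo) * bins)
    out[mask] = np.clip(idx, 0, bins - 1)
    return out


def _pairwise_complete(x, y):
    xa = np.asarray(x, dtype=object)
    ya = np.asarray(y, dtype=object)
    keep = np.array(
        [not is_missing(a) and not is_missing(b) for a, b in zip(xa, ya)], dtype=bool
    )
    return xa[keep], ya[keep]


def mutual_information(x, y) -> float:
    """Plug-in MI estimate (nats) between two discrete vectors.

    Computed over pairwise-complete observations; ``0*ln(0)`` terms
    contribute 0; the result is clamped at 0 against floating-point error.
    """
    xa, ya = _pairwise_complete(x, y)
    if xa.size == 0:
        raise ValueError("zero pairwise-complete observations")
    joint = pd.crosstab(pd.Series(xa), pd.Series(ya)).to_numpy(dtype=float)
    total = joint.sum()
    pxy = joint / total
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log(pxy / (px * py))
    mi = float(np.nansum(terms))
    return max(mi, 0.0)


def entropy(x) -> float:
    """Empirical entropy in nats (equals MI(X, X))."""
    return mutual_information(x, x)


def _observation_tables(ds: LongitudinalDataset, window_end: float | None):
    """Per-patient table (statics) and per-visit table (statics repeated +
    dynamics) with continuous columns discretised, as object-dtype columns."""
    schema = ds.schema
    per_patient = {
        f.name: [pt.static_values.get(f.name, MISSING) for pt in ds.patients]
        for f in schema.static_features
    }
    per_visit = {f.name: [] for f in schema.features}
    for pt in ds.patients:
        visits = pt.visits
        if window_end is not None:
            visits = [v for v in visits if 0.0 <= v.time <= window_end]
        for v in visits:
            for f in schema.static_features:
                per_visit[f.name].append(pt.static_values.get(f.name, MISSING))
            for f in schema.dynamic_features:
                per_visit[f.name].append(v.values.get(f.name, MISSING))

    def prepare(columns):
        out = {}
        for name, col in columns.items():
            spec = schema[name]
            if spec.scale == "continuous" and any(not is_missing(v) for v in col):
                out[name] = discretise_equal_width(col)
            else:
                out[name] = np.asarray(col, dtype=object)
        return out

    return prepare(per_patient), prepare(per_visit)


def compute_mi_matrix(
    donor_pool: LongitudinalDataset,
    window_end: float | None = DEFAULT_WINDOW_END,
) -> MIMatrix:
    """Pairwise MI between all base features of a donor pool.

    Static-static pairs are estimated on one row per patient (so patients
    with many visits are not over-weighted); any pair involving a dynamic
    feature is estimated on one row per in-window visit with the static
    values repeated. ``window_end=None`` uses all visits.

    A feature with no observed values gets a zero row/column (warned).
    """
    if not donor_pool.patients:
        raise ValueError("empty donor pool")
    schema = donor_pool.schema
    names = schema.feature_names
    static_names = {f.name for f in schema.static_features}
    per_patient, per_visit = _observation_tables(donor_pool, window_end)

    n = len(names)
    values = np.zeros((n, n))
    empty = set()
    for name in names:
        table = per_patient if name in static_names else per_visit
        if all(is_missing(v) for v in table[name]):
            empty.add(name)
            logger.warning("feature %r has no observed values; MI row set to 0", name)
    for a in range(n):
        if names[a] in empty:
            continue
        for b in range(a, n):
            if names[b] in empty:
                continue
            both_static = names[a] in static_names and names[b] in static_names
            table = per_patient if both_static else per_visit
            x, y = table[names[a]], table[names[b]]
            try:
                mi = mutual_information(x, y)
            except ValueError:  # zero pairwise-complete rows for this pair
                mi = 0.0
            values[a, b] = values[b, a] = mi
    return MIMatrix(values, list(names))
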