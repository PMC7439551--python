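"""Weighted k-nearest-neighbour imputation engine.

For each missing entry of a query subject the engine (i) flattens the
subject's window visits and every temporally matched donor into same-shape
feature vectors, (ii) min-max normalises continuous/ordinal entries over the
pooled samples, (iii) computes the pairwise-complete mixed-type distance —
0/1 mismatch for categorical entries, absolute difference for
continuous/ordinal ones, static contributions re-balanced by the visit count
``n``, everything divided by the visit-adjusted number of comparable entries
— optionally weighting every entry by the mutual information between its base
feature and the feature under imputation, (iv) drops donors sharing fewer
than 90% of the query's non-missing entries, (v) ranks the survivors and
(vi) aggregates the ``k`` nearest donors' raw values: inverse-distance
weighted mean after 1.5-IQR outlier trimming for continuous/ordinal targets,
mode for categorical ones.

Distances are therefore target-specific under MI weighting: the neighbours
chosen to impute one feature may differ from those chosen for another.
Previously imputed values of a subject are never reused: every query reads
from the untouched original record, writes go to a copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import (
    MISSING,
    FeatureSpec,
    LongitudinalDataset,
    PatientRecord,
    RegisterSchema,
    is_missing,
    quantile,
)
from .mutual_info import MIMatrix, compute_mi_matrix
from .sample_builder import (
    DEFAULT_TOLERANCE,
    DEFAULT_WINDOW_END,
    NoVisitInWindow,
    Sample,
    build_candidate_sample,
    build_query_sample,
    query_observed_total,
    select_window_visits,
)

__all__ = [
    "ImputationConfig",
    "DistanceContext",
    "NeighbourSet",
    "ImputationResult",
    "IncomparableSamples",
    "NoEligibleDonor",
    "normalise_pool",
    "pair_distance",
    "rank_neighbours",
    "aggregate_numeric",
    "aggregate_categorical",
    "impute_subject",
    "impute_dataset",
    "impute_random_baseline",
]

METHODS = ("wknn", "wknn_mi", "krn")


class IncomparableSamples(ValueError):
    """Two samples share zero non-missing entries."""


class NoEligibleDonor(ValueError):
    """No candidate holds a value for the target entry."""


@dataclass
class ImputationConfig:
    """Tunable parameters of the imputation engine.

    ``k`` is the neighbour count (20 by default, the best-performing setting
    for the MI-weighted method; the unweighted preset uses 10). ``seed`` only
    drives the random-neighbour baseline.
    """

    k: int = 20
    method: str = "wknn_mi"
    tolerance: float = DEFAULT_TOLERANCE
    window_end: float = DEFAULT_WINDOW_END
    comparability_threshold: float = 0.9
    distance_epsilon: float = 1e-9
    round_ordinal: bool = True
    seed: int | None = None

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not 0.0 <= self.comparability_threshold <= 1.0:
            raise ValueError("comparability_threshold must be in [0, 1]")
        if self.distance_epsilon <= 0:
            raise ValueError("distance_epsilon must be > 0")


def preset(method: str, **overrides) -> ImputationConfig:
    """Method preset with its selected neighbour count (wknn: k=10,
    wknn_mi/krn: k=20)."""
    defaults = {"wknn": 10, "wknn_mi": 20, "krn": 20}
    cfg = ImputationConfig(k=defaults[method], method=method)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# Sample encoding


def _encode_value(spec: FeatureSpec, value) -> float:
    if is_missing(value):
        return np.nan
    if spec.scale == "continuous":
        return float(value)
    if spec.scale == "ordinal":
        return float(value)
    return float(spec.levels.index(value))


def encode_sample(sample: Sample, schema: RegisterSchema) -> np.ndarray:
    """Flatten a sample to a float vector (NaN = missing; categorical values
    as level codes, compared only by equality)."""
    out = [_encode_value(f, v) for f, v in zip(schema.static_features, sample.static_block)]
    for block in sample.dynamic_blocks:
        out.extend(_encode_value(f, v) for f, v in zip(schema.dynamic_features, block))
    return np.asarray(out, dtype=float)


@dataclass
class DistanceContext:
    """Entry-level metadata shared by all distance computations on one pool.

    ``weight_row`` holds one weight per *base* feature (all ones for the
    unweighted method, an MI-matrix row for the MI-weighted one) and is
    broadcast to every per-visit copy of each dynamic feature; static entry
    contributions are multiplied by the query visit count ``n``.
    """

    n: int
    base_idx: np.ndarray
    is_static: np.ndarray
    is_cat: np.ndarray
    bounds: np.ndarray  # (n_base_features, 2) pooled min/max, NaN when unseen
    weight_row: np.ndarray

    @property
    def entry_weights(self) -> np.ndarray:
        return self.weight_row[self.base_idx]

    @property
    def static_multiplier(self) -> np.ndarray:
        return np.where(self.is_static, float(self.n), 1.0)

    def with_weights(self, weight_row) -> "DistanceContext":
        return DistanceContext(
            self.n, self.base_idx, self.is_static, self.is_cat, self.bounds,
            np.asarray(weight_row, dtype=float),
        )


def _entry_layout(schema: RegisterSchema, n: int):
    p, m = schema.p, schema.m
    base_idx = np.concatenate([np.arange(p)] + [p + np.arange(m)] * n)
    is_static = np.concatenate([np.ones(p, bool), np.zeros(n * m, bool)])
    is_cat = np.array(
        [f.scale == "categorical" for f in schema.static_features]
        + [f.scale == "categorical" for f in schema.dynamic_features] * n
    )
    return base_idx, is_static, is_cat


def normalise_pool(query: Sample, candidates: list, schema: RegisterSchema):
    """Min-max normalise continuous/ordinal entries over the pooled samples.

    Bounds for each base feature pool every per-visit copy across the query
    and *all* candidate samples. A constant pooled feature maps to 0
    everywhere, contributing 0 to any absolute difference; categorical codes
    are left untouched.

    Returns ``(norm_query, norm_candidates, ctx)`` where the first two are
    float vectors/matrix and ``ctx`` is a :class:`DistanceContext` with unit
    weights.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    n = query.n
    base_idx, is_static, is_cat = _entry_layout(schema, n)
    Q = encode_sample(query, schema)
    C = np.vstack([encode_sample(c, schema) for c in candidates])
    n_base = schema.p + schema.m
    bounds = np.full((n_base, 2), np.nan)
    pooled = np.vstack([Q, C])
    for b in range(n_base):
        cols = pooled[:, base_idx == b]
        if np.all(np.isnan(cols)):
            continue
        bounds[b] = [np.nanmin(cols), np.nanmax(cols)]

    def scale(arr):
        out = arr.copy()
        lo = bounds[base_idx, 0]
        hi = bounds[base_idx, 1]
        span = hi - lo
        numeric = ~is_cat
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (arr - lo) / span
        scaled[:, span == 0] = 0.0  # constant feature -> 0 everywhere
        out[:, numeric] = scaled[:, numeric]
        return out

    pool_scaled = scale(pooled)
    ctx = DistanceContext(n, base_idx, is_static, is_cat, bounds, np.ones(n_base))
    return pool_scaled[0], pool_scaled[1:], ctx


def _delta_matrix(Qn: np.ndarray, Cn: np.ndarray, ctx: DistanceContext):
    """Per-entry contribution matrix and comparability mask.

    Returns ``(delta, comparable)`` where ``delta`` is |v-u| for numeric and
    the 0/1 mismatch indicator for categorical entries (0 where
    incomparable), and ``comparable`` marks entries non-missing in both.
    """
    comparable = ~np.isnan(Qn) & ~np.isnan(Cn)
    delta = np.zeros_like(Cn)
    num = ~ctx.is_cat & comparable
    delta[num] = np.abs((Cn - Qn[None, :])[num])
    cat = ctx.is_cat & comparable
    delta[cat] = (Cn != Qn[None, :])[cat].astype(float)
    return delta, comparable


def _distances(Qn: np.ndarray, Cn: np.ndarray, ctx: DistanceContext):
    """Vectorised Gower-style weighted distance of every candidate row to the
    query. Incomparable pairs get +inf."""
    delta, comparable = _delta_matrix(Qn, Cn, ctx)
    mult = ctx.static_multiplier
    numer = delta @ (mult * ctx.entry_weights)
    denom = comparable @ mult
    with np.errstate(divide="ignore", invalid="ignore"):
        d = numer / denom
    d[denom == 0] = np.inf
    return d, denom


def pair_distance(v, u, ctx: DistanceContext) -> float:
    """Distance between two normalised sample vectors.

    With unit weights this is the plain visit-adjusted pairwise-complete
    mixed-type distance; with an MI row it is the MI-weighted variant.
    Raises :class:`IncomparableSamples` when no entry is observed in both.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    d, denom = _distances(v, u[None, :], ctx)
    if denom[0] == 0:
        raise IncomparableSamples("zero comparable entries")
    return float(d[0])


# ---------------------------------------------------------------------------
# Neighbour selection and aggregation


@dataclass
class NeighbourSet:
    """Ranked donors for one target entry."""

    candidate_ids: list
    distances: np.ndarray
    donor_values: list


@dataclass
class _TargetEntry:
    """A missing cell to impute: static feature, or dynamic feature at one
    window-visit index."""

    feature: FeatureSpec
    visit_index: int | None  # None for static targets

    @property
    def is_static(self) -> bool:
        return self.visit_index is None


def _donor_value(sample: Sample, schema: RegisterSchema, target: _TargetEntry):
    if target.is_static:
        sidx = [f.name for f in schema.static_features].index(target.feature.name)
        return sample.static_block[sidx]
    didx = [f.name for f in schema.dynamic_features].index(target.feature.name)
    return sample.dynamic_blocks[target.visit_index][didx]


def _ranked_order(distances: np.ndarray, candidate_ids: list) -> list:
    """Indices sorted by distance, ties broken by candidate id."""
    return sorted(range(len(candidate_ids)), key=lambda i: (distances[i], str(candidate_ids[i])))


def rank_neighbours(
    query: Sample,
    candidates: list,
    ctx: DistanceContext,
    target_feature: str,
    k: int,
    visit_index: int | None = None,
    *,
    schema: RegisterSchema,
    norm_query=None,
    norm_candidates=None,
) -> NeighbourSet:
    """Rank eligible donors for one target entry and keep the ``k`` nearest.

    Only candidates holding a non-missing value at the target entry are
    eligible; ties in distance break by candidate id. Raises
    :class:`NoEligibleDonor` when nothing can donate.
    """
    if norm_query is None or norm_candidates is None:
        norm_query, norm_candidates, base_ctx = normalise_pool(query, candidates, schema)
        ctx = base_ctx.with_weights(ctx.weight_row)
    target = _TargetEntry(schema[target_feature], visit_index)
    d, denom = _distances(norm_query, norm_candidates, ctx)
    donor_vals = [_donor_value(c, schema, target) for c in candidates]
    eligible = [
        i
        for i in range(len(candidates))
        if not is_missing(donor_vals[i]) and np.isfinite(d[i])
    ]
    if not eligible:
        raise NoEligibleDonor(f"no donor for {target_feature!r}")
    ids = [candidates[i].subject_id for i in eligible]
    sub_d = d[eligible]
    order = _ranked_order(sub_d, ids)[:k]
    return NeighbourSet(
        candidate_ids=[ids[i] for i in order],
        distances=np.array([sub_d[i] for i in order]),
        donor_values=[donor_vals[eligible[i]] for i in order],
    )


def aggregate_numeric(values, distances, spec: FeatureSpec, cfg: ImputationConfig):
    """Inverse-distance weighted mean of the donors' raw values after
    removing 1.5-IQR outliers; ordinal results are rounded half-up to the
    nearest admissible level when ``cfg.round_ordinal`` is on."""
    vals = np.asarray([float(v) for v in values], dtype=float)
    dist = np.asarray(distances, dtype=float)
    q1, q3 = quantile(vals, 0.25), quantile(vals, 0.75)
    iqr = q3 - q1
    keep = (vals >= q1 - 1.5 * iqr) & (vals <= q3 + 1.5 * iqr)
    if keep.any():  # trimming can never be allowed to empty the donor set
        vals, dist = vals[keep], dist[keep]
    w = 1.0 / np.maximum(dist, cfg.distance_epsilon)
    est = float(np.sum(w * vals) / np.sum(w))
    if spec.scale == "ordinal" and cfg.round_ordinal:
        levels = np.asarray([float(l) for l in spec.levels])
        diffs = np.abs(levels - est)
        best = np.flatnonzero(diffs == diffs.min())
        return spec.levels[int(best[-1])]  # half-up: tie goes to the larger level
    return est


def aggregate_categorical(values, distances, spec: FeatureSpec):
    """Unweighted mode of the donor values; ties resolve to the category
    holding the single closest donor, then to level order."""
    dist = np.asarray(distances, dtype=float)
    counts = {lev: 0 for lev in spec.levels}
    for v in values:
        counts[v] += 1
    top = max(counts.values())
    tied = [lev for lev in spec.levels if counts[lev] == top]
    if len(tied) == 1:
        return tied[0]
    best_d = {lev: min(dist[i] for i, v in enumerate(values) if v == lev) for lev in tied}
    closest = min(best_d.values())
    for lev in tied:  # level order breaks remaining ties
        if best_d[lev] == closest:
            return lev
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# Subject- and dataset-level loops


@dataclass
class ImputationResult:
    """An imputed dataset copy plus a per-cell provenance log."""

    dataset: LongitudinalDataset
    provenance: list = field(default_factory=list)
    n_imputed: int = 0
    n_uninputable: int = 0


class _SubjectPool:
    """All per-subject precomputation shared across target entries."""

    def __init__(self, subject, donor_pool, schema, cfg):
        self.schema = schema
        self.cfg = cfg
        self.query = build_query_sample(subject, schema, cfg.window_end)
        self.candidates = []
        for pt in donor_pool.patients:
            if pt.id == subject.id:
                continue
            s = build_candidate_sample(self.query, pt, schema, cfg.tolerance)
            if s is not None:
                self.candidates.append(s)
        if self.candidates:
            self.Qn, self.Cn, self.ctx = normalise_pool(self.query, self.candidates, schema)
            self._delta, self._comparable = _delta_matrix(self.Qn, self.Cn, self.ctx)
            mult = self.ctx.static_multiplier
            self._denom = self._comparable @ mult
            query_total = query_observed_total(self.query)
            adjusted = (self._comparable * mult).sum(axis=1)
            self.filter_pass = adjusted >= cfg.comparability_threshold * query_total
        else:
            self.filter_pass = np.zeros(0, bool)

    def distances(self, weight_row) -> np.ndarray:
        mult = self.ctx.static_multiplier
        w = np.asarray(weight_row, dtype=float)[self.ctx.base_idx]
        numer = self._delta @ (mult * w)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = numer / self._denom
        d[self._denom == 0] = np.inf
        return d

    def select(self, target: _TargetEntry, weight_row, rng=None):
        """Top-k donors for one target entry; None when uninputable."""
        donor_vals = [_donor_value(c, self.schema, target) for c in self.candidates]
        d = self.distances(weight_row)
        eligible = [
            i
            for i in range(len(self.candidates))
            if self.filter_pass[i] and not is_missing(donor_vals[i]) and np.isfinite(d[i])
        ]
        if not eligible:
            return None
        if self.cfg.method == "krn":
            take = min(self.cfg.k, len(eligible))
            chosen = list(rng.choice(len(eligible), size=take, replace=False))
            chosen = [eligible[i] for i in chosen]
            dist = np.ones(len(chosen))  # donors weigh equally in aggregation
        else:
            ids = [self.candidates[i].subject_id for i in eligible]
            order = _ranked_order(d[eligible], ids)[: self.cfg.k]
            chosen = [eligible[i] for i in order]
            dist = d[chosen]
        return NeighbourSet(
            candidate_ids=[self.candidates[i].subject_id for i in chosen],
            distances=np.asarray(dist, dtype=float),
            donor_values=[donor_vals[i] for i in chosen],
        )


def _missing_targets(subject, schema, window_end):
    """Missing static cells plus missing dynamic cells of window visits."""
    targets = []
    for f in schema.static_features:
        if is_missing(subject.static_values.get(f.name, MISSING)):
            targets.append(_TargetEntry(f, None))
    window = select_window_visits(subject, window_end)
    for idx, visit in enumerate(window):
        for f in schema.dynamic_features:
            if is_missing(visit.values.get(f.name, MISSING)):
                targets.append(_TargetEntry(f, idx))
    return targets, window


def _weight_row(cfg, mi, schema, feature_name):
    if cfg.method == "wknn_mi":
        if mi is None:
            raise ValueError("wknn_mi requires an MI matrix")
        return mi.row(feature_name)
    return np.ones(schema.p + schema.m)


def impute_subject(
    subject: PatientRecord,
    donor_pool: LongitudinalDataset,
    mi: MIMatrix | None,
    cfg: ImputationConfig,
    rng: np.random.Generator | None = None,
):
    """Impute every missing window entry of one subject.

    Returns ``(imputed_record, provenance)``; the input record is never
    modified and all queries read only original values, so previously imputed
    entries are never reused within the subject. Entries with no eligible
    donor stay missing (logged with ``donors: []``).
    """
    schema = donor_pool.schema
    targets, window = _missing_targets(subject, schema, cfg.window_end)
    result = subject.copy()
    if not targets:
        return result, []
    if cfg.method == "krn" and rng is None:
        rng = np.random.default_rng(cfg.seed)
    pool = _SubjectPool(subject, donor_pool, schema, cfg)
    provenance = []
    # window visits of the copy, aligned by time with the original's window
    window_times = {v.time for v in window}
    result_window = [v for v in result.visits if v.time in window_times]
    for target in targets:
        record = {
            "subject_id": subject.id,
            "feature": target.feature.name,
            "visit_index": target.visit_index,
            "method": cfg.method,
        }
        neigh = (
            pool.select(target, _weight_row(cfg, mi, schema, target.feature.name), rng)
            if pool.candidates
            else None
        )
        if neigh is None:
            record.update(imputed=None, donors=[])
            provenance.append(record)
            continue
        if target.feature.is_numeric:
            value = aggregate_numeric(neigh.donor_values, neigh.distances, target.feature, cfg)
            rule = "iqr_trimmed_inverse_distance_mean"
        else:
            value = aggregate_categorical(neigh.donor_values, neigh.distances, target.feature)
            rule = "mode"
        if target.is_static:
            result.static_values[target.feature.name] = value
        else:
            result_window[target.visit_index].values[target.feature.name] = value
        record.update(
            imputed=value,
            aggregation=rule,
            donors=list(neigh.candidate_ids),
            distances=[float(x) for x in neigh.distances],
            donor_values=list(neigh.donor_values),
        )
        provenance.append(record)
    return result, provenance


def impute_dataset(
    ds: LongitudinalDataset,
    donor_pool: LongitudinalDataset | str = "self",
    cfg: ImputationConfig | None = None,
    mi: MIMatrix | None = None,
) -> ImputationResult:
    """Impute every patient of a dataset.

    ``donor_pool="self"`` uses all *other* patients of ``ds`` as donors for
    each subject; an external pool uses only its patients (query subjects
    never donate to each other). The MI matrix, when needed and not supplied,
    is estimated once from the donor pool. Deterministic given ``cfg``.
    """
    cfg = cfg or ImputationConfig()
    external = not isinstance(donor_pool, str)
    if not external and donor_pool != "self":
        raise ValueError(f"unknown donor_pool {donor_pool!r}")
    pool_ds = donor_pool if external else ds
    if not pool_ds.patients or (not external and len(ds.patients) < 2):
        raise ValueError("empty donor pool")
    if cfg.method == "wknn_mi" and mi is None:
        mi = compute_mi_matrix(pool_ds, cfg.window_end)
    out = LongitudinalDataset(ds.schema, [])
    result = ImputationResult(out)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(ds.patients))
    for idx, pt in enumerate(ds.patients):
        rng = np.random.default_rng(seeds[idx]) if cfg.method == "krn" else None
        try:
            imputed, prov = impute_subject(pt, pool_ds, mi, cfg, rng)
        except NoVisitInWindow:
            imputed, prov = pt.copy(), []
        out.patients.append(imputed)
        result.provenance.extend(prov)
    result.n_imputed = sum(1 for r in result.provenance if r.get("imputed") is not None)
    result.n_uninputable = sum(1 for r in result.provenance if r.get("imputed") is None)
    return result


def impute_random_baseline(
    subject: PatientRecord,
    donor_pool: LongitudinalDataset,
    cfg: ImputationConfig,
    rng: np.random.Generator | None = None,
):
    """k-random-neighbours baseline: the identical pipeline, but the ``k``
    donors are a seeded uniform sample of the eligible candidates and weigh
    equally in aggregation."""
    cfg = ImputationConfig(**{**cfg.__dict__, "method": "krn"})
    return impute_subject(subject, donor_pool, None, cfg, rng)
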