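"""Adaptive k-NN sample construction.

For a query subject, the feature vector binds the ``p`` static values to one
block of ``m`` dynamic values per visit in the first months of screening
(window ``[0, 2]`` by default, i.e. the first three calendar months). A
candidate donor is mapped onto the query's visit schedule: for each query
visit time the candidate's closest-in-time visit within a tolerance (one
month by default) supplies that block, the same candidate visit possibly
serving several query visits; a candidate with an unmatched query time is
rejected outright.

Both vectors therefore share the exact shape ``p + n*m`` (``n`` = query visit
count), which is what the pairwise-complete weighted distance in
:mod:`wknnmi.imputer` requires.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import MISSING, PatientRecord, RegisterSchema, is_missing

__all__ = [
    "DEFAULT_WINDOW_END",
    "DEFAULT_TOLERANCE",
    "Sample",
    "ComparabilityCount",
    "NoVisitInWindow",
    "select_window_visits",
    "build_query_sample",
    "match_visits",
    "build_candidate_sample",
    "count_comparable",
    "filter_candidates",
]

#: End of the query window in months; visits with 0 <= t <= 2 span the first
#: three calendar months of screening.
DEFAULT_WINDOW_END = 2.0
#: Visit-matching tolerance in months (inclusive).
DEFAULT_TOLERANCE = 1.0


class NoVisitInWindow(ValueError):
    """Subject has no visit inside the query window."""


@dataclass
class Sample:
    """A flattened query/candidate feature vector with provenance.

    ``static_block`` holds ``p`` values in schema order; ``dynamic_blocks``
    holds ``n`` blocks of ``m`` values each, one per query visit in
    chronological order. For candidate samples ``matched_times`` records the
    candidate visit time that produced each block.
    """

    subject_id: object
    static_block: list
    dynamic_blocks: list
    query_times: list
    matched_times: list | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("a sample needs at least one dynamic block")
        m = len(self.dynamic_blocks[0])
        if any(len(b) != m for b in self.dynamic_blocks):
            raise ValueError("ragged dynamic blocks")

    @property
    def n(self) -> int:
        return len(self.dynamic_blocks)

    @property
    def p(self) -> int:
        return len(self.static_block)

    @property
    def m(self) -> int:
        return len(self.dynamic_blocks[0])

    def __len__(self) -> int:
        return self.p + self.n * self.m

    @property
    def values(self) -> list:
        """Flat vector: static block, then dynamic blocks in order."""
        flat = list(self.static_block)
        for block in self.dynamic_blocks:
            flat.extend(block)
        return flat


@dataclass(frozen=True)
class ComparabilityCount:
    """Pairwise-complete feature counts between two same-shape samples.

    ``adjusted_total`` re-balances static against per-visit-repeated dynamic
    entries: ``n * n_stat + n_dyn``.
    """

    n_stat: int
    n_dyn: int
    n: int

    @property
    def adjusted_total(self) -> int:
        return self.n * self.n_stat + self.n_dyn


def select_window_visits(
    subject: PatientRecord, window_end: float = DEFAULT_WINDOW_END
) -> list:
    """Visits with ``0 <= time <= window_end`` in chronological order."""
    visits = [v for v in subject.visits if 0.0 <= v.time <= window_end]
    if not visits:
        raise NoVisitInWindow(f"patient {subject.id}: no visit in [0, {window_end}]")
    return visits


def build_query_sample(
    subject: PatientRecord,
    schema: RegisterSchema,
    window_end: float = DEFAULT_WINDOW_END,
) -> Sample:
    """Flatten a subject's window visits into the query feature vector."""
    visits = select_window_visits(subject, window_end)
    static_block = [subject.static_values.get(f.name, MISSING) for f in schema.static_features]
    blocks = [
        [v.values.get(f.name, MISSING) for f in schema.dynamic_features] for v in visits
    ]
    return Sample(subject.id, static_block, blocks, [v.time for v in visits])


def match_visits(
    query_times: list,
    candidate: PatientRecord,
    tolerance: float = DEFAULT_TOLERANCE,
    search_end: float | None = None,
) -> list | None:
    """Map each query visit time to the candidate's closest visit.

    For each query time ``t`` the candidate visit minimising ``|time - t|``
    subject to ``|time - t| <= tolerance`` (inclusive) is chosen; equidistant
    visits resolve to the earlier one. The same candidate visit may serve
    several query times. Candidate visits outside ``[0, search_end]``
    (default ``max(query_times) + tolerance``) are not considered.

    Returns the matched :class:`~wknnmi.data_model.Visit` list aligned with
    ``query_times``, or ``None`` when some query time has no match (the
    candidate is then excluded from the neighbour search).
    """
    if not query_times:
        raise ValueError("query_times is empty")
    if search_end is None:
        search_end = max(query_times) + tolerance
    pool = [v for v in candidate.visits if 0.0 <= v.time <= search_end]
    matched = []
    for t in query_times:
        best = None
        best_gap = None
        for v in pool:
            gap = abs(v.time - t)
            if gap > tolerance:
                continue
            # earlier visit wins ties; pool is chronological so strict '<' keeps it
            if best_gap is None or gap < best_gap:
                best, best_gap = v, gap
        if best is None:
            return None
        matched.append(best)
    return matched


def build_candidate_sample(
    query: Sample,
    candidate: PatientRecord,
    schema: RegisterSchema,
    tolerance: float = DEFAULT_TOLERANCE,
) -> Sample | None:
    """Temporally map a candidate onto the query's visit schedule.

    Returns a sample of the query's exact shape (blocks possibly repeated
    when one candidate visit matches several query times, missing values
    passed through), or ``None`` if the candidate is rejected.
    """
    matched = match_visits(query.query_times, candidate, tolerance)
    if matched is None:
        return None
    static_block = [candidate.static_values.get(f.name, MISSING) for f in schema.static_features]
    blocks = [
        [v.values.get(f.name, MISSING) for f in schema.dynamic_features] for v in matched
    ]
    return Sample(
        candidate.id,
        static_block,
        blocks,
        list(query.query_times),
        matched_times=[v.time for v in matched],
    )


def count_comparable(v: Sample, u: Sample) -> ComparabilityCount:
    """Count static/dynamic entries non-missing in *both* samples."""
    if (v.p, v.n, v.m) != (u.p, u.n, u.m):
        raise ValueError("samples have different shapes")
    n_stat = sum(
        1
        for a, b in zip(v.static_block, u.static_block)
        if not is_missing(a) and not is_missing(b)
    )
    n_dyn = sum(
        1
        for bv, bu in zip(v.dynamic_blocks, u.dynamic_blocks)
        for a, b in zip(bv, bu)
        if not is_missing(a) and not is_missing(b)
    )
    return ComparabilityCount(n_stat, n_dyn, v.n)


def query_observed_total(query: Sample) -> int:
    """The query's own visit-adjusted non-missing count ``n*q_stat + q_dyn``."""
    q_stat = sum(1 for a in query.static_block if not is_missing(a))
    q_dyn = sum(1 for b in query.dynamic_blocks for a in b if not is_missing(a))
    return query.n * q_stat + q_dyn


def filter_candidates(
    query: Sample, candidates: list, threshold: float = 0.9
) -> list:
    """Drop candidates sharing fewer than ``threshold`` (90% by default) of
    the query's visit-adjusted non-missing features."""
    cutoff = threshold * query_observed_total(query)
    return [u for u in candidates if count_comparable(query, u).adjusted_total >= cutoff]
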