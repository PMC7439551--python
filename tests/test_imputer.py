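import numpy as np
import pytest

from wknnmi import (
    FeatureSpec,
    ImputationConfig,
    LongitudinalDataset,
    PatientRecord,
    RegisterSchema,
    Visit,
    impute_dataset,
    impute_random_baseline,
    impute_subject,
    write_register,
)
from wknnmi.data_model import MISSING, is_missing
from wknnmi.imputer import (
    DistanceContext,
    IncomparableSamples,
    aggregate_categorical,
    aggregate_numeric,
    normalise_pool,
    pair_distance,
    rank_neighbours,
)
from wknnmi.mutual_info import MIMatrix
from wknnmi.sample_builder import Sample


def ctx_for(n, base_idx, is_static, is_cat, weights):
    return DistanceContext(
        n=n,
        base_idx=np.asarray(base_idx),
        is_static=np.asarray(is_static, bool),
        is_cat=np.asarray(is_cat, bool),
        bounds=np.zeros((max(base_idx) + 1, 2)),
        weight_row=np.asarray(weights, float),
    )


def reference_distance(v, u, ctx):
    """Entry-by-entry evaluation of the weighted visit-adjusted distance —
    the independent oracle for the vectorised implementation."""
    num = den = 0.0
    for i in range(len(v)):
        if np.isnan(v[i]) or np.isnan(u[i]):
            continue
        mult = ctx.n if ctx.is_static[i] else 1.0
        w = ctx.weight_row[ctx.base_idx[i]]
        delta = float(v[i] != u[i]) if ctx.is_cat[i] else abs(v[i] - u[i])
        num += mult * w * delta
        den += mult
    if den == 0:
        raise IncomparableSamples
    return num / den


class TestPairDistance:
    def test_identical_samples_zero(self):
        ctx = ctx_for(2, [0, 1, 1], [True, False, False], [False, False, False], [1, 1])
        v = np.array([0.3, 0.7, 0.1])
        assert pair_distance(v, v, ctx) == 0.0

    def test_unit_weight_hand_value(self):
        """n=1, one continuous static (|delta|=0.5), one categorical dynamic
        mismatch: (1*0.5 + 1) / (1*1 + 1) = 0.75."""
        ctx = ctx_for(1, [0, 1], [True, False], [False, True], [1.0, 1.0])
        assert pair_distance([0.0, 0.0], [0.5, 1.0], ctx) == pytest.approx(0.75, abs=1e-12)

    def test_mi_weight_hand_value(self):
        """Same vectors, weights 0.2 (static) and 1.0:
        (1*0.2*0.5 + 1) / 2 = 0.55."""
        ctx = ctx_for(1, [0, 1], [True, False], [False, True], [0.2, 1.0])
        assert pair_distance([0.0, 0.0], [0.5, 1.0], ctx) == pytest.approx(0.55, abs=1e-12)

    def _random_case(self, rng):
        p, m, n = rng.integers(1, 4), rng.integers(1, 4), rng.integers(1, 5)
        n_base = p + m
        base_idx = np.concatenate([np.arange(p)] + [p + np.arange(m)] * n)
        is_static = np.concatenate([np.ones(p, bool), np.zeros(n * m, bool)])
        is_cat = rng.random(n_base) < 0.4
        entry_cat = is_cat[base_idx]
        L = p + n * m

        def vec():
            x = np.where(entry_cat, rng.integers(0, 3, L).astype(float),
                         rng.random(L))
            x[rng.random(L) < 0.25] = np.nan
            return x

        ctx_unit = ctx_for(n, base_idx, is_static, entry_cat & is_cat[base_idx], None)
        # rebuild with proper weight rows
        return base_idx, is_static, is_cat[base_idx], n, n_base, vec

    def test_unit_weights_equal_unweighted_form_on_fuzzed_pairs(self):
        """The MI-weighted distance with all weights 1 coincides with the
        plain distance, checked against the entry-by-entry oracle."""
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            base_idx, is_static, entry_cat, n, n_base, vec = self._random_case(rng)
            ctx1 = ctx_for(n, base_idx, is_static, entry_cat, np.ones(n_base))
            w = rng.random(n_base) + 0.1
            ctxw = ctx_for(n, base_idx, is_static, entry_cat, w)
            v, u = vec(), vec()
            try:
                ref_unit = reference_distance(v, u, ctx1)
            except IncomparableSamples:
                with pytest.raises(IncomparableSamples):
                    pair_distance(v, u, ctx1)
                continue
            assert pair_distance(v, u, ctx1) == pytest.approx(ref_unit, abs=1e-12)
            assert pair_distance(v, u, ctxw) == pytest.approx(
                reference_distance(v, u, ctxw), abs=1e-12
            )
            checked += 1

    def test_symmetry_and_both_missing_irrelevant(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            base_idx, is_static, entry_cat, n, n_base, vec = self._random_case(rng)
            ctx = ctx_for(n, base_idx, is_static, entry_cat, rng.random(n_base) + 0.1)
            v, u = vec(), vec()
            try:
                d = pair_distance(v, u, ctx)
            except IncomparableSamples:
                continue
            assert pair_distance(u, v, ctx) == pytest.approx(d, abs=1e-15)
            # blank an entry missing in both: distance unchanged
            both = np.isnan(v) & np.isnan(u)
            v2, u2 = v.copy(), u.copy()
            v2[both], u2[both] = np.nan, np.nan
            assert pair_distance(v2, u2, ctx) == pytest.approx(d, abs=1e-15)


class TestNormalisePool:
    def test_min_max_scaling(self, tiny_schema):
        q = Sample("q", [10.0, "f"], [[2, "no"]], [0.0])
        c1 = Sample("a", [20.0, "m"], [[0, "no"]], [0.0])
        c2 = Sample("b", [30.0, "f"], [[4, "yes"]], [0.0])
        Qn, Cn, ctx = normalise_pool(q, [c1, c2], tiny_schema)
        assert Qn[0] == 0.0 and Cn[0, 0] == 0.5 and Cn[1, 0] == 1.0
        assert Qn[2] == 0.5  # ordinal 2 within pooled [0, 4]

    def test_constant_feature_contributes_zero(self, tiny_schema):
        q = Sample("q", [10.0, "f"], [[2, "no"]], [0.0])
        c = Sample("a", [10.0, "m"], [[2, "no"]], [0.0])
        Qn, Cn, ctx = normalise_pool(q, [c], tiny_schema)
        assert Qn[0] == 0.0 and Cn[0, 0] == 0.0

    def test_affine_transform_invariance(self, tiny_schema):
        """Rescaling a raw continuous feature leaves distances unchanged."""
        rng = np.random.default_rng(2)
        ages = rng.normal(60, 10, size=6)
        def pool(scale, shift):
            q = Sample("q", [ages[0] * scale + shift, "f"], [[2, "no"]], [0.0])
            cs = [Sample(f"c{i}", [a * scale + shift, "m"], [[1, "no"]], [0.0])
                  for i, a in enumerate(ages[1:])]
            return normalise_pool(q, cs, tiny_schema)

        Qa, Ca, ctxa = pool(1.0, 0.0)
        Qb, Cb, ctxb = pool(3.0, -7.0)
        for row_a, row_b in zip(Ca, Cb):
            assert pair_distance(Qa, row_a, ctxa) == pytest.approx(
                pair_distance(Qb, row_b, ctxb), abs=1e-12
            )


class TestRankNeighbours:
    def test_brute_force_oracle_equivalence(self, tiny_schema):
        """Selection equals an exhaustive sort of pairwise distances on 200
        random instances with <= 30 candidates."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_cand = int(rng.integers(2, 31))
            def sample(sid):
                age = float(rng.normal(50, 10)) if rng.random() > 0.2 else MISSING
                sex = ("f", "m")[rng.integers(0, 2)] if rng.random() > 0.2 else MISSING
                score = int(rng.integers(0, 5)) if rng.random() > 0.2 else MISSING
                vent = ("no", "yes")[rng.integers(0, 2)] if rng.random() > 0.2 else MISSING
                return Sample(sid, [age, sex], [[score, vent]], [0.0])

            q = sample("q")
            cands = [sample(f"c{i:02d}") for i in range(n_cand)]
            Qn, Cn, ctx = normalise_pool(q, cands, tiny_schema)
            k = int(rng.integers(1, 8))
            try:
                got = rank_neighbours(q, cands, ctx, "score", k, visit_index=0,
                                      schema=tiny_schema, norm_query=Qn, norm_candidates=Cn)
            except Exception:
                got = None
            # brute force: all eligible candidates sorted by (distance, id)
            brute = []
            for i, c in enumerate(cands):
                if is_missing(c.dynamic_blocks[0][0]):
                    continue
                try:
                    d = pair_distance(Qn, Cn[i], ctx)
                except IncomparableSamples:
                    continue
                brute.append((d, str(c.subject_id), c.subject_id))
            brute.sort()
            if not brute:
                assert got is None
                continue
            expected = [b[2] for b in brute[:k]]
            assert got is not None and got.candidate_ids == expected
            assert (np.diff(got.distances) >= -1e-15).all()

    def test_all_donors_missing_target_is_uninputable(self, tiny_schema):
        from wknnmi.imputer import NoEligibleDonor

        q = Sample("q", [50.0, "f"], [[2, "no"]], [0.0])
        cands = [Sample("a", [55.0, "m"], [[MISSING, "no"]], [0.0])]
        Qn, Cn, ctx = normalise_pool(q, cands, tiny_schema)
        with pytest.raises(NoEligibleDonor):
            rank_neighbours(q, cands, ctx, "score", 5, visit_index=0,
                            schema=tiny_schema, norm_query=Qn, norm_candidates=Cn)


class TestAggregation:
    cfg = ImputationConfig()
    cont = FeatureSpec("x", "static", "continuous")
    ordinal = FeatureSpec("o", "dynamic", "ordinal", levels=(0, 1, 2, 3, 4))
    cat = FeatureSpec("c", "static", "categorical", levels=("A", "B"))

    def test_constant_donors(self):
        assert aggregate_numeric([2, 2, 2], [0.1, 0.5, 0.9], self.cont, self.cfg) == 2

    def test_equal_distances_symmetric_mean(self):
        assert aggregate_numeric([1, 3], [0.5, 0.5], self.cont, self.cfg) == pytest.approx(2)

    def test_iqr_outlier_removed(self):
        """{1,2,3,100}: 100 lies above Q3 + 1.5*IQR under the linear-
        interpolation quartile rule, so the mean is over {1,2,3}."""
        got = aggregate_numeric([1, 2, 3, 100], [0.5] * 4, self.cont, self.cfg)
        assert got == pytest.approx(2.0)

    def test_inverse_distance_weighting_pulls_toward_closest(self):
        got = aggregate_numeric([0.0, 4.0], [0.1, 0.9], self.cont, self.cfg)
        expected = (10 * 0.0 + (1 / 0.9) * 4.0) / (10 + 1 / 0.9)
        assert got == pytest.approx(expected)

    def test_zero_distance_uses_epsilon_floor(self):
        got = aggregate_numeric([1.0, 3.0], [0.0, 0.5], self.cont, self.cfg)
        assert got == pytest.approx(1.0, abs=1e-6)  # exact duplicate dominates

    def test_ordinal_rounds_half_up_to_level(self):
        assert aggregate_numeric([1, 2], [0.5, 0.5], self.ordinal, self.cfg) == 2
        cfg_raw = ImputationConfig(round_ordinal=False)
        assert aggregate_numeric([1, 2], [0.5, 0.5], self.ordinal, cfg_raw) == pytest.approx(1.5)

    def test_mode(self):
        assert aggregate_categorical(["A", "A", "B"], [0.9, 0.8, 0.1], self.cat) == "A"

    def test_mode_tie_broken_by_closest_donor(self):
        assert aggregate_categorical(["A", "B"], [0.9, 0.2], self.cat) == "B"

    def test_single_donor(self):
        assert aggregate_categorical(["B"], [0.4], self.cat) == "B"


def planted_duplicate_dataset(n=30, seed=5):
    """y (static continuous) equals x exactly; donors are exact matches."""
    schema = RegisterSchema(
        (
            FeatureSpec("x", "static", "continuous"),
            FeatureSpec("y", "static", "continuous"),
            FeatureSpec("score", "dynamic", "ordinal", levels=(0, 1, 2, 3, 4)),
        )
    )
    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        x = float(rng.uniform(0, 10))
        visits = [Visit(0.0, {"score": int(rng.integers(0, 5))})]
        patients.append(PatientRecord(f"p{i}", {"x": x, "y": x}, visits))
    return LongitudinalDataset(schema, patients)


class TestImputeSubject:
    def test_no_missing_returns_unchanged(self, tiny_dataset):
        pt = tiny_dataset.patients[0]
        out, prov = impute_subject(pt, tiny_dataset, None, ImputationConfig(method="wknn"))
        assert prov == []
        assert out.static_values == pt.static_values

    def test_planted_duplicate_recovered(self):
        ds = planted_duplicate_dataset()
        subject = ds.patients[0].copy()
        truth = subject.static_values["y"]
        subject.static_values["y"] = MISSING
        mi = MIMatrix(np.ones((3, 3)), ds.schema.feature_names)
        # strong weight on the duplicated source feature
        mi.values[1, 0] = mi.values[0, 1] = 5.0
        out, prov = impute_subject(subject, ds, mi, ImputationConfig(k=1, method="wknn_mi"))
        assert out.static_values["y"] == pytest.approx(truth, abs=0.2)

    def test_uniform_mi_matrix_reduces_to_unweighted(self, masked_cohort):
        ds = masked_cohort.masked_dataset()
        schema = ds.schema
        uniform = MIMatrix(np.ones((len(schema), len(schema))), schema.feature_names)
        subject = next(
            p for p in ds.patients
            if any(is_missing(v) for v in p.static_values.values())
        )
        cfg_mi = ImputationConfig(k=10, method="wknn_mi")
        cfg_plain = ImputationConfig(k=10, method="wknn")
        out_mi, prov_mi = impute_subject(subject, ds, uniform, cfg_mi)
        out_plain, prov_plain = impute_subject(subject, ds, None, cfg_plain)
        assert write_register(
            LongitudinalDataset(schema, [out_mi])
        ).equals(write_register(LongitudinalDataset(schema, [out_plain])))

    def test_only_missing_entries_change(self, masked_cohort):
        ds = masked_cohort.masked_dataset()
        subject = ds.patients[0]
        out, _ = impute_subject(subject, ds, None, ImputationConfig(method="wknn"))
        for name, val in subject.static_values.items():
            if not is_missing(val):
                assert out.static_values[name] == val
        for v_in, v_out in zip(subject.visits, out.visits):
            for name, val in v_in.values.items():
                if not is_missing(val):
                    assert v_out.values[name] == val


class TestImputeDataset:
    def test_fully_observed_is_identity(self, masked_cohort):
        complete = masked_cohort.complete
        res = impute_dataset(complete, "self", ImputationConfig(method="wknn"))
        assert res.n_imputed == 0
        assert write_register(res.dataset).equals(write_register(complete))

    def test_self_mode_donors_are_exactly_the_others(self, masked_cohort):
        ds = masked_cohort.masked_dataset()
        res = impute_dataset(ds, "self", ImputationConfig(k=5, method="wknn"))
        ids = {p.id for p in ds.patients}
        for rec in res.provenance:
            assert rec["subject_id"] not in rec["donors"]
            assert set(rec["donors"]) <= ids - {rec["subject_id"]}

    def test_external_mode_ignores_other_query_subjects(self, masked_cohort):
        """Imputing a held-out subject is invariant to arbitrary corruption
        of the other held-out subjects."""
        ds = masked_cohort.masked_dataset()
        test_ds = ds.subset([p.id for p in ds.patients[:6]])
        train_ds = ds.subset([p.id for p in ds.patients[6:]])
        cfg = ImputationConfig(k=10, method="wknn_mi")
        baseline = impute_dataset(test_ds, train_ds, cfg)
        corrupted = test_ds.copy()
        for pt in corrupted.patients[1:]:
            for f, v in pt.static_values.items():
                if isinstance(v, float):
                    pt.static_values[f] = v + 1000.0
        again = impute_dataset(corrupted, train_ds, cfg)
        first = LongitudinalDataset(ds.schema, [baseline.dataset.patients[0]])
        first2 = LongitudinalDataset(ds.schema, [again.dataset.patients[0]])
        assert write_register(first).equals(write_register(first2))

    def test_imputed_values_within_donor_range_and_levels(self, masked_cohort):
        ds = masked_cohort.masked_dataset()
        res = impute_dataset(ds, "self", ImputationConfig(k=10, method="wknn_mi"))
        schema = ds.schema
        assert res.n_imputed > 0
        for rec in res.provenance:
            if rec["imputed"] is None:
                continue
            spec = schema[rec["feature"]]
            if spec.is_numeric:
                donors = [float(v) for v in rec["donor_values"]]
                assert min(donors) - 1e-9 <= float(rec["imputed"]) <= max(donors) + 1e-9
            if spec.scale in ("ordinal", "categorical"):
                assert rec["imputed"] in spec.levels


class TestRandomBaseline:
    def test_deterministic_given_seed(self, masked_cohort):
        ds = masked_cohort.masked_dataset()
        cfg = ImputationConfig(k=5, method="krn", seed=99)
        a = impute_dataset(ds, "self", cfg)
        b = impute_dataset(ds, "self", cfg)
        assert write_register(a.dataset).equals(write_register(b.dataset))

    def test_k_at_least_pool_uses_everyone(self):
        ds = planted_duplicate_dataset(n=6)
        subject = ds.patients[0].copy()
        subject.static_values["y"] = MISSING
        cfg = ImputationConfig(k=50, method="krn", seed=0)
        out, prov = impute_random_baseline(subject, ds, cfg)
        assert len(prov[0]["donors"]) == 5  # all other patients

    def test_equal_aggregation_weights(self):
        ds = planted_duplicate_dataset(n=8)
        subject = ds.patients[0].copy()
        subject.static_values["y"] = MISSING
        cfg = ImputationConfig(k=3, method="krn", seed=1)
        _out, prov = impute_random_baseline(subject, ds, cfg)
        assert len(set(prov[0]["distances"])) == 1
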