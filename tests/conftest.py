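import pytest

from wknnmi import (
    FeatureSpec,
    LongitudinalDataset,
    PatientRecord,
    RegisterSchema,
    SyntheticConfig,
    Visit,
    als_register_schema,
    generate_cohort,
    inject_missingness,
)


@pytest.fixture(scope="session")
def als_schema():
    return als_register_schema()


@pytest.fixture(scope="session")
def tiny_schema():
    """2 static + 2 dynamic features, one of each scale family."""
    return RegisterSchema(
        (
            FeatureSpec("age", "static", "continuous", units="years"),
            FeatureSpec("sex", "static", "categorical", levels=("f", "m")),
            FeatureSpec("score", "dynamic", "ordinal", levels=(0, 1, 2, 3, 4)),
            FeatureSpec("vent", "dynamic", "categorical", levels=("no", "yes")),
        )
    )


def make_patient(pid, age, sex, rows, **kw):
    """rows: list of (time, score, vent)."""
    visits = [Visit(t, {"score": s, "vent": v}) for t, s, v in rows]
    return PatientRecord(pid, {"age": age, "sex": sex}, visits, **kw)


@pytest.fixture
def tiny_dataset(tiny_schema):
    patients = [
        make_patient("a", 50.0, "f", [(0.0, 4, "no"), (1.0, 3, "no"), (2.0, 3, "yes")]),
        make_patient("b", 60.0, "m", [(0.0, 2, "no"), (1.1, 1, "yes")]),
        make_patient("c", 55.0, "f", [(0.0, 4, "no"), (0.9, 4, "no")]),
        make_patient("d", 70.0, "m", [(0.0, 1, "yes"), (2.0, 0, "yes")]),
        make_patient("e", 52.0, "f", [(0.0, 3, "no"), (1.0, 3, "no")]),
    ]
    return LongitudinalDataset(tiny_schema, patients)


@pytest.fixture(scope="session")
def masked_cohort():
    """The reference synthetic scenario with 10% MCAR, fixed seed."""
    gt = inject_missingness(generate_cohort(SyntheticConfig(n_subjects=80, seed=11)))
    return gt


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size reference scenario (200 subjects) for recovery checks."""
    return inject_missingness(generate_cohort(SyntheticConfig(seed=1)))
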