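"""Domain types and I/O for longitudinal mixed-type clinical registers.

A register is stored in *long format*: one row per patient visit, with the
static features (constant across a patient's visits) repeated on every row.
Each feature is declared in a :class:`RegisterSchema` as static or dynamic and
as continuous, ordinal or categorical; ordinal and categorical features carry
an explicit list of admissible levels.

Missing values are represented by a single sentinel, :data:`MISSING` (``None``
at the Python level); they never leak into feature space as magic numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MISSING",
    "is_missing",
    "FeatureSpec",
    "RegisterSchema",
    "Visit",
    "PatientRecord",
    "LongitudinalDataset",
    "SchemaError",
    "ValidationError",
    "load_schema",
    "load_register",
    "write_register",
    "summarise_dataset",
    "stratified_split",
    "als_register_schema",
]

#: Sentinel for a missing value anywhere in the data model.
MISSING = None

TEMPORAL_KINDS = ("static", "dynamic")
SCALES = ("continuous", "ordinal", "categorical")


def is_missing(value) -> bool:
    """True for the missing sentinel, ``None``, or a float NaN."""
    if value is None:
        return True
    if isinstance(value, float) and np.isnan(value):
        return True
    return False


class SchemaError(ValueError):
    """Malformed schema declaration."""


class ValidationError(ValueError):
    """Data that does not conform to its schema."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one register feature.

    Parameters
    ----------
    name : str
        Unique feature identifier (column name in the long-format table).
    temporal_kind : {"static", "dynamic"}
        Static features are constant across a patient's visits; dynamic ones
        are re-measured at every visit.
    scale : {"continuous", "ordinal", "categorical"}
    levels : tuple, optional
        Admissible values, required for ordinal (totally ordered,
        numeric-codable) and categorical (unordered) features; must be absent
        for continuous ones.
    units : str, optional
        Free-text measurement units.
    """

    name: str
    temporal_kind: str
    scale: str
    levels: tuple | None = None
    units: str | None = None

    def __post_init__(self):
        if self.temporal_kind not in TEMPORAL_KINDS:
            raise SchemaError(f"{self.name}: unknown temporal_kind {self.temporal_kind!r}")
        if self.scale not in SCALES:
            raise SchemaError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "continuous":
            if self.levels is not None:
                raise SchemaError(f"{self.name}: continuous features take no levels")
        else:
            if not self.levels:
                raise SchemaError(f"{self.name}: {self.scale} features require levels")
            object.__setattr__(self, "levels", tuple(self.levels))
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"{self.name}: duplicate levels")
            if self.scale == "ordinal":
                try:
                    codes = [float(v) for v in self.levels]
                except (TypeError, ValueError) as exc:
                    raise SchemaError(f"{self.name}: ordinal levels must be numeric-codable") from exc
                if codes != sorted(codes):
                    raise SchemaError(f"{self.name}: ordinal levels must be sorted")

    @property
    def is_static(self) -> bool:
        return self.temporal_kind == "static"

    @property
    def is_numeric(self) -> bool:
        """Continuous or ordinal: enters distances through ``|v - u|``."""
        return self.scale in ("continuous", "ordinal")

    def check_value(self, value):
        """Return ``value`` (level-coerced for discrete scales) or raise."""
        if is_missing(value):
            return MISSING
        if self.scale == "continuous":
            try:
                return float(value)
            except (TypeError, ValueError) as exc:
                raise ValidationError(f"{self.name}: non-numeric value {value!r}") from exc
        for lev in self.levels:
            if value == lev:
                return lev
            # long-format CSV round-trips numeric levels through strings/floats
            try:
                if float(value) == float(lev):
                    return lev
            except (TypeError, ValueError):
                pass
        raise ValidationError(f"{self.name}: value {value!r} not in levels {self.levels}")


@dataclass(frozen=True)
class RegisterSchema:
    """Ordered feature declarations for one register.

    ``p`` static features precede nothing in particular in the file, but all
    derived feature vectors use schema order: statics first, then dynamics.
    """

    features: tuple

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(self.features))
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate feature names")

    @property
    def static_features(self) -> tuple:
        return tuple(f for f in self.features if f.is_static)

    @property
    def dynamic_features(self) -> tuple:
        return tuple(f for f in self.features if not f.is_static)

    @property
    def p(self) -> int:
        """Number of static features."""
        return len(self.static_features)

    @property
    def m(self) -> int:
        """Number of dynamic features."""
        return len(self.dynamic_features)

    @property
    def feature_names(self) -> list:
        return [f.name for f in self.features]

    def __len__(self) -> int:
        return len(self.features)

    def __getitem__(self, name: str) -> FeatureSpec:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)


@dataclass
class Visit:
    """One screening visit: time in months since the patient's first visit."""

    time: float
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = float(self.time)
        if self.time < 0:
            raise ValidationError(f"visit time {self.time} < 0")


@dataclass
class PatientRecord:
    """A patient's static values, chronologically sorted visits and outcome.

    ``survival_time`` is months from the first visit to death (``event ==
    'deceased'``) or last contact (``event == 'censored'``); both are optional
    and only needed by the survival-sample constructor.
    """

    id: object
    static_values: dict = field(default_factory=dict)
    visits: list = field(default_factory=list)
    survival_time: float | None = None
    event: str | None = None

    def __post_init__(self):
        times = [v.time for v in self.visits]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(f"patient {self.id}: visits not strictly sorted by time")
        if self.visits and self.visits[0].time != 0.0:
            raise ValidationError(f"patient {self.id}: first visit not at time 0")
        if self.survival_time is not None and self.survival_time < 0:
            raise ValidationError(f"patient {self.id}: negative survival time")
        if self.event is not None and self.event not in ("deceased", "censored"):
            raise ValidationError(f"patient {self.id}: unknown event {self.event!r}")

    def copy(self) -> "PatientRecord":
        return PatientRecord(
            id=self.id,
            static_values=dict(self.static_values),
            visits=[Visit(v.time, dict(v.values)) for v in self.visits],
            survival_time=self.survival_time,
            event=self.event,
        )


@dataclass
class LongitudinalDataset:
    """A schema plus a list of patients conforming to it."""

    schema: RegisterSchema
    patients: list = field(default_factory=list)

    def __post_init__(self):
        ids = [pt.id for pt in self.patients]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate patient ids")
        for pt in self.patients:
            self._validate_patient(pt)

    def _validate_patient(self, pt: PatientRecord):
        static_names = {f.name for f in self.schema.static_features}
        dynamic_names = {f.name for f in self.schema.dynamic_features}
        for name in pt.static_values:
            if name not in static_names:
                raise ValidationError(f"patient {pt.id}: unknown static feature {name!r}")
        for name, value in pt.static_values.items():
            pt.static_values[name] = self.schema[name].check_value(value)
        for visit in pt.visits:
            for name in visit.values:
                if name not in dynamic_names:
                    raise ValidationError(f"patient {pt.id}: unknown dynamic feature {name!r}")
            for name, value in visit.values.items():
                visit.values[name] = self.schema[name].check_value(value)

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, patient_id) -> PatientRecord:
        for pt in self.patients:
            if pt.id == patient_id:
                return pt
        raise KeyError(patient_id)

    def copy(self) -> "LongitudinalDataset":
        return LongitudinalDataset(self.schema, [pt.copy() for pt in self.patients])

    def subset(self, patient_ids) -> "LongitudinalDataset":
        wanted = set(patient_ids)
        return LongitudinalDataset(self.schema, [pt for pt in self.patients if pt.id in wanted])


# ---------------------------------------------------------------------------
# Schema I/O


def _spec_from_mapping(entry: dict) -> FeatureSpec:
    try:
        name = entry["name"]
        temporal_kind = entry["temporal_kind"]
        scale = entry["scale"]
    except KeyError as exc:
        raise SchemaError(f"schema entry missing key {exc}") from exc
    levels = entry.get("levels")
    if levels is not None:
        levels = tuple(levels)
    return FeatureSpec(name, temporal_kind, scale, levels, entry.get("units"))


def load_schema(path_or_stream) -> RegisterSchema:
    """Read a YAML/JSON schema file: a list (or ``{features: [...]}``) of
    per-feature mappings with keys name/temporal_kind/scale/levels/units."""
    if hasattr(path_or_stream, "read"):
        raw = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream) as fh:
            raw = yaml.safe_load(fh)
    if isinstance(raw, dict):
        raw = raw.get("features", raw)
    if not isinstance(raw, list):
        raise SchemaError("schema file must contain a list of feature entries")
    return RegisterSchema(tuple(_spec_from_mapping(e) for e in raw))


def save_schema(schema: RegisterSchema, path):
    entries = []
    for f in schema.features:
        entry = {"name": f.name, "temporal_kind": f.temporal_kind, "scale": f.scale}
        if f.levels is not None:
            entry["levels"] = list(f.levels)
        if f.units is not None:
            entry["units"] = f.units
        entries.append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)


def als_register_schema() -> RegisterSchema:
    """The packaged ALS-register-like schema.

    11 static features (sex, premorbid and at-diagnosis BMI, FVC at
    diagnosis, familiality, genetics, FTD, onset site, age at onset,
    diagnostic delay, onset delta) and 14 dynamic ones (the 12 ALSFRS-R
    items scored 0-4, plus the NIV and PEG intervention indicators).
    """
    import importlib.resources as res

    with res.files("wknnmi").joinpath("schemas/als_register.yaml").open() as fh:
        return load_schema(fh)


# ---------------------------------------------------------------------------
# Register I/O

ID_COL = "patient_id"
TIME_COL = "visit_time"
SURV_TIME_COL = "survival_time"
EVENT_COL = "event"


def load_register(visits_table, schema, *, id_col=ID_COL, time_col=TIME_COL) -> LongitudinalDataset:
    """Load a long-format register (CSV path, buffer or DataFrame).

    Static values are taken from each patient's rows (an error if they
    conflict within a patient); visit times are re-based so every patient's
    first visit sits at 0; empty cells stay missing.
    """
    if isinstance(schema, (str, bytes)) or hasattr(schema, "read"):
        schema = load_schema(schema)
    if isinstance(visits_table, pd.DataFrame):
        df = visits_table.copy()
    else:
        df = pd.read_csv(visits_table)
    if id_col not in df.columns or time_col not in df.columns:
        raise ValidationError(f"table must have {id_col!r} and {time_col!r} columns")
    known = {id_col, time_col, SURV_TIME_COL, EVENT_COL} | set(schema.feature_names)
    unknown = set(df.columns) - known
    if unknown:
        raise ValidationError(f"unknown columns: {sorted(unknown)}")
    missing_cols = set(schema.feature_names) - set(df.columns)
    if missing_cols:
        raise ValidationError(f"schema features absent from table: {sorted(missing_cols)}")

    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any():
        raise ValidationError("non-numeric visit time")
    df = df.assign(**{time_col: times})

    patients = []
    for pid, grp in df.groupby(id_col, sort=False):
        grp = grp.sort_values(time_col)
        t0 = grp[time_col].iloc[0]
        static_values = {}
        for f in schema.static_features:
            observed = [v for v in grp[f.name] if not is_missing(v)]
            coerced = {repr(f.check_value(v)) for v in observed}
            if len(coerced) > 1:
                raise ValidationError(
                    f"patient {pid}: static feature {f.name!r} varies across rows"
                )
            static_values[f.name] = f.check_value(observed[0]) if observed else MISSING
        visits = []
        for _, row in grp.iterrows():
            values = {
                f.name: f.check_value(row[f.name]) if not is_missing(row[f.name]) else MISSING
                for f in schema.dynamic_features
            }
            visits.append(Visit(row[time_col] - t0, values))
        surv, event = None, None
        if SURV_TIME_COL in grp.columns:
            sv = grp[SURV_TIME_COL].iloc[0]
            if not is_missing(sv):
                surv = float(sv)
        if EVENT_COL in grp.columns:
            ev = grp[EVENT_COL].iloc[0]
            if not is_missing(ev):
                event = str(ev)
        patients.append(PatientRecord(pid, static_values, visits, surv, event))
    return LongitudinalDataset(schema, patients)


def write_register(ds: LongitudinalDataset, path_or_buf=None, *, id_col=ID_COL, time_col=TIME_COL):
    """Write a dataset back to long-format CSV (inverse of :func:`load_register`)."""
    rows = []
    has_surv = any(pt.survival_time is not None for pt in ds.patients)
    for pt in ds.patients:
        for visit in pt.visits:
            row = {id_col: pt.id, time_col: visit.time}
            for f in ds.schema.static_features:
                row[f.name] = pt.static_values.get(f.name, MISSING)
            for f in ds.schema.dynamic_features:
                row[f.name] = visit.values.get(f.name, MISSING)
            if has_surv:
                row[SURV_TIME_COL] = pt.survival_time
                row[EVENT_COL] = pt.event
            rows.append(row)
    cols = [id_col, time_col] + ds.schema.feature_names
    if has_surv:
        cols += [SURV_TIME_COL, EVENT_COL]
    df = pd.DataFrame(rows, columns=cols)
    if path_or_buf is None:
        return df
    df.to_csv(path_or_buf, index=False)
    return df


# ---------------------------------------------------------------------------
# Summaries


def _feature_observations(ds: LongitudinalDataset, spec: FeatureSpec) -> list:
    """All value slots for a feature: one per patient (static) or per visit
    (dynamic), missing included."""
    if spec.is_static:
        return [pt.static_values.get(spec.name, MISSING) for pt in ds.patients]
    return [v.values.get(spec.name, MISSING) for pt in ds.patients for v in pt.visits]


def quantile(values, q) -> float:
    """Linear-interpolation ("type 7") quantile, the convention used for every
    quartile/IQR in this package."""
    return float(np.quantile(np.asarray(values, dtype=float), q, method="linear"))


def summarise_dataset(ds: LongitudinalDataset) -> pd.DataFrame:
    """Per-feature summary: missing %, quartiles (continuous/ordinal) or level
    frequencies (categorical).

    Missing percentages are computed over the unit at which the feature lives:
    per patient for static features, per visit for dynamic ones.
    """
    if not ds.patients:
        raise ValidationError("empty dataset")
    rows = []
    for spec in ds.schema.features:
        obs = _feature_observations(ds, spec)
        n_total = len(obs)
        present = [v for v in obs if not is_missing(v)]
        row = {
            "feature": spec.name,
            "temporal_kind": spec.temporal_kind,
            "scale": spec.scale,
            "n_slots": n_total,
            "missing_pct": 100.0 * (n_total - len(present)) / n_total if n_total else 100.0,
        }
        if spec.is_numeric:
            if present:
                vals = [float(v) for v in present]
                row["q25"], row["q50"], row["q75"] = (quantile(vals, q) for q in (0.25, 0.5, 0.75))
            else:
                row["q25"] = row["q50"] = row["q75"] = np.nan
        else:
            counts = {lev: 0 for lev in spec.levels}
            for v in present:
                counts[v] += 1
            row["level_freqs"] = (
                {lev: c / len(present) for lev, c in counts.items()} if present else {}
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Stratified splitting


def _balance_columns(ds: LongitudinalDataset) -> np.ndarray:
    """Patient x column matrix used to score split balance.

    Continuous/ordinal features contribute their per-patient mean (dynamic
    features averaged over the patient's visits); each categorical level
    contributes a 0/1 indicator. Missing -> NaN.
    """
    cols = []
    for spec in ds.schema.features:
        per_patient = []
        for pt in ds.patients:
            if spec.is_static:
                vals = [pt.static_values.get(spec.name, MISSING)]
            else:
                vals = [v.values.get(spec.name, MISSING) for v in pt.visits]
            vals = [v for v in vals if not is_missing(v)]
            per_patient.append(vals)
        if spec.is_numeric:
            cols.append(
                [np.mean([float(v) for v in vals]) if vals else np.nan for vals in per_patient]
            )
        else:
            for lev in spec.levels:
                cols.append(
                    [
                        np.mean([1.0 if v == lev else 0.0 for v in vals]) if vals else np.nan
                        for vals in per_patient
                    ]
                )
    return np.asarray(cols, dtype=float).T


def stratified_split(
    ds: LongitudinalDataset,
    test_fraction: float,
    seed: int,
    n_candidates: int = 1000,
):
    """Patient-level train/test split balanced over all variables.

    Among ``n_candidates`` seeded random splits, returns the one minimising
    the sum over features of absolute train-test differences in summary
    statistics (means for continuous/ordinal, level frequencies for
    categorical). Deterministic given ``seed``.

    Returns ``(train, test)`` :class:`LongitudinalDataset` pair.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    n = len(ds.patients)
    if n < 2:
        raise ValidationError("need at least 2 patients to split")
    n_test = int(round(n * test_fraction))
    n_test = min(max(n_test, 1), n - 1)

    matrix = _balance_columns(ds)
    rng = np.random.default_rng(seed)
    best_score, best_test_idx = np.inf, None
    for _ in range(n_candidates):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        with np.errstate(invalid="ignore"):
            diff = np.nanmean(matrix[train_idx], axis=0) - np.nanmean(matrix[test_idx], axis=0)
        score = np.nansum(np.abs(diff))
        if score < best_score:
            best_score, best_test_idx = score, test_idx
    test_ids = {ds.patients[i].id for i in best_test_idx}
    train = LongitudinalDataset(ds.schema, [pt for pt in ds.patients if pt.id not in test_ids])
    test = LongitudinalDataset(ds.schema, [pt for pt in ds.patients if pt.id in test_ids])
    return train, test
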