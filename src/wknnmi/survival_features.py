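"""Fixed-length survival samples from the first months of screening visits.

Each patient's window visits are condensed into one vector: the ``p`` static
values plus, for every dynamic feature, three derived features — the minimum,
the maximum, and the slope of a least-squares line of value against visit
time in months — giving ``p + 3*m`` entries (53 for the packaged ALS-like
schema). The binary outcome answers "does the subject survive more than
``horizon`` (36) months from the first screening visit?"; patients censored
before the horizon are excluded because the question cannot be answered for
them. Native missing values are carried through into the samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    MISSING,
    FeatureSpec,
    LongitudinalDataset,
    PatientRecord,
    is_missing,
)
from .sample_builder import DEFAULT_WINDOW_END, NoVisitInWindow, select_window_visits

__all__ = [
    "SurvivalSample",
    "derive_dynamic_summaries",
    "build_survival_samples",
    "survival_frame",
    "make_dataset_variants",
]

LABEL_LONG = "long"
LABEL_SHORT = "short"


@dataclass
class SurvivalSample:
    """One patient's fixed-length survival feature vector and label."""

    subject_id: object
    values: dict  # feature name -> value (static) or derived (min/max/slope)
    label: str

    def __len__(self) -> int:
        return len(self.values)


def _numeric(spec: FeatureSpec, value) -> float:
    """Dynamic values on a numeric axis for min/max/slope; binary
    interventions (and any categorical) encode as their level index (0/1)."""
    if spec.scale == "categorical":
        return float(spec.levels.index(value))
    return float(value)


def derive_dynamic_summaries(
    subject: PatientRecord,
    spec: FeatureSpec,
    window_end: float = DEFAULT_WINDOW_END,
):
    """(min, max, slope) of one dynamic feature over the window visits.

    Slope is the least-squares slope of value against time (months), defined
    only with >= 2 observations at distinct times; all three are missing when
    nothing is observed.
    """
    window = select_window_visits(subject, window_end)
    points = [
        (v.time, _numeric(spec, v.values[spec.name]))
        for v in window
        if not is_missing(v.values.get(spec.name, MISSING))
    ]
    if not points:
        return MISSING, MISSING, MISSING
    values = [val for _, val in points]
    vmin, vmax = min(values), max(values)
    times = [t for t, _ in points]
    if len(set(times)) < 2:
        return vmin, vmax, MISSING
    slope = float(np.polyfit(times, values, 1)[0])
    return vmin, vmax, slope


def _label(subject: PatientRecord, horizon: float):
    """'long' / 'short' / None (None = censored before horizon, excluded).

    Death at exactly the horizon counts as short (strict "more than");
    censoring at or after the horizon means the subject was alive then.
    """
    if subject.survival_time is None or subject.event is None:
        raise ValueError(f"patient {subject.id}: survival metadata required")
    if subject.event == "deceased":
        return LABEL_LONG if subject.survival_time > horizon else LABEL_SHORT
    return LABEL_LONG if subject.survival_time >= horizon else None


def build_survival_samples(
    ds: LongitudinalDataset,
    horizon: float = 36.0,
    window_end: float = DEFAULT_WINDOW_END,
) -> list:
    """Survival samples for every labellable patient with window visits."""
    samples = []
    for pt in ds.patients:
        label = _label(pt, horizon)
        if label is None:
            continue
        try:
            select_window_visits(pt, window_end)
        except NoVisitInWindow:
            continue
        values = {}
        for f in ds.schema.static_features:
            values[f.name] = pt.static_values.get(f.name, MISSING)
        for f in ds.schema.dynamic_features:
            vmin, vmax, slope = derive_dynamic_summaries(pt, f, window_end)
            values[f"{f.name}_min"] = vmin
            values[f"{f.name}_max"] = vmax
            values[f"{f.name}_slope"] = slope
        samples.append(SurvivalSample(pt.id, values, label))
    return samples


def survival_frame(samples: list) -> pd.DataFrame:
    """Samples as a DataFrame (index = subject id, last column = label)."""
    rows = []
    for s in samples:
        row = {"subject_id": s.subject_id, **s.values, "label": s.label}
        rows.append(row)
    df = pd.DataFrame(rows).set_index("subject_id")
    return df.where(pd.notna(df), other=np.nan)


def make_dataset_variants(
    train: LongitudinalDataset,
    imputers: dict | None = None,
    horizon: float = 36.0,
    window_end: float = DEFAULT_WINDOW_END,
) -> dict:
    """The survival-sample set variants used to probe imputation impact.

    ``original``: native missing values carried through. ``complete_cases``:
    only samples with zero missing entries. ``complete_features``: only
    derived columns with zero missing entries. Plus one variant per entry of
    ``imputers`` (label -> callable mapping a dataset to an imputed dataset),
    applied to the visits *before* sample construction.
    """
    original = survival_frame(build_survival_samples(train, horizon, window_end))
    feature_cols = [c for c in original.columns if c != "label"]
    variants = {"original": original}

    complete_cases = original.dropna(axis=0, subset=feature_cols)
    if complete_cases.empty:
        raise ValueError("complete-cases variant is empty")
    variants["complete_cases"] = complete_cases

    keep = [c for c in feature_cols if not original[c].isna().any()]
    if not keep:
        raise ValueError("complete-features variant is empty")
    variants["complete_features"] = original[keep + ["label"]]

    for label, imputer in (imputers or {}).items():
        imputed_ds = imputer(train)
        variants[label] = survival_frame(build_survival_samples(imputed_ds, horizon, window_end))
    return variants
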