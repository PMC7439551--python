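"""Synthetic ALS-register-like cohorts with known ground truth.

The generator emulates the structure of a progression register built from
screening visits: per-subject visit schedules with 1-4 roughly monthly
visits in the first three months (plus follow-up visits used only for donor
matching), 12 correlated ordinal 0-4 functional items declining with a
per-subject latent progression rate, monotone binary intervention
indicators that switch on as decline accumulates, correlated continuous
static features, survival times tied to the progression rate, and
configurable MCAR/MAR missingness applied on top of a fully observed ground
truth.

One static feature is deterministically tied to an observed one (BMI at
diagnosis = premorbid BMI minus a fixed shift), planting a relationship
that a well-functioning MI-weighted imputer must recover almost exactly —
the workhorse of the recovery tests. Premorbid BMI is drawn uniformly so
the planted relationship has dense support everywhere, and a configurable
set of columns is never masked (real registers likewise have fully observed
columns: sex, onset site, age at onset, diagnostic delay), which keeps the
tie's source and the MAR covariates observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .data_model import (
    MISSING,
    LongitudinalDataset,
    PatientRecord,
    Visit,
    als_register_schema,
    is_missing,
)
from .evaluation import EvaluationReport
from .imputer import ImputationResult
from .sample_builder import DEFAULT_WINDOW_END

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "inject_missingness",
    "score_against_truth",
]

ITEM_NAMES = [f"alsfrs_{i}" for i in range(1, 13)]
# per-item difficulty offsets, shaped so medians roughly fall like a real
# functional scale (respiratory item near ceiling, fine-motor items lower)
ITEM_OFFSETS = np.array([0.6, 0.2, 0.7, 0.9, 1.4, 1.4, 1.0, 1.1, 1.8, 0.4, 0.3, -0.6])
BULBAR_ITEMS = slice(0, 3)  # speech/salivation/swallowing analogues
LIMB_ITEMS = slice(3, 9)


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults are the package's reference
    scenario (200 subjects, 10% MCAR, item noise sd 0.5)."""

    n_subjects: int = 200
    #: probability of 1, 2, 3 or 4 visits inside the query window
    visit_count_probs: tuple = (0.1, 0.2, 0.35, 0.35)
    visit_spacing: float = 0.9  # months between consecutive visits
    visit_jitter: float = 0.15  # uniform +- jitter on each spacing
    followup_months: float = 8.0  # visits keep accruing this long
    rate_shape: float = 2.0  # gamma shape of the progression rate (points/month)
    rate_scale: float = 0.15
    severity_sd: float = 0.8  # per-subject baseline severity latent
    item_noise_sd: float = 0.5
    bmi_range: tuple = (19.0, 31.0)  # uniform support of premorbid BMI
    bmi_shift: float = 1.2  # deterministic tie: bmi_dx = bmi_pre - shift
    niv_threshold: float = 2.2  # cumulative decline that triggers NIV
    peg_threshold: float = 2.8
    missing_rate: float = 0.1
    mechanism: str = "MCAR"
    mar_log_odds: float = 1.0  # shift for male / bulbar strata under MAR
    #: columns that are never masked, like the register's fully observed ones
    never_missing: tuple = (
        "sex", "age_at_onset", "diagnostic_delay", "onset_delta", "bmi_premorbid",
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not np.isclose(sum(self.visit_count_probs), 1.0):
            raise ValueError("visit_count_probs must sum to 1")


#: a mask cell: (patient_id, feature_name, visit_time or None for static)
MaskCell = tuple


@dataclass
class GroundTruth:
    """A fully observed cohort, the injected missingness mask, and the
    configuration that generated both."""

    complete: LongitudinalDataset
    mask: list = field(default_factory=list)
    config: SyntheticConfig | None = None

    def masked_dataset(self) -> LongitudinalDataset:
        """The cohort with the mask applied (what the imputer sees)."""
        ds = self.complete.copy()
        for pid, feature, time in self.mask:
            pt = ds[pid]
            if time is None:
                pt.static_values[feature] = MISSING
            else:
                for v in pt.visits:
                    if v.time == time:
                        v.values[feature] = MISSING
                        break
        return ds

    def true_value(self, pid, feature, time):
        pt = self.complete[pid]
        if time is None:
            return pt.static_values[feature]
        for v in pt.visits:
            if v.time == time:
                return v.values[feature]
        raise KeyError((pid, feature, time))


def _visit_times(rng, cfg) -> np.ndarray:
    n_window = rng.choice([1, 2, 3, 4], p=cfg.visit_count_probs)
    times = [0.0]
    t = 0.0
    while True:
        t += cfg.visit_spacing + rng.uniform(-cfg.visit_jitter, cfg.visit_jitter)
        if t > cfg.followup_months:
            break
        times.append(round(t, 3))
    # keep at most n_window visits inside the query window, all later ones
    window = [x for x in times if x <= DEFAULT_WINDOW_END][:n_window]
    later = [x for x in times if x > DEFAULT_WINDOW_END]
    return np.array(window + later)


def generate_cohort(cfg: SyntheticConfig | None = None) -> GroundTruth:
    """Draw a fully observed cohort under the packaged ALS-like schema.

    Deterministic given ``cfg.seed``; the returned ground truth has an empty
    mask (apply :func:`inject_missingness` for a masked view).
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    schema = als_register_schema()
    patients = []
    for i in range(cfg.n_subjects):
        sex = "male" if rng.random() < 0.52 else "female"
        onset_site = "bulbar" if rng.random() < 0.34 else "limb"
        genetics = rng.choice(
            ["C9orf72", "FUS", "SOD1", "TARDBP", "wild_type"],
            p=[0.08, 0.01, 0.02, 0.02, 0.87],
        )
        # familial cases mostly carry a known mutation; FTD tracks C9orf72
        familiality = "yes" if rng.random() < (0.85 if genetics != "wild_type" else 0.03) else "no"
        ftd = "yes" if rng.random() < (0.6 if genetics == "C9orf72" else 0.1) else "no"
        rate = rng.gamma(cfg.rate_shape, cfg.rate_scale)  # points/month
        severity = abs(rng.normal(0.6, cfg.severity_sd))  # baseline deficit
        age = float(np.clip(rng.normal(63.0, 10.0), 25.0, 90.0))
        delay = float(np.clip(rng.lognormal(np.log(9.0), 0.6), 1.0, 60.0))
        onset_delta = -(delay + rng.uniform(0.0, 4.0))
        bmi_pre = float(rng.uniform(*cfg.bmi_range))
        bmi_dx = bmi_pre - cfg.bmi_shift  # deterministic tie
        fvc = float(np.clip(rng.normal(100.0 - 25.0 * rate - 8.0 * severity, 12.0), 20.0, 150.0))
        statics = {
            "sex": sex,
            "bmi_premorbid": bmi_pre,
            "bmi_diagnosis": bmi_dx,
            "fvc_diagnosis": fvc,
            "familiality": familiality,
            "genetics": genetics,
            "ftd": ftd,
            "onset_site": onset_site,
            "age_at_onset": age,
            "diagnostic_delay": delay,
            "onset_delta": onset_delta,
        }
        site_shift = np.zeros(12)
        if onset_site == "bulbar":
            site_shift[BULBAR_ITEMS] = 1.0
        else:
            site_shift[LIMB_ITEMS] = 0.7
        visits = []
        for t in _visit_times(rng, cfg):
            decline = severity + rate * t
            raw = (
                4.0
                - decline
                - ITEM_OFFSETS
                - site_shift
                + rng.normal(0.0, cfg.item_noise_sd, size=12)
            )
            items = np.clip(np.round(raw), 0, 4).astype(int)
            values = {name: int(v) for name, v in zip(ITEM_NAMES, items)}
            values["niv"] = "yes" if decline > cfg.niv_threshold else "no"
            values["peg"] = "yes" if decline > cfg.peg_threshold else "no"
            visits.append(Visit(float(t), values))
        # survival: faster progressors die sooner; independent censoring
        surv = float(6.0 + 55.0 * np.exp(-2.5 * rate) + rng.exponential(6.0))
        censor = float(rng.uniform(6.0, 110.0))
        if censor < surv:
            survival_time, event = censor, "censored"
        else:
            survival_time, event = surv, "deceased"
        patients.append(
            PatientRecord(f"S{i:04d}", statics, visits, survival_time, event)
        )
    return GroundTruth(LongitudinalDataset(schema, patients), [], cfg)


def _maskable_cells(ds: LongitudinalDataset, window_end: float, never_missing=()) -> list:
    """Static cells plus in-window dynamic cells — the entries the windowed
    imputer is responsible for — minus the always-observed columns."""
    cells = []
    skip = set(never_missing)
    for pt in ds.patients:
        for f in ds.schema.static_features:
            if f.name not in skip and not is_missing(pt.static_values.get(f.name, MISSING)):
                cells.append((pt.id, f.name, None))
        for v in pt.visits:
            if not 0.0 <= v.time <= window_end:
                continue
            for f in ds.schema.dynamic_features:
                if f.name not in skip and not is_missing(v.values.get(f.name, MISSING)):
                    cells.append((pt.id, f.name, v.time))
    return cells


def inject_missingness(
    gt: GroundTruth,
    mechanism: str | None = None,
    rate: float | None = None,
    seed: int | None = None,
    window_end: float = DEFAULT_WINDOW_END,
) -> GroundTruth:
    """Mask cells of a fully observed cohort; returns a new GroundTruth
    carrying the mask.

    MCAR masks every maskable cell independently with probability ``rate``.
    MAR shifts the masking log-odds by ``mar_log_odds`` for male subjects —
    sex is never masked, so the probability depends only on an observed
    covariate, never on the masked value itself.
    """
    cfg = gt.config or SyntheticConfig()
    mechanism = mechanism or cfg.mechanism
    rate = cfg.missing_rate if rate is None else rate
    seed = cfg.seed if seed is None else seed
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cells = _maskable_cells(gt.complete, window_end, cfg.never_missing)
    mask = []
    base_logit = np.log(rate / (1.0 - rate)) if rate > 0 else -np.inf
    for pid, feature, time in cells:
        if mechanism == "MCAR":
            p = rate
        else:
            pt = gt.complete[pid]
            shift = cfg.mar_log_odds if pt.static_values.get("sex") == "male" else 0.0
            p = 1.0 / (1.0 + np.exp(-(base_logit + shift))) if rate > 0 else 0.0
        if rng.random() < p:
            mask.append((pid, feature, time))
    masked_per_patient = {}
    for pid, _f, _t in mask:
        masked_per_patient[pid] = masked_per_patient.get(pid, 0) + 1
    totals = {}
    for pid, _f, _t in cells:
        totals[pid] = totals.get(pid, 0) + 1
    for pid, nm in masked_per_patient.items():
        if nm == totals[pid]:
            warnings.warn(f"mask removes the entire record of patient {pid}")
    return GroundTruth(gt.complete, mask, replace(cfg, mechanism=mechanism, missing_rate=rate))


def score_against_truth(imputed, gt: GroundTruth, method: str = "") -> EvaluationReport:
    """Score an imputation exactly over the masked cells.

    ``imputed`` may be an :class:`~wknnmi.imputer.ImputationResult` or a
    plain dataset. Cells left missing count as uninputable and are excluded
    from the metrics.
    """
    ds = imputed.dataset if isinstance(imputed, ImputationResult) else imputed
    if not gt.mask:
        raise ValueError("ground truth carries no mask")
    report = EvaluationReport(method=method)
    for pid, feature, time in gt.mask:
        true = gt.true_value(pid, feature, time)
        pt = ds[pid]
        if time is None:
            got = pt.static_values.get(feature, MISSING)
        else:
            got = next((v.values.get(feature, MISSING) for v in pt.visits if v.time == time), MISSING)
        if is_missing(got):
            report.n_uninputable += 1
            continue
        report.records.append(
            {"subject_id": pid, "feature": feature,
             "visit_index": None if time is None else time, "true": true, "imputed": got}
        )
    return report
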