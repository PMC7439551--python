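"""Masking experiments and imputation quality metrics.

Quality is scored per feature over the ``T`` cells imputed in an experiment:
range-normalised root-mean-square deviation (nRMSD) for continuous/ordinal
features, proportion of falsely classified (PFC) for categorical ones, plus
a per-cell normalised absolute error (nAE) used for paired significance
tests. The normalising range is the range of the *true* values of the
evaluated cells — exactly what the formulas divide by — not the range over
the whole dataset.

The masking protocol removes, for one subject and one feature at a time, all
that feature's measured values from the subject's window visits, re-imputes
them from the untouched donors, and compares against the held-back truth;
masking one feature at a time keeps the dataset's native missingness pattern
essentially intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import MISSING, LongitudinalDataset, is_missing
from .imputer import ImputationConfig, impute_subject
from .mutual_info import MIMatrix, compute_mi_matrix
from .sample_builder import NoVisitInWindow, select_window_visits

__all__ = [
    "nrmsd",
    "pfc",
    "nae",
    "MaskingPlan",
    "EvaluationReport",
    "build_masking_plan",
    "run_masking_evaluation",
    "cross_validate_k",
    "compare_methods",
]


def nrmsd(true_values, imputed_values) -> float:
    """Root-mean-square deviation divided by the range of the true values.

    Returns NaN ("undefined") when the true values have zero range; such
    features are excluded from averages.
    """
    t = np.asarray(true_values, dtype=float)
    m = np.asarray(imputed_values, dtype=float)
    if t.size != m.size or t.size == 0:
        raise ValueError("need equal-length non-empty vectors")
    rng = t.max() - t.min()
    if rng == 0:
        return math.nan
    return float(np.sqrt(np.mean((t - m) ** 2)) / rng)


def pfc(true_values, imputed_values) -> float:
    """Proportion of falsely classified: the fraction of mismatches."""
    if len(true_values) != len(imputed_values) or len(true_values) == 0:
        raise ValueError("need equal-length non-empty vectors")
    wrong = sum(1 for t, m in zip(true_values, imputed_values) if t != m)
    return wrong / len(true_values)


def nae(true_value, imputed_value, feature_range: float) -> float:
    """Normalised absolute error of a single imputed value."""
    if feature_range == 0:
        return math.nan
    return abs(float(true_value) - float(imputed_value)) / feature_range


@dataclass(frozen=True)
class MaskingTask:
    subject_id: object
    feature: str
    #: (visit_index or None, true value) pairs for the masked cells
    cells: tuple


@dataclass
class MaskingPlan:
    """One task per (subject, feature) with at least one observed value."""

    tasks: list


@dataclass
class EvaluationReport:
    """Per-feature metrics and per-cell records from a masking experiment."""

    method: str
    #: records: subject_id, feature, visit_index, true, imputed
    records: list = field(default_factory=list)
    n_uninputable: int = 0

    def _feature_pairs(self):
        pairs = {}
        for r in self.records:
            pairs.setdefault(r["feature"], []).append((r["true"], r["imputed"]))
        return pairs

    def per_feature(self, schema) -> pd.DataFrame:
        """Feature x metric table (nRMSD for continuous/ordinal, PFC for
        categorical), with imputed-cell counts."""
        rows = []
        for feature, pairs in self._feature_pairs().items():
            spec = schema[feature]
            t = [p[0] for p in pairs]
            m = [p[1] for p in pairs]
            if spec.is_numeric:
                value, metric = nrmsd(t, m), "nrmsd"
            else:
                value, metric = pfc(t, m), "pfc"
            rows.append(
                {"feature": feature, "scale": spec.scale, "metric": metric,
                 "value": value, "n_cells": len(pairs)}
            )
        return pd.DataFrame(rows).set_index("feature")

    def nae_records(self, schema) -> pd.DataFrame:
        """Per-cell nAE for continuous/ordinal features, range taken over the
        true values of the feature's evaluated cells."""
        pairs = self._feature_pairs()
        rows = []
        for feature, fp in pairs.items():
            if not schema[feature].is_numeric:
                continue
            truths = np.asarray([p[0] for p in fp], dtype=float)
            rng = truths.max() - truths.min()
            for r in self.records:
                if r["feature"] != feature:
                    continue
                rows.append(
                    {**{k: r[k] for k in ("subject_id", "feature", "visit_index")},
                     "nae": nae(r["true"], r["imputed"], rng)}
                )
        return pd.DataFrame(rows)

    def class_averages(self, schema) -> dict:
        """Plain feature means of the per-feature metrics, by scale class."""
        table = self.per_feature(schema)
        out = {}
        for scale in ("continuous", "ordinal", "categorical"):
            sub = table[table["scale"] == scale]["value"].dropna()
            out[scale] = float(sub.mean()) if len(sub) else math.nan
        return out


def build_masking_plan(ds: LongitudinalDataset, window_end: float) -> MaskingPlan:
    """All (subject, feature) tasks with >= 1 observed window value.

    For a static feature the single static cell is masked; for a dynamic one
    every observed cell of the subject's window visits is masked at once.
    """
    tasks = []
    for pt in ds.patients:
        try:
            window = select_window_visits(pt, window_end)
        except NoVisitInWindow:
            continue
        for f in ds.schema.static_features:
            v = pt.static_values.get(f.name, MISSING)
            if not is_missing(v):
                tasks.append(MaskingTask(pt.id, f.name, ((None, v),)))
        for f in ds.schema.dynamic_features:
            cells = tuple(
                (idx, visit.values[f.name])
                for idx, visit in enumerate(window)
                if not is_missing(visit.values.get(f.name, MISSING))
            )
            if cells:
                tasks.append(MaskingTask(pt.id, f.name, cells))
    return MaskingPlan(tasks)


def _masked_subject(subject, task, window_end):
    masked = subject.copy()
    if task.cells[0][0] is None:
        masked.static_values[task.feature] = MISSING
    else:
        window = select_window_visits(masked, window_end)
        for idx, _true in task.cells:
            window[idx].values[task.feature] = MISSING
    return masked


def run_masking_evaluation(
    ds: LongitudinalDataset,
    methods: dict,
    donor_pool: LongitudinalDataset | str = "self",
    mi: MIMatrix | None = None,
    plan: MaskingPlan | None = None,
) -> dict:
    """Score one or more imputation configurations under identical masks.

    ``methods`` maps a label to an :class:`ImputationConfig`. Donors are the
    other patients of ``ds`` ("self") or an external pool; either way they
    keep their original values while one (subject, feature) is masked at a
    time. Returns ``{label: EvaluationReport}``. Cells that no donor could
    impute are counted and excluded.
    """
    if not ds.patients:
        raise ValueError("empty dataset")
    window_ends = {cfg.window_end for cfg in methods.values()}
    if len(window_ends) != 1:
        raise ValueError("all configurations must share window_end")
    window_end = window_ends.pop()
    if plan is None:
        plan = build_masking_plan(ds, window_end)
    external = not isinstance(donor_pool, str)
    pool_ds = donor_pool if external else ds
    mi_by_label = {}
    for label, cfg in methods.items():
        if cfg.method == "wknn_mi":
            mi_by_label[label] = mi if mi is not None else compute_mi_matrix(pool_ds, window_end)
    reports = {label: EvaluationReport(method=cfg.method) for label, cfg in methods.items()}
    rng_streams = {
        label: np.random.SeedSequence(cfg.seed).spawn(len(plan.tasks))
        for label, cfg in methods.items()
        if cfg.method == "krn"
    }
    for t_idx, task in enumerate(plan.tasks):
        subject = ds[task.subject_id]
        masked = _masked_subject(subject, task, window_end)
        for label, cfg in methods.items():
            rng = (
                np.random.default_rng(rng_streams[label][t_idx])
                if cfg.method == "krn"
                else None
            )
            imputed, _prov = impute_subject(masked, pool_ds, mi_by_label.get(label), cfg, rng)
            window = select_window_visits(imputed, window_end)
            for visit_index, true in task.cells:
                if visit_index is None:
                    got = imputed.static_values.get(task.feature, MISSING)
                else:
                    got = window[visit_index].values.get(task.feature, MISSING)
                if is_missing(got):
                    reports[label].n_uninputable += 1
                    continue
                reports[label].records.append(
                    {"subject_id": task.subject_id, "feature": task.feature,
                     "visit_index": visit_index, "true": true, "imputed": got}
                )
    return reports


def _overall_score(report: EvaluationReport, schema) -> float:
    """Simple average of the numeric-class mean nRMSD and the categorical
    mean PFC (classes with no defined metric are skipped)."""
    table = report.per_feature(schema)
    numeric = table[table["metric"] == "nrmsd"]["value"].dropna()
    categ = table[table["metric"] == "pfc"]["value"].dropna()
    parts = [s.mean() for s in (numeric, categ) if len(s)]
    return float(np.mean(parts)) if parts else math.nan


def cross_validate_k(
    ds: LongitudinalDataset,
    k_grid=(5, 10, 15, 20, 25),
    folds: int = 10,
    method: str = "wknn_mi",
    seed: int = 0,
    cfg: ImputationConfig | None = None,
) -> tuple:
    """Select the neighbour count by fold-held-out masking evaluation.

    Patients are partitioned into ``folds`` seeded folds; for each ``k``,
    each fold's subjects are masked one feature at a time and imputed using
    all out-of-fold patients as donors. The selected ``k`` minimises the
    pooled overall error (mean of numeric-class nRMSD and categorical-class
    PFC feature means).

    Returns ``(table, best_k)`` where ``table`` is a per-k DataFrame.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not k_grid:
        raise ValueError("empty k grid")
    n = len(ds.patients)
    if folds > n:
        raise ValueError("more folds than patients")
    base = cfg or ImputationConfig(method=method)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for pos, idx in enumerate(order):
        fold_of[idx] = pos % folds
    rows = []
    best_k, best_score = None, np.inf
    for k in k_grid:
        cfg_k = ImputationConfig(**{**base.__dict__, "k": int(k), "method": method})
        records = []
        n_unimputable = 0
        for fold in range(folds):
            held = ds.subset([ds.patients[i].id for i in range(n) if fold_of[i] == fold])
            donors = ds.subset([ds.patients[i].id for i in range(n) if fold_of[i] != fold])
            reports = run_masking_evaluation(held, {"m": cfg_k}, donor_pool=donors)
            records.extend(reports["m"].records)
            n_unimputable += reports["m"].n_uninputable
        merged = EvaluationReport(method=method, records=records, n_uninputable=n_unimputable)
        score = _overall_score(merged, ds.schema)
        rows.append({"k": int(k), "score": score, "n_cells": len(records),
                     "n_uninputable": n_unimputable})
        if score < best_score:
            best_score, best_k = score, int(k)
    return pd.DataFrame(rows).set_index("k"), best_k


def compare_methods(report_a: EvaluationReport, report_b: EvaluationReport, schema) -> pd.DataFrame:
    """Paired per-feature significance tests between two reports.

    Continuous/ordinal features: two-tailed Wilcoxon signed-rank on the
    paired nAE values with zero-inclusive ("pratt") ranking. Categorical
    features: McNemar's test on the paired correct/incorrect 2x2 table. The
    reports must come from identical masking plans.
    """
    from statsmodels.stats.contingency_tables import mcnemar

    def keyed(report):
        return {
            (r["subject_id"], r["feature"], r["visit_index"]): r for r in report.records
        }

    a, b = keyed(report_a), keyed(report_b)
    common = sorted(set(a) & set(b), key=str)
    if not common:
        raise ValueError("reports share no imputed cells")
    nae_a = report_a.nae_records(schema)
    nae_b = report_b.nae_records(schema)

    rows = []
    for spec in schema.features:
        keys = [kk for kk in common if kk[1] == spec.name]
        if not keys:
            continue
        if spec.is_numeric:
            sub_a = nae_a[nae_a["feature"] == spec.name].set_index(["subject_id", "visit_index"])
            sub_b = nae_b[nae_b["feature"] == spec.name].set_index(["subject_id", "visit_index"])
            idx = [(kk[0], kk[2]) for kk in keys]
            xa = sub_a.loc[idx, "nae"].to_numpy(dtype=float)
            xb = sub_b.loc[idx, "nae"].to_numpy(dtype=float)
            if np.allclose(xa, xb):
                pvalue, test = 1.0, "wilcoxon_pratt(all ties)"
            else:
                res = stats.wilcoxon(xa, xb, zero_method="pratt", alternative="two-sided")
                pvalue, test = float(res.pvalue), "wilcoxon_pratt"
            stat_summary = {"mean_a": float(np.mean(xa)), "mean_b": float(np.mean(xb))}
        else:
            ok_a = np.array([a[kk]["true"] == a[kk]["imputed"] for kk in keys])
            ok_b = np.array([b[kk]["true"] == b[kk]["imputed"] for kk in keys])
            table = np.array(
                [[np.sum(ok_a & ok_b), np.sum(ok_a & ~ok_b)],
                 [np.sum(~ok_a & ok_b), np.sum(~ok_a & ~ok_b)]]
            )
            if table[0, 1] + table[1, 0] == 0:
                pvalue, test = 1.0, "mcnemar(no discordant pairs)"
            else:
                res = mcnemar(table, exact=True)
                pvalue, test = float(res.pvalue), "mcnemar_exact"
            stat_summary = {
                "pfc_a": float(np.mean(~ok_a)), "pfc_b": float(np.mean(~ok_b))
            }
        rows.append(
            {"feature": spec.name, "scale": spec.scale, "test": test,
             "p_value": pvalue, "n_pairs": len(keys), **stat_summary}
        )
    return pd.DataFrame(rows).set_index("feature")
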