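"""End-to-end validation of the screening score on a labelled cohort.

Mirrors how a clinical prediction rule is externally validated: a descriptive
table comparing OSA with non-OSA subjects (chi-squared or Fisher for
categorical variables, t-test or Mann–Whitney for continuous ones), ROC/AUC
per PSG stratum for both the diagnostic (AHI >= 5/h) and the moderate/severe
(AHI >= 15/h) outcome, a single cutoff selected on the full cohort at the
diagnostic threshold under a sensitivity >= 95% constraint and reused
everywhere, and the full diagnostic-accuracy battery per stratum x threshold.

Subjects with missing predictors are scored through the classifier's exact
marginalized inference, never dropped; subjects with a missing AHI cannot be
labelled and are excluded from validation (and counted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .cohort import (
    DEFAULT_ENCODING,
    MODEL_VARIABLES,
    EncodingConfig,
    PatientRecord,
    encode_record,
)
from .metrics import (
    DiagnosticReport,
    ROCResult,
    accuracy_metrics,
    auc_confidence_interval,
    confusion_from_scores,
    reconstruct_confusion,
    roc_curve,
    select_cutoff,
)
from .tan import TANClassifier

__all__ = [
    "ValidationSpec",
    "StudyReport",
    "describe_cohort",
    "run_validation",
    "reconstruct_report",
]


@dataclass(frozen=True)
class ValidationSpec:
    """What to validate: outcome thresholds, strata, cutoff policy, CI methods."""

    ahi_thresholds: tuple[float, ...] = (5.0, 15.0)
    strata: tuple[str, ...] = ("all", "III", "I")
    cutoff: float | str = "auto"  # "auto" = sensitivity-constrained selection
    min_sensitivity: float = 0.95
    ci_method: str = "wilson"
    auc_ci_method: str = "delong"
    continuous_test: str = "auto"  # "auto" (Shapiro gate) / "t" / "mw"

    def validate(self) -> None:
        if list(self.ahi_thresholds) != sorted(self.ahi_thresholds) or min(self.ahi_thresholds) <= 0:
            raise ValueError("ahi_thresholds must be positive and increasing")
        if isinstance(self.cutoff, str):
            if self.cutoff != "auto":
                raise ValueError("cutoff must be a probability or 'auto'")
        elif not 0 < self.cutoff < 1:
            raise ValueError("numeric cutoff must lie in (0, 1)")
        if self.continuous_test not in ("auto", "t", "mw"):
            raise ValueError("continuous_test must be 'auto', 't' or 'mw'")


@dataclass
class StudyReport:
    """Everything the validation produces, serializable to JSON/CSV."""

    cutoff: float
    cells: dict  # (stratum, threshold) -> dict with auc/auc_ci/n/n_pos/report
    descriptive: pd.DataFrame | None = None
    n_excluded_missing_ahi: int = 0
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        cells = {}
        for (stratum, thr), cell in self.cells.items():
            key = f"{stratum}|ahi>={thr:g}"
            out = {k: cell[k] for k in ("n", "n_pos", "auc", "auc_ci", "insufficient")}
            out["report"] = cell["report"].to_dict() if cell["report"] is not None else None
            cells[key] = out
        return {
            "cutoff": self.cutoff,
            "n_excluded_missing_ahi": self.n_excluded_missing_ahi,
            "cells": cells,
            "descriptive": None if self.descriptive is None
            else self.descriptive.to_dict(orient="records"),
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True, allow_nan=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    def metrics_table(self) -> pd.DataFrame:
        """Metrics as rows, stratum x threshold as columns (printed precision)."""
        columns = {}
        for (stratum, thr), cell in self.cells.items():
            name = f"AHI>={thr:g}/h {stratum}"
            if cell["report"] is None:
                columns[name] = {}
            else:
                columns[name] = cell["report"].printed()
        return pd.DataFrame(columns)


# ---------------------------------------------------------------------------
# descriptive table


_CATEGORICAL = [
    ("male_gender", lambda r: None if r.sex is None else (r.sex == "male")),
    ("nc_increased", None),  # from the encoder
    ("witnessed_apneas", lambda r: r.witnessed_apneas),
    ("nocturia", lambda r: r.nocturia),
    ("cfa", lambda r: r.cfa),
    ("obese", None),  # BMI threshold
    ("ess_increased", None),  # ESS threshold
    ("snoring", lambda r: r.snoring),
    ("morning_headache", lambda r: r.morning_headache),
    ("non_restful_sleep", lambda r: r.non_restful_sleep),
    ("hypertension", lambda r: r.hypertension),
    ("diabetes", lambda r: r.diabetes),
    ("dyslipidemia", lambda r: r.dyslipidemia),
    ("cardiac_pathology", lambda r: r.cardiac_pathology),
    ("stroke", lambda r: r.stroke),
    ("depression", lambda r: r.depression),
]

_CONTINUOUS = [
    ("age_years", lambda r: r.age_years),
    ("neck_circumference_cm", lambda r: r.neck_circumference_cm),
    ("bmi", lambda r: r.bmi_kg_m2),
    ("ess", lambda r: None if r.ess_score is None else float(r.ess_score)),
]


def _categorical_test(a_pos: int, a_n: int, b_pos: int, b_n: int) -> tuple[float | None, str]:
    """Chi-squared on the 2x2 group-by-level table; Fisher if any expected < 5."""
    table = np.array([[a_pos, a_n - a_pos], [b_pos, b_n - b_pos]], dtype=float)
    if a_n == 0 or b_n == 0:
        return None, "none (empty group)"
    if table.sum(axis=0).min() == 0:  # constant variable: no test, no signal
        return 1.0, "none (constant variable)"
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if expected.min() < 5:
        _, p = stats.fisher_exact(table.astype(int))
        return float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table)
    return float(p), "chi2"


def _shapiro_normal(x: np.ndarray) -> bool:
    if x.size < 3:
        return False
    if x.size > 5000:
        x = np.sort(x)[:: max(1, x.size // 5000)][:5000]
    if np.ptp(x) == 0:
        return False
    return stats.shapiro(x).pvalue > 0.05


def describe_cohort(
    records: list[PatientRecord],
    encoding: EncodingConfig = DEFAULT_ENCODING,
    ahi_threshold: float = 5.0,
    continuous_test: str = "auto",
) -> pd.DataFrame:
    """Group comparison table (non-OSA vs OSA), one row per variable.

    Categorical variables: n (%) per group with chi-squared, or Fisher's exact
    when any expected 2x2 cell is below 5.  Continuous variables: mean (SD)
    with Welch's t-test when both groups pass Shapiro–Wilk at 5%, otherwise
    median (IQR) with Mann–Whitney.  P-values are reported unadjusted.
    Subjects with missing AHI are excluded (the grouping is undefined).
    """
    labelled = [r for r in records if r.ahi_events_per_hour is not None]
    groups = {False: [], True: []}
    for r in labelled:
        groups[r.ahi_events_per_hour >= ahi_threshold].append(r)
    n_by_group = {k: len(v) for k, v in groups.items()}

    def getter(name):
        if name == "nc_increased":
            return lambda r: {"yes": True, "no": False, None: None}[encode_record(r, encoding).nc_increased]
        if name == "obese":
            return lambda r: None if r.bmi_kg_m2 is None else r.bmi_kg_m2 >= encoding.obesity_bmi_threshold
        if name == "ess_increased":
            return lambda r: None if r.ess_score is None else r.ess_score >= encoding.ess_increased_threshold
        return dict(_CATEGORICAL)[name]

    rows = []
    for name, fn in _CATEGORICAL:
        fn = fn or getter(name)
        vals = {g: [v for v in map(fn, rs) if v is not None] for g, rs in groups.items()}
        n_missing = len(labelled) - sum(len(v) for v in vals.values())
        counts = {g: int(np.sum(vals[g])) for g in (False, True)}
        ns = {g: len(vals[g]) for g in (False, True)}
        if ns[False] == 0 and ns[True] == 0:
            rows.append({"variable": name, "type": "categorical", "normal": "-", "osa": "-",
                         "p_value": None, "test": "none (all missing)", "n_missing": n_missing})
            continue
        p, test = _categorical_test(counts[False], ns[False], counts[True], ns[True])

        def pct(g):
            return "-" if ns[g] == 0 else f"{counts[g]} ({100 * counts[g] / ns[g]:.0f}%)"

        rows.append({"variable": name, "type": "categorical", "normal": pct(False),
                     "osa": pct(True), "p_value": p, "test": test, "n_missing": n_missing})

    for name, fn in _CONTINUOUS:
        vals = {g: np.array([v for v in map(fn, rs) if v is not None], dtype=float)
                for g, rs in groups.items()}
        n_missing = len(labelled) - sum(v.size for v in vals.values())
        if vals[False].size == 0 or vals[True].size == 0:
            rows.append({"variable": name, "type": "continuous", "normal": "-", "osa": "-",
                         "p_value": None, "test": "none (empty group)", "n_missing": n_missing})
            continue
        if continuous_test == "t":
            use_t = True
        elif continuous_test == "mw":
            use_t = False
        else:
            use_t = _shapiro_normal(vals[False]) and _shapiro_normal(vals[True])
        if use_t:
            p = float(stats.ttest_ind(vals[False], vals[True], equal_var=False).pvalue)
            summ = {g: f"{vals[g].mean():.1f} ({vals[g].std(ddof=1):.1f})" for g in (False, True)}
            test = "welch-t"
        else:
            if np.ptp(np.concatenate([vals[False], vals[True]])) == 0:
                p, test = 1.0, "none (constant variable)"
            else:
                p = float(stats.mannwhitneyu(vals[False], vals[True]).pvalue)
                test = "mann-whitney"
            summ = {g: f"{np.median(vals[g]):.1f} ({np.percentile(vals[g], 25):.1f}-"
                       f"{np.percentile(vals[g], 75):.1f})" for g in (False, True)}
        rows.append({"variable": name, "type": "continuous", "normal": summ[False],
                     "osa": summ[True], "p_value": p, "test": test, "n_missing": n_missing})

    df = pd.DataFrame(rows)
    df.attrs["n_per_group"] = {"normal": n_by_group[False], "osa": n_by_group[True]}
    return df


# ---------------------------------------------------------------------------
# validation runs


def _scores_and_frame(cohort, model, scores, encoding) -> pd.DataFrame:
    """Normalize the cohort to a frame with score / ahi / psg_type columns."""
    if isinstance(cohort, pd.DataFrame):
        df = cohort.copy()
        if "ahi" not in df.columns:
            raise ValueError("encoded cohort frame needs an 'ahi' column")
        if "psg_type" not in df.columns:
            df["psg_type"] = None
        if scores is None:
            if model is None:
                if "score" in df.columns:
                    scores = df["score"].to_numpy(dtype=float)
                else:
                    raise ValueError("provide a model or a score column")
            else:
                scores = model.predict_osa_probability(df[list(model.feature_names_in_)])
        out = pd.DataFrame({"score": np.asarray(scores, dtype=float),
                            "ahi": df["ahi"].to_numpy(dtype=float),
                            "psg_type": df["psg_type"].to_numpy(dtype=object)})
        return out
    records: list[PatientRecord] = list(cohort)
    if scores is None:
        if model is None:
            raise ValueError("provide a model or precomputed scores")
        encoded = [encode_record(r, encoding) for r in records]
        scores = model.predict_osa_probability(encoded)
    ahi = np.array([np.nan if r.ahi_events_per_hour is None else r.ahi_events_per_hour
                    for r in records], dtype=float)
    psg = np.array([r.psg_type for r in records], dtype=object)
    return pd.DataFrame({"score": np.asarray(scores, dtype=float), "ahi": ahi, "psg_type": psg})


def run_validation(
    cohort,
    model: TANClassifier | None = None,
    scores=None,
    spec: ValidationSpec = ValidationSpec(),
    encoding: EncodingConfig = DEFAULT_ENCODING,
    descriptive: bool = True,
    provenance: dict | None = None,
) -> StudyReport:
    """The full validation: ROC/AUC per stratum x threshold, cutoff, reports.

    ``cohort`` is a list of :class:`PatientRecord` or an encoded DataFrame
    with the model variables plus ``ahi`` (and optionally ``psg_type`` /
    ``score``).  The cutoff is selected once, on the full cohort at the first
    (diagnostic) threshold, and reused for every stratum and threshold; the
    selection is guaranteed to meet the sensitivity floor or the run fails.
    Deterministic given (cohort, spec): row order does not matter.
    """
    spec.validate()
    frame = _scores_and_frame(cohort, model, scores, encoding)
    n_missing_ahi = int(frame["ahi"].isna().sum())
    frame = frame[frame["ahi"].notna()].reset_index(drop=True)
    if len(frame) == 0:
        raise ValueError("no subjects with an AHI: nothing to validate")

    labels5 = frame["ahi"].to_numpy() >= spec.ahi_thresholds[0]
    if spec.cutoff == "auto":
        roc_all = roc_curve(frame["score"], labels5)
        cutoff = select_cutoff(roc_all, spec.min_sensitivity)
        achieved = confusion_from_scores(frame["score"], labels5, cutoff)
        sens = achieved.tp / achieved.positives
        if sens < spec.min_sensitivity:  # guaranteed by construction; fail loudly if not
            raise AssertionError(f"selected cutoff reaches sensitivity {sens:.3f} "
                                 f"< floor {spec.min_sensitivity}")
    else:
        cutoff = float(spec.cutoff)

    cells = {}
    for thr in spec.ahi_thresholds:
        labels = frame["ahi"].to_numpy() >= thr
        for stratum in spec.strata:
            sel = np.ones(len(frame), dtype=bool) if stratum == "all" \
                else (frame["psg_type"].to_numpy(dtype=object) == stratum)
            s, y = frame["score"].to_numpy()[sel], labels[sel]
            cell = {"n": int(sel.sum()), "n_pos": int(y.sum()),
                    "auc": None, "auc_ci": None, "insufficient": False,
                    "roc": None, "report": None}
            if cell["n"] == 0:
                cell["insufficient"] = True
            elif y.all() or not y.any():
                cell["insufficient"] = True  # single class: AUC undefined
                cell["report"] = accuracy_metrics(
                    confusion_from_scores(s, y, cutoff), spec.ci_method, cutoff)
            else:
                roc = roc_curve(s, y)
                cell["roc"] = roc
                cell["auc"] = roc.auc
                if roc.n_pos >= 2 and roc.n_neg >= 2:
                    cell["auc_ci"] = list(auc_confidence_interval(roc, spec.auc_ci_method))
                cell["report"] = accuracy_metrics(
                    confusion_from_scores(s, y, cutoff), spec.ci_method, cutoff)
            cells[(stratum, float(thr))] = cell

    desc = None
    if descriptive and not isinstance(cohort, pd.DataFrame):
        desc = describe_cohort(list(cohort), encoding, spec.ahi_thresholds[0],
                               spec.continuous_test)
    prov = {"package_version": _pkg_version, "spec": {
        "ahi_thresholds": list(spec.ahi_thresholds), "strata": list(spec.strata),
        "cutoff": spec.cutoff, "min_sensitivity": spec.min_sensitivity,
        "ci_method": spec.ci_method, "auc_ci_method": spec.auc_ci_method}}
    if provenance:
        prov.update(provenance)
    return StudyReport(cutoff=cutoff, cells=cells, descriptive=desc,
                       n_excluded_missing_ahi=n_missing_ahi, provenance=prov)


def reconstruct_report(
    n: int, n_pos: int, sensitivity: float, specificity: float,
    ci_method: str = "wilson", cutoff: float | None = None,
) -> DiagnosticReport:
    """Full metric battery from printed (n, positives, sensitivity, specificity)."""
    table = reconstruct_confusion(n, n_pos, sensitivity, specificity)
    return accuracy_metrics(table, ci_method=ci_method, cutoff=cutoff)
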