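"""Diagnostic test accuracy: ROC/AUC, cutoff selection and the 2x2 metric battery.

The screening score is validated the way clinical prediction rules are: a ROC
curve over the score, AUC with a DeLong confidence interval, a cutoff chosen to
guarantee sensitivity >= 95%, and at that cutoff the full set of diagnostic
accuracy measures (sensitivity, specificity, predictive values, likelihood
ratios, pre-/post-test odds, diagnostic odds ratio, F-score) with 95% CIs.
A subject is called screen-positive when the score is strictly greater than
the cutoff.

Integer 2x2 tables can also be reconstructed from printed summary statistics
(n, positives, sensitivity, specificity) — the bridge from a published report
to exact counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionTable",
    "Estimate",
    "DiagnosticReport",
    "ROCResult",
    "CutoffUnattainableError",
    "confusion_from_scores",
    "reconstruct_confusion",
    "accuracy_metrics",
    "ratio_metrics_from_rates",
    "roc_curve",
    "auc_confidence_interval",
    "compare_auc_independent",
    "select_cutoff",
    "round_half_away",
]

Z95 = norm.ppf(0.975)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed tables)."""
    if not math.isfinite(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


class CutoffUnattainableError(ValueError):
    """No operating point satisfies the sensitivity constraint."""


@dataclass(frozen=True)
class ConfusionTable:
    """Integer 2x2 table at a cutoff: true/false positives and negatives."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n == 0:
            raise ValueError("empty confusion table")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class Estimate:
    """A point estimate with an optional 95% CI and a degeneracy flag."""

    value: float
    lo: float | None = None
    hi: float | None = None
    flag: str | None = None

    def to_dict(self) -> dict:
        d: dict = {"value": self.value}
        if self.lo is not None:
            d["ci95"] = [self.lo, self.hi]
        if self.flag:
            d["flag"] = self.flag
        return d


@dataclass(frozen=True)
class DiagnosticReport:
    """All accuracy measures computed from one confusion table at one cutoff."""

    table: ConfusionTable
    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    dor: Estimate
    pretest_odds: Estimate
    posttest_odds_pos: Estimate
    posttest_odds_neg: Estimate
    f_score: Estimate
    cutoff: float | None = None

    _METRICS = (
        "sensitivity", "specificity", "ppv", "npv", "accuracy",
        "lr_pos", "lr_neg", "dor", "pretest_odds",
        "posttest_odds_pos", "posttest_odds_neg", "f_score",
    )
    _PERCENT = ("sensitivity", "specificity", "ppv", "npv", "accuracy")

    def to_dict(self) -> dict:
        out = {
            "table": {"tp": self.table.tp, "fn": self.table.fn,
                      "fp": self.table.fp, "tn": self.table.tn},
            "cutoff": self.cutoff,
        }
        for m in self._METRICS:
            out[m] = getattr(self, m).to_dict()
        return out

    def printed(self) -> dict[str, str]:
        """Rendered to the precision used in published tables.

        Proportions as percentages with 1 decimal place, ratio metrics with 2;
        rounding is half away from zero.
        """
        out = {}
        for m in self._METRICS:
            est: Estimate = getattr(self, m)
            if m in self._PERCENT:
                out[m] = f"{round_half_away(100 * est.value, 1):.1f}"
            else:
                v = est.value
                out[m] = "inf" if math.isinf(v) else f"{round_half_away(v, 2):.2f}"
        return out


@dataclass(frozen=True)
class ROCResult:
    """Operating points (cutoff ascending), AUC and class sizes.

    ``cutoffs[0]`` is -inf (everyone screen-positive); at each later point the
    positivity rule is score > cutoff, so sensitivity is non-increasing in the
    cutoff.  Raw per-class scores are retained for DeLong variance estimation.
    """

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    fpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    pos_scores: np.ndarray = field(repr=False, default=None)
    neg_scores: np.ndarray = field(repr=False, default=None)

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def confusion_from_scores(scores, labels, cutoff: float) -> ConfusionTable:
    """Tally the 2x2 table: predicted positive iff score > cutoff (strict)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if scores.size == 0:
        raise ValueError("empty input")
    pred = scores > cutoff
    return ConfusionTable(
        tp=int(np.sum(pred & labels)),
        fn=int(np.sum(~pred & labels)),
        fp=int(np.sum(pred & ~labels)),
        tn=int(np.sum(~pred & ~labels)),
    )


def reconstruct_confusion(n: int, n_pos: int, sensitivity: float, specificity: float) -> ConfusionTable:
    """Integer 2x2 table implied by printed (n, positives, sensitivity, specificity).

    tp and tn are the rounded products (half away from zero); fn and fp the
    complements.  The returned table reproduces the inputs to within rounding.
    """
    if not 0 < n_pos < n:
        raise ValueError("need 0 < n_pos < n")
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be proportions")
    n_neg = n - n_pos
    tp = int(round_half_away(sensitivity * n_pos))
    tn = int(round_half_away(specificity * n_neg))
    fn = n_pos - tp
    fp = n_neg - tn
    if fn < 0 or fp < 0:
        raise ValueError("inputs imply negative cells")
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn)


def _wilson(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def _clopper(count: int, nobs: int) -> tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="beta")
    return float(lo), float(hi)


def _proportion(count: int, nobs: int, ci) -> Estimate:
    if nobs == 0:
        return Estimate(float("nan"), flag="undefined: empty denominator")
    lo, hi = ci(count, nobs)
    return Estimate(count / nobs, lo, hi)


def accuracy_metrics(
    table: ConfusionTable,
    ci_method: str = "wilson",
    cutoff: float | None = None,
    zero_cell: str = "flag",
) -> DiagnosticReport:
    """All accuracy measures with 95% CIs from one 2x2 table.

    Proportion CIs use the Wilson score interval (``ci_method="clopper-pearson"``
    for exact); likelihood-ratio CIs the Katz log method; the diagnostic odds
    ratio the Woolf log method.  Post-test odds = pre-test odds x LR, with CIs
    scaled from the LR interval (prevalence treated as fixed).  ``zero_cell``:
    "flag" reports inf/0 with a flag; "haldane" adds 0.5 to every cell for the
    ratio metrics only.
    """
    if ci_method == "wilson":
        ci = _wilson
    elif ci_method in ("clopper-pearson", "beta", "exact"):
        ci = _clopper
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    if zero_cell not in ("flag", "haldane"):
        raise ValueError(f"unknown zero_cell policy {zero_cell!r}")

    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    n = table.n
    sens = _proportion(tp, tp + fn, ci)
    spec = _proportion(tn, tn + fp, ci)
    ppv = _proportion(tp, tp + fp, ci)
    npv = _proportion(tn, tn + fn, ci)
    acc = _proportion(tp + tn, n, ci)

    if zero_cell == "haldane" and 0 in (tp, fn, fp, tn):
        rtp, rfn, rfp, rtn = (tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5)
    else:
        rtp, rfn, rfp, rtn = float(tp), float(fn), float(fp), float(tn)

    # LR+ = sens/(1-spec): events tp of (tp+fn) vs fp of (fp+tn)
    lr_pos = _katz_ratio_f(rtp, rtp + rfn, rfp, rfp + rtn)
    # LR- = (1-sens)/spec
    lr_neg = _katz_ratio_f(rfn, rtp + rfn, rtn, rfp + rtn)

    # diagnostic odds ratio, Woolf CI
    if 0 in (tp, fn, fp, tn) and zero_cell == "flag":
        if fn == 0 or fp == 0:
            dor = Estimate(float("inf"), flag="infinite: zero discordant cell")
        else:
            dor = Estimate(0.0, flag="zero: empty concordant cell")
    else:
        value = (rtp * rtn) / (rfn * rfp)
        se = math.sqrt(1 / rtp + 1 / rfn + 1 / rfp + 1 / rtn)
        dor = Estimate(value, value * math.exp(-Z95 * se), value * math.exp(Z95 * se))

    if table.negatives == 0:
        pretest = Estimate(float("inf"), flag="infinite: no negatives")
    else:
        plo, phi = ci(table.positives, n)
        pt = table.positives / table.negatives
        pretest = Estimate(pt, plo / (1 - plo) if plo < 1 else float("inf"),
                           phi / (1 - phi) if phi < 1 else float("inf"))

    def _post(lr: Estimate) -> Estimate:
        if not math.isfinite(pretest.value) or not math.isfinite(lr.value):
            return Estimate(pretest.value * lr.value if lr.value == lr.value else float("nan"),
                            flag="degenerate input odds/LR")
        if lr.lo is None:
            return Estimate(pretest.value * lr.value, flag=lr.flag)
        return Estimate(pretest.value * lr.value, pretest.value * lr.lo, pretest.value * lr.hi)

    f_den = 2 * tp + fp + fn
    if f_den == 0:
        f_score = Estimate(float("nan"), flag="undefined: no positives predicted or present")
    else:
        flo, fhi = ci(2 * tp, f_den)
        f_score = Estimate(2 * tp / f_den, flo, fhi, flag="CI from binomial approximation")

    return DiagnosticReport(
        table=table, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        accuracy=acc, lr_pos=lr_pos, lr_neg=lr_neg, dor=dor,
        pretest_odds=pretest, posttest_odds_pos=_post(lr_pos),
        posttest_odds_neg=_post(lr_neg), f_score=f_score, cutoff=cutoff,
    )


def _katz_ratio_f(x1: float, n1: float, x2: float, n2: float) -> Estimate:
    if x2 == 0:
        return Estimate(float("inf") if x1 > 0 else float("nan"),
                        flag="infinite: zero denominator cell")
    value = (x1 / n1) / (x2 / n2)
    if x1 == 0:
        return Estimate(0.0, flag="zero: no events in numerator")
    se_sq = 1 / x1 - 1 / n1 + 1 / x2 - 1 / n2
    if se_sq <= 0:
        return Estimate(value, value, value, flag="degenerate variance")
    se = math.sqrt(se_sq)
    return Estimate(value, value * math.exp(-Z95 * se), value * math.exp(Z95 * se))


def ratio_metrics_from_rates(sensitivity: float, specificity: float) -> dict[str, float]:
    """LR+, LR- and DOR straight from (possibly rounded) printed rates.

    Published tables often derive ratio metrics from the rounded sensitivity
    and specificity they print rather than from the integer cells; this is
    that computation path.
    """
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must be proportions")
    lr_pos = sensitivity / (1 - specificity) if specificity < 1 else float("inf")
    lr_neg = (1 - sensitivity) / specificity if specificity > 0 else float("inf")
    dor = lr_pos / lr_neg if lr_neg > 0 else float("inf")
    return {"lr_pos": lr_pos, "lr_neg": lr_neg, "dor": dor}


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_curve(scores, labels) -> ROCResult:
    """Operating points at every distinct score; trapezoidal AUC.

    With the strict score > cutoff positivity rule the trapezoidal AUC equals
    the Mann–Whitney statistic with half credit for ties.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores and labels must be matching non-empty 1-D arrays")
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    n_pos, n_neg = pos.size, neg.size
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    uniq = np.unique(scores)
    cutoffs = np.concatenate(([-np.inf], uniq))
    tp = n_pos - np.searchsorted(pos, cutoffs, side="right")
    fp = n_neg - np.searchsorted(neg, cutoffs, side="right")
    sens = tp / n_pos
    fpr = fp / n_neg
    auc = float(np.trapezoid(sens[::-1], fpr[::-1]))
    return ROCResult(cutoffs=cutoffs, sensitivity=sens, fpr=fpr, auc=auc,
                     n_pos=n_pos, n_neg=n_neg, pos_scores=pos, neg_scores=neg)


def _delong_variance(roc: ROCResult) -> float:
    """DeLong variance of the AUC from the placement components."""
    pos, neg = roc.pos_scores, roc.neg_scores
    m, n = pos.size, neg.size
    # V10_i = fraction of negatives below pos_i (ties half); V01_j symmetric
    v10 = (np.searchsorted(neg, pos, side="left")
           + 0.5 * (np.searchsorted(neg, pos, side="right")
                    - np.searchsorted(neg, pos, side="left"))) / n
    v01 = (np.searchsorted(pos, neg, side="left")
           + 0.5 * (np.searchsorted(pos, neg, side="right")
                    - np.searchsorted(pos, neg, side="left"))) / m
    v01 = 1.0 - v01  # fraction of positives above neg_j
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _hanley_mcneil_variance(roc: ROCResult) -> float:
    a = roc.auc
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    m, n = roc.n_pos, roc.n_neg
    return (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)


def auc_confidence_interval(roc: ROCResult, method: str = "delong", level: float = 0.95) -> tuple[float, float]:
    """Wald CI on the AUC scale, truncated to [0, 1].

    Degenerate variance (perfect or constant scores) yields the flagged point
    interval [auc, auc].
    """
    if roc.n_pos < 2 or roc.n_neg < 2:
        raise ValueError("need at least 2 subjects per class for an AUC CI")
    if method == "delong":
        var = _delong_variance(roc)
    elif method in ("hanley-mcneil", "hanley"):
        var = _hanley_mcneil_variance(roc)
    else:
        raise ValueError(f"unknown AUC CI method {method!r}")
    if var <= 0:
        return (roc.auc, roc.auc)
    z = norm.ppf(0.5 + level / 2)
    half = z * math.sqrt(var)
    return (max(0.0, roc.auc - half), min(1.0, roc.auc + half))


def compare_auc_independent(roc1: ROCResult, roc2: ROCResult) -> float:
    """Two-sided p-value for AUC1 = AUC2 on disjoint samples.

    Unpaired z-test with summed DeLong variances.  The caller is responsible
    for the samples being disjoint (e.g. different PSG strata); the paired
    covariance term is deliberately absent.
    """
    v = _delong_variance(roc1) + _delong_variance(roc2)
    diff = roc1.auc - roc2.auc
    if v <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(v)
    return float(2 * norm.sf(abs(z)))


def select_cutoff(roc: ROCResult, min_sensitivity: float = 0.95) -> float:
    """Largest-specificity cutoff among points with sensitivity >= the floor.

    Ties in specificity resolve toward the larger cutoff.  Raises
    :class:`CutoffUnattainableError` when no operating point qualifies.
    """
    ok = roc.sensitivity >= min_sensitivity
    if not ok.any():
        raise CutoffUnattainableError(
            f"no operating point reaches sensitivity {min_sensitivity}")
    spec = 1.0 - roc.fpr
    best_spec = spec[ok].max()
    candidates = ok & (spec == best_spec)
    return float(roc.cutoffs[candidates].max())
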