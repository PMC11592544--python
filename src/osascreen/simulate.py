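"""Seeded synthetic cohorts with the statistical shape of the validation cohort.

The study data behind the screening tool are not publicly available, so every
pipeline stage is exercised on synthetic cohorts instead.  The default
:class:`CohortConfig` encodes the published validation-cohort statistics:
n=216 suspected-OSA adults, 82% OSA prevalence overall, a 73/143 split between
in-laboratory (PSG I) and home (PSG III) sleep studies with stratum prevalences
66% and 90%, a 44/32/24% mild/moderate/severe mix among OSA cases, and
class-conditional distributions for each predictor (e.g. male sex in 107/177
OSA vs 12/39 non-OSA subjects; age 59±12 vs 48±11 years).

Predictors are sampled independently given the class by default (a naive
generator); :func:`generate_from_model` instead samples exactly from a fitted
TAN joint, which is what parameter-recovery tests need.  Within-class joint
dependencies of the real cohort are not published and are not emulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort import MODEL_VARIABLES, PatientRecord
from .tan import TANClassifier

__all__ = [
    "CohortConfig",
    "default_cohort_config",
    "generate_cohort",
    "generate_from_model",
    "attach_ahi",
    "reference_tan_model",
]

# log-normal neck circumference matched to published median / IQR:
# mu = ln(median); sigma = ln(q75/q25) / (2 * z_{0.75})
_Z75 = 0.6744897501960817


def _lognorm_params(median: float, q25: float, q75: float) -> tuple[float, float]:
    return float(np.log(median)), float(np.log(q75 / q25) / (2 * _Z75))


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameterization; defaults reproduce the validation cohort.

    Class-conditional probabilities are given as (non-OSA, OSA) pairs.
    ``missingness`` maps a record field name to a per-cell missing rate.
    """

    n: int = 216
    psg3_fraction: float = 143 / 216
    prevalence_psg1: float = 0.66
    prevalence_psg3: float = 0.90
    severity_mix: tuple[float, float, float] = (0.44, 0.32, 0.24)  # mild/moderate/severe
    # six model predictors, class-conditional
    p_male: tuple[float, float] = (12 / 39, 107 / 177)
    age_mean: tuple[float, float] = (48.0, 59.0)
    age_sd: tuple[float, float] = (11.0, 12.0)
    nc_median: tuple[float, float] = (36.0, 41.0)
    nc_iqr: tuple[tuple[float, float], tuple[float, float]] = ((33.0, 39.0), (38.0, 44.0))
    p_cfa: tuple[float, float] = (2 / 39, 23 / 177)
    p_witnessed_apneas: tuple[float, float] = (12 / 39, 108 / 177)
    p_nocturia: tuple[float, float] = (14 / 39, 109 / 177)
    # descriptive covariates
    bmi_mean: tuple[float, float] = (28.0, 31.0)
    bmi_sd: tuple[float, float] = (5.0, 6.0)
    ess_mean: tuple[float, float] = (11.0, 9.5)
    ess_sd: tuple[float, float] = (6.0, 6.0)
    p_snoring: tuple[float, float] = (0.72, 0.97)
    p_morning_headache: tuple[float, float] = (0.56, 0.35)
    p_non_restful_sleep: tuple[float, float] = (0.74, 0.50)
    p_hypertension: tuple[float, float] = (0.31, 0.61)
    p_diabetes: tuple[float, float] = (0.03, 0.28)
    p_dyslipidemia: tuple[float, float] = (0.29, 0.50)
    p_cardiac_pathology: tuple[float, float] = (0.03, 0.14)
    p_stroke: tuple[float, float] = (0.06, 0.07)
    p_depression: tuple[float, float] = (0.29, 0.28)
    severe_ahi_exp_mean: float = 15.0  # severe AHI = 30 + Exp(mean)
    missingness: dict = field(default_factory=dict)
    seed: int | None = None

    @property
    def prevalence(self) -> float:
        """Marginal OSA prevalence implied by the PSG strata (~0.82)."""
        return (self.psg3_fraction * self.prevalence_psg3
                + (1 - self.psg3_fraction) * self.prevalence_psg1)

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        props = [self.psg3_fraction, self.prevalence_psg1, self.prevalence_psg3,
                 *self.severity_mix]
        for name in ("p_male", "p_cfa", "p_witnessed_apneas", "p_nocturia",
                     "p_snoring", "p_morning_headache", "p_non_restful_sleep",
                     "p_hypertension", "p_diabetes", "p_dyslipidemia",
                     "p_cardiac_pathology", "p_stroke", "p_depression"):
            props.extend(getattr(self, name))
        if any(not 0 <= p <= 1 for p in props):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        for rate in self.missingness.values():
            if not 0 <= rate <= 1:
                raise ValueError("missingness rates must lie in [0, 1]")

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CohortConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)

        def tup(v):
            return tuple(tup(x) for x in v) if isinstance(v, list) else v

        return cls(**{k: tup(v) for k, v in data.items()})


def default_cohort_config() -> CohortConfig:
    """The published validation-cohort conditions (n=216, 82% prevalence, ...)."""
    return CohortConfig()


def _severity_and_ahi(osa: np.ndarray, cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """AHI consistent with class and severity: <5 / [5,15) / [15,30) / >=30."""
    n = osa.size
    sev_edges = np.cumsum(cfg.severity_mix)
    u_sev = rng.random(n)
    severity = np.searchsorted(sev_edges, u_sev, side="right")  # 0 mild, 1 moderate, 2 severe
    u = rng.random(n)
    exp_tail = rng.exponential(cfg.severe_ahi_exp_mean, size=n)
    ahi = np.where(osa,
                   np.select([severity == 0, severity == 1],
                             [5.0 + 10.0 * u, 15.0 + 15.0 * u],
                             default=30.0 + exp_tail),
                   5.0 * u)
    return np.floor(ahi * 10.0) / 10.0  # 1 dp, flooring so severity bands survive


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> list[PatientRecord]:
    """Draw a synthetic cohort; identical seeds give bit-identical cohorts.

    Sampling order per subject: PSG stratum, OSA status from the stratum
    prevalence, severity and AHI, then each predictor and covariate from its
    class-conditional distribution, then missingness masks.
    """
    cfg = config or default_cohort_config()
    cfg.validate()
    if seed is None:
        seed = cfg.seed if cfg.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = cfg.n
    if n == 0:
        return []

    psg3 = rng.random(n) < cfg.psg3_fraction
    prev = np.where(psg3, cfg.prevalence_psg3, cfg.prevalence_psg1)
    osa = rng.random(n) < prev
    ahi = _severity_and_ahi(osa, cfg, rng)
    cls = osa.astype(int)  # index into (non-OSA, OSA) parameter pairs

    def bern(p_pair):
        return rng.random(n) < np.asarray(p_pair)[cls]

    male = bern(cfg.p_male)
    # age: truncated normal >= 18, whole years
    mu = np.asarray(cfg.age_mean)[cls]
    sd = np.asarray(cfg.age_sd)[cls]
    a = (18.0 - mu) / sd
    age = np.round(truncnorm.ppf(rng.random(n), a, np.inf, loc=mu, scale=sd))
    # neck circumference: log-normal matched to median / IQR, 1 dp
    nc_mu = np.empty(n)
    nc_sigma = np.empty(n)
    for k in (0, 1):
        m, s = _lognorm_params(cfg.nc_median[k], *cfg.nc_iqr[k])
        nc_mu[cls == k] = m
        nc_sigma[cls == k] = s
    nc = np.round(np.exp(nc_mu + nc_sigma * rng.standard_normal(n)), 1)
    cfa = bern(cfg.p_cfa)
    apneas = bern(cfg.p_witnessed_apneas)
    nocturia = bern(cfg.p_nocturia)
    bmi = np.round(np.clip(np.asarray(cfg.bmi_mean)[cls]
                           + np.asarray(cfg.bmi_sd)[cls] * rng.standard_normal(n), 15.0, None), 1)
    ess = np.clip(np.round(np.asarray(cfg.ess_mean)[cls]
                           + np.asarray(cfg.ess_sd)[cls] * rng.standard_normal(n)), 0, 24).astype(int)
    covs = {name: bern(getattr(cfg, f"p_{name}"))
            for name in ("snoring", "morning_headache", "non_restful_sleep", "hypertension",
                         "diabetes", "dyslipidemia", "cardiac_pathology", "stroke", "depression")}

    miss = {f: (rng.random(n) < rate) if rate > 0 else np.zeros(n, dtype=bool)
            for f, rate in cfg.missingness.items()}

    def val(name, arr, i, cast=lambda v: v):
        if name in miss and miss[name][i]:
            return None
        return cast(arr[i])

    width = len(str(n))
    records = []
    for i in range(n):
        records.append(PatientRecord(
            id=f"S{i + 1:0{width}d}",
            sex=val("sex", male, i, lambda v: "male" if v else "female"),
            age_years=val("age_years", age, i, float),
            neck_circumference_cm=val("neck_circumference_cm", nc, i, float),
            cfa=val("cfa", cfa, i, bool),
            witnessed_apneas=val("witnessed_apneas", apneas, i, bool),
            nocturia=val("nocturia", nocturia, i, bool),
            bmi_kg_m2=val("bmi", bmi, i, float),
            ess_score=val("ess", ess, i, int),
            snoring=val("snoring", covs["snoring"], i, bool),
            morning_headache=val("morning_headache", covs["morning_headache"], i, bool),
            non_restful_sleep=val("non_restful_sleep", covs["non_restful_sleep"], i, bool),
            hypertension=val("hypertension", covs["hypertension"], i, bool),
            diabetes=val("diabetes", covs["diabetes"], i, bool),
            dyslipidemia=val("dyslipidemia", covs["dyslipidemia"], i, bool),
            cardiac_pathology=val("cardiac_pathology", covs["cardiac_pathology"], i, bool),
            stroke=val("stroke", covs["stroke"], i, bool),
            depression=val("depression", covs["depression"], i, bool),
            psg_type="III" if psg3[i] else "I",
            ahi_events_per_hour=val("ahi", ahi, i, float),
        ))
    return records


def attach_ahi(is_osa: np.ndarray, config: CohortConfig | None, rng: np.random.Generator) -> np.ndarray:
    """AHI values consistent with a given OSA indicator (label round-trips)."""
    cfg = config or default_cohort_config()
    return _severity_and_ahi(np.asarray(is_osa, dtype=bool), cfg, rng)


def reference_tan_model() -> TANClassifier:
    """A synthetic, hand-specified TAN over the six screening variables.

    Used as the known ground truth in structure/parameter-recovery studies.
    Deliberately well conditioned: balanced class prior, near-uniform root
    (age band), strong parent effects on every tree edge (0.7 vs 0.3, so each
    edge is identifiable from moderate samples), and extreme probabilities in
    the cells conditioned on the 4-level root, whose effective counts are the
    smallest.  It is not a fit to any real cohort.
    """
    from .cohort import VARIABLE_LEVELS
    from .tan import TANStructure

    m = TANClassifier(alpha=1.0)
    names = list(MODEL_VARIABLES)
    m.feature_names_in_ = names
    m.levels_ = {f: tuple(VARIABLE_LEVELS[f]) for f in names}
    m.classes_ = np.array([False, True], dtype=object)
    edges = (
        ("age_band", "nocturia"),
        ("nocturia", "sex"),
        ("sex", "nc_increased"),
        ("nc_increased", "witnessed_apneas"),
        ("witnessed_apneas", "cfa"),
    )
    m.structure_ = TANStructure("osa", tuple(names), edges, "age_band")
    m.structure_.validate()
    m.class_prior_ = np.array([0.5, 0.5])
    cpts: dict[str, np.ndarray] = {}
    cpts["age_band"] = np.array([[0.30, 0.25, 0.25, 0.20],
                                 [0.20, 0.25, 0.25, 0.30]])
    p_yes = np.array([[0.80, 0.15, 0.80, 0.15],
                      [0.85, 0.20, 0.85, 0.20]])  # nocturia | class, age_band
    cpts["nocturia"] = np.stack([p_yes, 1 - p_yes], axis=-1)

    def binary_cpt(p0: float, p1: float, class_shift: float = 0.05) -> np.ndarray:
        base = np.array([[p0, p1], [p0 - class_shift, p1 - class_shift]])
        return np.stack([base, 1 - base], axis=-1)

    cpts["sex"] = binary_cpt(0.70, 0.35)  # parent: nocturia
    cpts["nc_increased"] = binary_cpt(0.65, 0.30)  # parent: sex
    cpts["witnessed_apneas"] = binary_cpt(0.70, 0.35)  # parent: nc_increased
    cpts["cfa"] = binary_cpt(0.65, 0.30)  # parent: witnessed_apneas
    m.cpts_ = cpts
    m.n_features_in_ = len(names)
    m.metadata_ = {"synthetic": True, "source": "hand-specified reference model"}
    return m


def generate_from_model(
    model: TANClassifier,
    n: int,
    seed: int,
    config: CohortConfig | None = None,
    include_psg: bool = True,
) -> pd.DataFrame:
    """Exact ancestral sample from a fitted TAN joint, as an encoded cohort.

    Returns a DataFrame with one column per model variable (categorical
    levels), an ``ahi`` column consistent with the sampled class (so the AHI
    >= 5 rule reproduces it exactly) and, optionally, a ``psg_type`` column
    drawn independently of the class from the configured stratum mix.
    """
    cfg = config or default_cohort_config()
    rng = np.random.default_rng(seed)
    X, y = model.sample(n, rng)
    is_osa = np.array([bool(v) for v in y])
    df = X.copy()
    df["ahi"] = _severity_and_ahi(is_osa, cfg, rng)
    if include_psg:
        df["psg_type"] = np.where(rng.random(n) < cfg.psg3_fraction, "III", "I")
    return df
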