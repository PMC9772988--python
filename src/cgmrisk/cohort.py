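"""Synthetic cohort and CGM trace generator.

Generates cohorts of non-diabetic adults followed for five years for
incident type 2 diabetes, together with their baseline CGM traces, in
two modes:

* **matched-moments** — the outcome split is fixed (e.g. 499 subjects of
  whom 22 progress) and baseline covariates are drawn group-conditionally
  from distributions calibrated to the study population's printed group
  summaries (moments for continuous labs, prevalences for binary traits,
  median/IQR for the time-above-range distribution);
* **causal-logistic** — covariates are drawn from the non-progressor
  population and the outcome is sampled from a logistic model with a
  configurable per-percentage-point TAR effect, for parameter-recovery
  studies.

Joint structure uses a Gaussian copula over (HbA1c, FPG, TAR-propensity,
BMI, HOMA-IR, metabolic load): the paper trail for real cohorts offers
only pairwise correlations, so the copula correlations are modelling
choices, set so that TAR correlates strongly with HbA1c and FPG.

The CGM trace model is: an HbA1c-linked basal level (via the linear
estimated-average-glucose relation), a circadian sinusoid with an early
morning trough, three daily meal excursions with a gamma-shaped rise and
decay, and autocorrelated AR(1) sensor noise.  The subject's meal
excursion amplitude is solved by bisection so that the *expected*
fraction of readings above 140 mg/dL equals the subject's TAR
propensity; group TAR medians therefore match their configured targets
without per-trace tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from scipy.signal import lfilter
from scipy.special import expit, ndtr

from .metrics import CGMRecord, SAMPLES_PER_DAY

__all__ = [
    "GroupParams",
    "TraceParams",
    "CausalCoefficients",
    "GeneratorConfig",
    "ConfigurationError",
    "generate_cohort",
    "generate_cgm_trace",
    "generate_traces",
    "assign_outcomes_causal",
    "write_cohort_csv",
    "write_traces_csv",
]

#: Enrolment excludes baseline (confirmed) diabetes.  FPG is bounded below
#: the 126 mg/dL diagnostic threshold — the truncated family still attains
#: the printed group moments there.  HbA1c is bounded at 7.4%: an ADA
#: diagnosis needs two abnormal samples, so single unconfirmed baseline
#: values in [6.5, 7.4) are compatible with enrolment, and the printed
#: progressor-group SD of 0.7 is only attainable with that tail present.
_FPG_BOUNDS = (50.0, 125.9)
_HBA1C_BOUNDS = (3.8, 7.4)
_AGE_BOUNDS = (18.0, 85.0)
_BMI_BOUNDS = (15.0, 60.0)

_COPULA_VARS = ("hba1c", "fpg", "tar", "bmi", "homa", "metload")

_Z75 = stats.norm.ppf(0.75)


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


@dataclass
class GroupParams:
    """Group-conditional calibration targets (one outcome group)."""

    age: tuple[float, float]
    bmi: tuple[float, float]
    fpg: tuple[float, float]
    hba1c: tuple[float, float]
    homa_ir: tuple[float, float]
    p_male: float
    p_family_history: float
    p_abdominal_obesity: float
    p_hypertriglyceridaemia: float
    p_low_hdl: float
    p_high_bp: float
    tar_median: float
    tar_iqr: tuple[float, float]


@dataclass
class TraceParams:
    """CGM trace model parameters (all glucose quantities in mg/dL)."""

    eag_slope: float = 28.7
    eag_intercept: float = -46.7
    basal_offset: float = 8.0
    #: ceiling on the between-meal basal level: non-diabetic glucose
    #: regulation keeps fasting/basal glucose below the high-TIR threshold
    #: even when the HbA1c-implied average is higher, the excess being
    #: expressed through post-meal excursions
    basal_cap: float = 130.0
    basal_jitter_sd: float = 4.0
    circadian_median: float = 8.0
    circadian_sigma: float = 0.5
    circadian_trough_hour: float = 4.0
    meal_hours: tuple[float, ...] = (8.0, 13.5, 20.5)
    meal_sizes: tuple[float, ...] = (0.8, 1.0, 0.9)
    meal_time_jitter_sd_h: float = 0.5
    meal_size_sigma: float = 0.25
    meal_tau_h: float = 0.6
    noise_sd: float = 6.0
    noise_ar1: float = 0.8
    start_date: str = "2012-06-01"


@dataclass
class CausalCoefficients:
    """Log-odds per covariate unit for causal-logistic outcome assignment.

    The intercept is solved at run time so that the expected outcome
    prevalence equals ``target_prevalence``.
    """

    age: float = math.log(1.03)
    sex_male: float = 0.0
    family_history_dm: float = math.log(1.8)
    bmi: float = math.log(1.10)
    hba1c: float = math.log(3.0)
    tar_pct: float = math.log(1.06)
    target_prevalence: float = 0.044


def _default_groups() -> dict:
    return {
        "non_progressor": GroupParams(
            age=(46.4, 13.8),
            bmi=(27.6, 4.9),
            fpg=(87.0, 10.0),
            hba1c=(5.3, 0.3),
            homa_ir=(2.55, 1.69),
            p_male=0.35,
            p_family_history=0.50,
            p_abdominal_obesity=0.36,
            p_hypertriglyceridaemia=0.16,
            p_low_hdl=0.17,
            p_high_bp=0.36,
            tar_median=1.9,
            tar_iqr=(0.4, 5.1),
        ),
        "progressor": GroupParams(
            age=(54.8, 10.0),
            bmi=(33.2, 4.8),
            fpg=(105.0, 12.0),
            hba1c=(5.8, 0.7),
            homa_ir=(5.32, 3.31),
            p_male=0.32,
            p_family_history=0.64,
            p_abdominal_obesity=0.86,
            p_hypertriglyceridaemia=0.27,
            p_low_hdl=0.27,
            p_high_bp=0.77,
            tar_median=7.8,
            tar_iqr=(4.5, 20.0),
        ),
    }


def _default_wear_probs() -> dict:
    # pooled wear-day frequencies across the analysed cohort
    return {2: 9 / 499, 3: 16 / 499, 4: 29 / 499, 5: 427 / 499, 6: 18 / 499}


def _default_correlations() -> dict:
    return {
        "hba1c:fpg": 0.70,
        "hba1c:tar": 0.83,
        "fpg:tar": 0.76,
        "bmi:hba1c": 0.35,
        "bmi:fpg": 0.35,
        "bmi:tar": 0.35,
        "homa:hba1c": 0.40,
        "homa:fpg": 0.45,
        "homa:tar": 0.40,
        "homa:bmi": 0.55,
        "metload:hba1c": 0.25,
        "metload:fpg": 0.25,
        "metload:tar": 0.25,
        "metload:bmi": 0.50,
        "metload:homa": 0.40,
    }


@dataclass
class GeneratorConfig:
    """Full generator configuration; defaults reproduce the study-scale
    cohort of 499 subjects with 22 progressors."""

    n_subjects: int = 499
    n_progressors: int = 22
    groups: dict = field(default_factory=_default_groups)
    wear_day_probs: dict = field(default_factory=_default_wear_probs)
    correlations: dict = field(default_factory=_default_correlations)
    component_loading: float = 0.55
    trace: TraceParams = field(default_factory=TraceParams)
    causal: CausalCoefficients = field(default_factory=CausalCoefficients)
    tar_max_pct: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.n_progressors < self.n_subjects:
            raise ConfigurationError("need 0 <= n_progressors < n_subjects")
        for name, gp in self.groups.items():
            for var in ("age", "bmi", "fpg", "hba1c", "homa_ir"):
                mean, sd = getattr(gp, var)
                if sd <= 0:
                    raise ConfigurationError(f"{name}.{var}: SD must be > 0")
            for var in (
                "p_male",
                "p_family_history",
                "p_abdominal_obesity",
                "p_hypertriglyceridaemia",
                "p_low_hdl",
                "p_high_bp",
            ):
                p = getattr(gp, var)
                if not 0 <= p <= 1:
                    raise ConfigurationError(f"{name}.{var}: prevalence not in [0,1]")
            q1, q3 = gp.tar_iqr
            if not 0 < q1 < gp.tar_median < q3:
                raise ConfigurationError(f"{name}: need 0 < Q1 < median < Q3 for TAR")
        probs = np.array(list(self.wear_day_probs.values()), dtype=float)
        if np.any(probs < 0) or np.any(probs > 1) or abs(probs.sum() - 1) > 1e-9:
            raise ConfigurationError("wear-day probabilities must be in [0,1] and sum to 1")
        mat = self.correlation_matrix()
        if np.linalg.eigvalsh(mat).min() < 1e-10:
            raise ConfigurationError("copula correlation matrix is not positive definite")

    def correlation_matrix(self) -> np.ndarray:
        mat = np.eye(len(_COPULA_VARS))
        idx = {v: i for i, v in enumerate(_COPULA_VARS)}
        for key, rho in self.correlations.items():
            a, b = key.split(":")
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = rho
        return mat

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "GeneratorConfig":
        cfg = cls()
        for key, value in raw.items():
            if key == "groups":
                cfg.groups = {
                    name: GroupParams(**{k: _tup(v) for k, v in gp.items()})
                    for name, gp in value.items()
                }
            elif key == "trace":
                cfg.trace = TraceParams(**{k: _tup(v) for k, v in value.items()})
            elif key == "causal":
                cfg.causal = CausalCoefficients(**value)
            elif key == "wear_day_probs":
                cfg.wear_day_probs = {int(k): float(v) for k, v in value.items()}
            else:
                setattr(cfg, key, value)
        return cfg


def _tup(v):
    return tuple(v) if isinstance(v, list) else v


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# marginal distribution helpers


def fit_truncnorm_moments(
    mean: float, sd: float, lo: float, hi: float
) -> tuple[float, float, bool]:
    """Underlying (mu, sigma) of a truncated normal whose *truncated*
    mean and SD match the targets.

    Returns ``(mu, sigma, matched)``; ``matched`` is False when the
    target SD is unattainable within the family under the given bounds
    (the solver then returns the best least-squares fit).
    """

    def resid(p):
        mu, log_sigma = p
        sigma = math.exp(log_sigma)
        a, b = (lo - mu) / sigma, (hi - mu) / sigma
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sigma, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.least_squares(
        resid, [mean, math.log(sd)], method="lm", xtol=1e-12, ftol=1e-12
    )
    mu, sigma = sol.x[0], math.exp(sol.x[1])
    err = float(np.max(np.abs(resid(sol.x))))
    return mu, sigma, err < 1e-4 * max(1.0, abs(mean))


def _truncnorm_ppf(u, mean, sd, lo, hi, cache={}):
    key = (mean, sd, lo, hi)
    if key not in cache:
        cache[key] = fit_truncnorm_moments(mean, sd, lo, hi)[:2]
    mu, sigma = cache[key]
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return stats.truncnorm.ppf(u, a, b, loc=mu, scale=sigma)


def _lognorm_from_mean_sd(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _tar_from_z(z: np.ndarray, gp: GroupParams) -> np.ndarray:
    """TAR propensity (%) from a standard-normal score via a two-piece
    lognormal quantile model anchored on the printed median and quartiles.

    The log-scale spread differs below and above the median
    (``sigma = ln(median/Q1)/z75`` vs ``ln(Q3/median)/z75``), so all three
    printed quantiles are matched exactly; a symmetric lognormal would
    overstate the upper tail of the non-progressor group."""
    q1, q3 = gp.tar_iqr
    sigma_lo = math.log(gp.tar_median / q1) / _Z75
    sigma_hi = math.log(q3 / gp.tar_median) / _Z75
    sigma = np.where(z < 0, sigma_lo, sigma_hi)
    return gp.tar_median * np.exp(sigma * z)


# ---------------------------------------------------------------------------
# cohort generation


def _latent_flag(metload, p, loading, rng):
    eps = rng.standard_normal(metload.size)
    latent = loading * metload + math.sqrt(1 - loading**2) * eps
    return ndtr(latent) < p


def _cond_truncnorm(u, flag, loc, scale, lo, cut, hi):
    """Draw from a truncated normal conditioned on being above (flag) or
    below (not flag) ``cut``, via conditional CDF inversion."""
    a_lo = np.where(flag, cut, lo)
    a_hi = np.where(flag, hi, cut)
    a = (a_lo - loc) / scale
    b = (a_hi - loc) / scale
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def _generate_group(
    n: int, gp: GroupParams, config: GeneratorConfig, rng, outcome: bool
) -> pd.DataFrame:
    chol = np.linalg.cholesky(config.correlation_matrix())
    z = rng.standard_normal((n, len(_COPULA_VARS))) @ chol.T
    u = ndtr(z)

    hba1c = _truncnorm_ppf(u[:, 0], *gp.hba1c, *_HBA1C_BOUNDS)
    fpg = _truncnorm_ppf(u[:, 1], *gp.fpg, *_FPG_BOUNDS)
    tar = np.clip(_tar_from_z(z[:, 2], gp), 0.02, config.tar_max_pct)
    bmi = _truncnorm_ppf(u[:, 3], *gp.bmi, *_BMI_BOUNDS)
    mu_h, sd_h = _lognorm_from_mean_sd(*gp.homa_ir)
    homa = np.clip(np.exp(mu_h + sd_h * z[:, 4]), 0.1, 40.0)
    metload = z[:, 5]

    insulin = homa * 22.5 / (fpg / 18.0)
    age = _truncnorm_ppf(rng.random(n), *gp.age, *_AGE_BOUNDS)
    male = rng.random(n) < gp.p_male
    family_history = rng.random(n) < gp.p_family_history

    lam = config.component_loading
    abd = _latent_flag(metload, gp.p_abdominal_obesity, lam, rng)
    htg = _latent_flag(metload, gp.p_hypertriglyceridaemia, lam, rng)
    lhdl = _latent_flag(metload, gp.p_low_hdl, lam, rng)
    hbp = _latent_flag(metload, gp.p_high_bp, lam, rng)

    waist_cut = np.where(male, 102.0, 88.0)
    waist_loc = np.where(male, 94.0, 84.0) + 0.8 * (bmi - 27.6)
    waist = _cond_truncnorm(
        rng.random(n), abd, waist_loc, 6.0, 55.0, waist_cut, waist_cut + 45.0
    )

    # triglycerides: lognormal body, conditioned on the >=150 flag
    ln_tg_mu, ln_tg_sd = math.log(110.0), 0.45
    f150 = ndtr((math.log(150.0) - ln_tg_mu) / ln_tg_sd)
    u_tg = rng.random(n)
    u_cond = np.where(htg, f150 + u_tg * (1 - f150), u_tg * f150)
    tg = np.exp(ln_tg_mu + ln_tg_sd * stats.norm.ppf(np.clip(u_cond, 1e-12, 1 - 1e-12)))

    hdl_cut = np.where(male, 40.0, 50.0)
    hdl_loc = np.where(male, 46.0, 57.0)
    hdl = _cond_truncnorm(rng.random(n), ~lhdl, hdl_loc, 12.0, 20.0, hdl_cut, 120.0)

    meds = hbp & (rng.random(n) < 0.45)
    u_bp = rng.random(n)
    sbp = np.empty(n)
    untreated_high = hbp & ~meds
    sbp[untreated_high] = _cond_truncnorm(
        u_bp[untreated_high],
        np.ones(untreated_high.sum(), bool),
        137.0, 10.0, 90.0, 130.0, 200.0,
    )
    sbp[meds] = stats.truncnorm.ppf(
        u_bp[meds], (100.0 - 134.0) / 14.0, (200.0 - 134.0) / 14.0, loc=134.0, scale=14.0
    )
    low = ~hbp
    sbp[low] = stats.truncnorm.ppf(
        u_bp[low], (90.0 - 118.0) / 8.0, (129.9 - 118.0) / 8.0, loc=118.0, scale=8.0
    )
    dbp = 0.5 * sbp + 12.0 + rng.normal(0.0, 5.0, n)
    dbp = np.where(hbp, np.clip(dbp, 50.0, 120.0), np.clip(dbp, 50.0, 84.9))

    wear_days = rng.choice(
        list(config.wear_day_probs), p=list(config.wear_day_probs.values()), size=n
    )

    return pd.DataFrame(
        {
            "outcome_t2d_5y": outcome,
            "age": np.round(age, 1),
            "sex": np.where(male, "male", "female"),
            "sex_male": male,
            "family_history_dm": family_history,
            "bmi": np.round(bmi, 1),
            "waist": np.round(waist, 1),
            "fpg": np.round(fpg, 1),
            "hba1c": np.round(hba1c, 2),
            "fasting_insulin": np.round(insulin, 2),
            "homa_ir": np.round(homa, 2),
            "triglycerides": np.round(tg, 1),
            "hdl": np.round(hdl, 1),
            "sbp": np.round(sbp, 1),
            "dbp": np.round(dbp, 1),
            "antihypertensive_use": meds,
            "tar_propensity_pct": np.round(tar, 3),
            "wear_days": wear_days.astype(int),
        }
    )


def generate_cohort(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate a matched-moments cohort table.

    Exactly ``n_subjects`` rows of which ``n_progressors`` have
    ``outcome_t2d_5y = True``; covariates drawn group-conditionally.
    Reproducible bit-for-bit given ``config.seed``.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_prog = config.n_progressors
    n_non = config.n_subjects - n_prog
    parts = [
        _generate_group(n_non, config.groups["non_progressor"], config, rng, False),
        _generate_group(n_prog, config.groups["progressor"], config, rng, True),
    ]
    cohort = pd.concat(parts, ignore_index=True)
    cohort = cohort.iloc[rng.permutation(len(cohort))].reset_index(drop=True)
    width = max(4, len(str(len(cohort))))
    cohort.insert(0, "subject_id", [f"S{i + 1:0{width}d}" for i in range(len(cohort))])
    # enrolment excludes confirmed baseline diabetes: FPG is below the
    # diagnostic threshold by construction and elevated single HbA1c values
    # are unconfirmed, so no profile satisfies the two-sample ADA criteria
    assert (cohort["fpg"] < 126).all() and (cohort["hba1c"] < 7.5).all()
    return cohort


# ---------------------------------------------------------------------------
# trace generation


def _meal_component(t_hours: np.ndarray, n_days: int, tp: TraceParams, rng) -> np.ndarray:
    meal = np.zeros_like(t_hours)
    for day in range(n_days):
        for hour, size in zip(tp.meal_hours, tp.meal_sizes):
            tk = 24.0 * day + hour + rng.normal(0.0, tp.meal_time_jitter_sd_h)
            amp = size * math.exp(rng.normal(0.0, tp.meal_size_sigma))
            x = np.clip((t_hours - tk) / tp.meal_tau_h, 0.0, 12.0)
            meal += amp * x * np.exp(1.0 - x)
    return meal


def _solve_amplitude(path_with_noise, meal, q_target, a_max=500.0, iters=40):
    """Bisection for the meal amplitude at which the trace's realised
    fraction of readings above 140 mg/dL equals the TAR propensity.

    Solving against the already-drawn noise path (rather than its
    expectation) makes each simulated week express its drawn propensity
    up to grid resolution, so the group TAR distribution reproduces the
    configured quantiles without a mixing bias from realisation noise.
    The fraction is a nondecreasing step function of the amplitude
    because the meal component is nonnegative.
    """

    def realised_tar(a):
        # same predicate as the range metric: values are reported to one
        # decimal, so round before comparing against the threshold
        return float(np.mean(np.round(path_with_noise + a * meal, 1) > 140.0))

    if realised_tar(0.0) >= q_target:
        return 0.0
    if realised_tar(a_max) <= q_target:
        return a_max
    lo, hi = 0.0, a_max
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if realised_tar(mid) < q_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cgm_trace(
    profile,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
    rng=None,
) -> CGMRecord:
    """Simulate one subject's CGM trace on the 5-minute grid.

    ``profile`` is a cohort row (mapping-like) providing ``hba1c``,
    ``tar_propensity_pct`` and optionally ``wear_days`` and
    ``subject_id``.  The trace has exactly ``wear_days x 288`` samples,
    clamped to the device range [40, 400] mg/dL.
    """
    config = config or GeneratorConfig()
    tp = config.trace
    if rng is None:
        rng = np.random.default_rng(seed)
    wear_days = int(profile.get("wear_days", 0)) if hasattr(profile, "get") else int(
        getattr(profile, "wear_days", 0)
    )
    if wear_days <= 0:
        wear_days = int(
            rng.choice(list(config.wear_day_probs), p=list(config.wear_day_probs.values()))
        )
    hba1c = float(profile["hba1c"] if hasattr(profile, "__getitem__") else profile.hba1c)
    q = float(
        profile["tar_propensity_pct"]
        if hasattr(profile, "__getitem__")
        else profile.tar_propensity_pct
    ) / 100.0

    n = wear_days * SAMPLES_PER_DAY
    t_hours = np.arange(n) * (24.0 / SAMPLES_PER_DAY)
    circ_amp = (
        math.exp(rng.normal(math.log(tp.circadian_median), tp.circadian_sigma))
        if tp.circadian_median > 0
        else 0.0
    )
    # the regulation ceiling applies to the between-meal level at its
    # circadian peak, so the cap does not leave a floor on TAR
    basal = min(
        tp.eag_slope * hba1c + tp.eag_intercept - tp.basal_offset,
        tp.basal_cap - circ_amp,
    ) + rng.normal(0.0, tp.basal_jitter_sd)
    circ = -circ_amp * np.cos(2 * np.pi * (t_hours - tp.circadian_trough_hour) / 24.0)
    meal = _meal_component(t_hours, wear_days, tp, rng)

    phi = tp.noise_ar1
    if tp.noise_sd > 0:
        innov = rng.normal(0.0, tp.noise_sd * math.sqrt(1 - phi**2), n)
        x0 = rng.normal(0.0, tp.noise_sd)
        noise, _ = lfilter([1.0], [1.0, -phi], innov, zi=[phi * x0])
    else:
        noise = np.zeros(n)

    path = basal + circ + noise
    amplitude = _solve_amplitude(path, meal, q)

    glucose = np.clip(path + amplitude * meal, 40.0, 400.0).round(1)
    start = np.datetime64(tp.start_date, "ns")
    times = start + (np.arange(n) * 5 * 60 * 1_000_000_000).astype("timedelta64[ns]")
    sid = str(
        profile.get("subject_id", "subject")
        if hasattr(profile, "get")
        else getattr(profile, "subject_id", "subject")
    )
    return CGMRecord(subject_id=sid, times=times, glucose=glucose)


def generate_traces(
    cohort: pd.DataFrame, config: GeneratorConfig | None = None, seed: int | None = None
) -> dict[str, CGMRecord]:
    """Simulate traces for every cohort row; one child generator per
    subject (spawned from ``seed``) so subsets reproduce independently."""
    config = config or GeneratorConfig()
    seeds = np.random.SeedSequence(config.seed if seed is None else seed).spawn(
        len(cohort)
    )
    records: dict[str, CGMRecord] = {}
    for (_, row), ss in zip(cohort.iterrows(), seeds):
        rec = generate_cgm_trace(row, config, rng=np.random.default_rng(ss))
        records[rec.subject_id] = rec
    return records


# ---------------------------------------------------------------------------
# causal-logistic outcome assignment


def assign_outcomes_causal(
    cohort: pd.DataFrame,
    tar_pct,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Redraw outcomes from a logistic model on the measured covariates.

    ``tar_pct`` is the per-subject TAR (%), aligned with ``cohort`` rows.
    The intercept is solved so the expected prevalence equals the
    configured target; outcomes are then Bernoulli draws.  Returns a copy
    with ``outcome_t2d_5y`` replaced and a ``p_outcome`` column of the
    generating probabilities.
    """
    config = config or GeneratorConfig()
    coefs = config.causal
    required = ["age", "sex_male", "family_history_dm", "bmi", "hba1c"]
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort missing covariates: {missing}")
    tar = np.asarray(tar_pct, dtype=float)
    if tar.shape[0] != len(cohort):
        raise ValueError("tar_pct length does not match cohort")
    lp = (
        coefs.age * cohort["age"].to_numpy(float)
        + coefs.sex_male * cohort["sex_male"].to_numpy(float)
        + coefs.family_history_dm * cohort["family_history_dm"].to_numpy(float)
        + coefs.bmi * cohort["bmi"].to_numpy(float)
        + coefs.hba1c * cohort["hba1c"].to_numpy(float)
        + coefs.tar_pct * tar
    )

    def prevalence_gap(b0):
        return float(np.mean(expit(b0 + lp))) - coefs.target_prevalence

    intercept = optimize.brentq(prevalence_gap, -60.0, 20.0, xtol=1e-10)
    p = expit(intercept + lp)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = cohort.copy()
    out["outcome_t2d_5y"] = rng.random(len(cohort)) < p
    out["p_outcome"] = p
    out.attrs["causal_intercept"] = intercept
    return out


# ---------------------------------------------------------------------------
# writers


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """One row per subject; units: age years, bmi kg/m2, waist cm, fpg and
    lipids mg/dL, hba1c NGSP %, insulin uU/mL, pressures mmHg."""
    cohort.to_csv(path, index=False)


def write_traces_csv(records: dict[str, CGMRecord], path) -> None:
    """Long format: subject_id, ISO-8601 timestamp, glucose_mg_dl."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": rec.subject_id,
                "timestamp": rec.times,
                "glucose_mg_dl": rec.glucose,
            }
        )
        for rec in records.values()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
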