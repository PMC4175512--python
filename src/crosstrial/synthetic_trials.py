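"""Paired synthetic randomized trials for cross-trial comparison studies.

Emulates the data situation of a matching-adjusted indirect comparison in
advanced pancreatic neuroendocrine tumors: one placebo-controlled trial with
individual patient data (IPD) available, and a second placebo-controlled
trial of a different active drug for which only published aggregates exist —
baseline margins, Kaplan–Meier figures with at-risk tables, and hazard
ratios.  Both trials allow placebo patients to cross over to active therapy
after disease progression, which contaminates intention-to-treat overall
survival.

Outcome model: conditional on covariates, progression and death times are
exponential with log-linear covariate and treatment effects (proportional
hazards).  PFS is the minimum of progression and death.  A Bernoulli-chosen
subset of placebo progressors crosses over at the progression time, after
which the death hazard is multiplied by ``exp(post_crossover_log_hr_os)``
(memorylessness makes the sequential redraw exact).  Administrative
censoring applies at the trial's data cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covariates import SITE_LEVELS, linear_predictor
from .km_reconstruction import AtRiskTable, DigitizedCurve

# Baseline margins of the two emulated study populations.  The IPD-trial
# values are the everolimus-trial study sample before matching; the
# comparator values are those reported for the sunitinib trial.
IPD_TRIAL_MARGINS: dict[str, float] = {
    "age_median": 58.0,
    "age_gt_64": 0.274,
    "female": 0.449,
    "ecog0": 0.688,
    "dx_ge3y": 0.467,
    "n_sites_2": 0.368,
    "n_sites_ge3": 0.350,
    "distant_mets": 0.962,
    "prior_ssa": 0.492,
    "prior_chemo": 0.487,
}

COMPARATOR_MARGINS: dict[str, float] = {
    "age_median": 56.5,
    "age_gt_64": 0.263,
    "female": 0.520,
    "ecog0": 0.550,
    "dx_ge3y": 0.480,
    "n_sites_2": 0.337,
    "n_sites_ge3": 0.349,
    "distant_mets": 0.947,
    "prior_ssa": 0.363,
    "prior_chemo": 0.690,
}

#: prognostic log-hazard-ratios shared by PFS and OS in the default scenario
DEFAULT_COVARIATE_LOG_HRS: dict[str, float] = {
    "ecog0": -0.5,
    "prior_chemo": 0.25,
    "n_sites_ge3": 0.30,
    "distant_mets": 0.35,
}

#: monthly onset hazards per adverse event and arm, IPD (everolimus-like) trial
DEFAULT_AE_HAZARDS_IPD: dict[str, dict[str, float]] = {
    "peripheral_edema": {"active": 0.030, "placebo": 0.010},
    "fever": {"active": 0.025, "placebo": 0.012},
    "neutropenia": {"active": 0.004, "placebo": 0.004},
    "hypertension": {"active": 0.006, "placebo": 0.006},
}

#: comparator (sunitinib-like) trial: myelosuppression and hypertension on active
DEFAULT_AE_HAZARDS_COMPARATOR: dict[str, dict[str, float]] = {
    "peripheral_edema": {"active": 0.012, "placebo": 0.011},
    "fever": {"active": 0.013, "placebo": 0.012},
    "neutropenia": {"active": 0.030, "placebo": 0.004},
    "hypertension": {"active": 0.035, "placebo": 0.006},
}


@dataclass(frozen=True)
class TrialConfig:
    """Generating parameters of one synthetic placebo-controlled trial.

    Hazards are monthly rates; log-HRs are natural-log hazard ratios for the
    active arm versus placebo conditional on covariates.
    """

    n_per_arm: int
    covariate_margins: dict[str, float]
    baseline_hazard_pfs: float
    baseline_hazard_os: float
    log_hr_treatment_pfs: float
    log_hr_treatment_os: float
    covariate_log_hrs: dict[str, float] = field(default_factory=dict)
    crossover_probability: float = 0.0
    post_crossover_log_hr_os: float = 0.0
    censor_cutoff_months: float = 40.0
    ecog2_proportion: float = 0.0
    ae_hazards: dict[str, dict[str, float]] = field(default_factory=dict)
    label: str = "trial"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        for r in (self.baseline_hazard_pfs, self.baseline_hazard_os):
            if not np.isfinite(r) or r <= 0:
                raise ValueError("baseline hazards must be finite and > 0")
        for v in (
            self.log_hr_treatment_pfs,
            self.log_hr_treatment_os,
            self.post_crossover_log_hr_os,
            *self.covariate_log_hrs.values(),
        ):
            if not np.isfinite(v):
                raise ValueError("log hazard ratios must be finite")
        if not 0.0 <= self.crossover_probability <= 1.0:
            raise ValueError("crossover_probability must be in [0, 1]")
        for name, p in self.covariate_margins.items():
            if name != "age_median" and not 0.0 <= p <= 1.0:
                raise ValueError(f"margin {name!r}={p} outside [0, 1]")

    def with_(self, **kwargs) -> "TrialConfig":
        return replace(self, **kwargs)


def ipd_trial_config(seed: int = 0, n_per_arm: int = 205, **overrides) -> TrialConfig:
    """Default configuration of the IPD (everolimus-like) trial.

    Placebo median PFS ≈ 4.6 months, treatment PFS HR 0.35, OS effect
    HR ≈ 0.61 versus an uncontaminated placebo, 73% crossover at
    progression, 39-month follow-up.
    """
    cfg = dict(
        n_per_arm=n_per_arm,
        covariate_margins=dict(IPD_TRIAL_MARGINS),
        baseline_hazard_pfs=np.log(2) / 4.6,
        baseline_hazard_os=np.log(2) / 30.0,
        log_hr_treatment_pfs=np.log(0.35),
        log_hr_treatment_os=np.log(0.61),
        covariate_log_hrs=dict(DEFAULT_COVARIATE_LOG_HRS),
        crossover_probability=0.73,
        post_crossover_log_hr_os=np.log(0.70),
        censor_cutoff_months=39.0,
        ae_hazards={k: dict(v) for k, v in DEFAULT_AE_HAZARDS_IPD.items()},
        label="ipd_trial",
        seed=seed,
    )
    cfg.update(overrides)
    return TrialConfig(**cfg)


def comparator_trial_config(seed: int = 1, n_per_arm: int = 86, **overrides) -> TrialConfig:
    """Default configuration of the aggregate-only (sunitinib-like) trial.

    Placebo median PFS ≈ 5.5 months, treatment PFS HR 0.42, 69% crossover,
    30-month follow-up (shorter cutoff than the IPD trial).
    """
    cfg = dict(
        n_per_arm=n_per_arm,
        covariate_margins=dict(COMPARATOR_MARGINS),
        baseline_hazard_pfs=np.log(2) / 5.5,
        baseline_hazard_os=np.log(2) / 30.0,
        log_hr_treatment_pfs=np.log(0.42),
        log_hr_treatment_os=np.log(0.61),
        covariate_log_hrs=dict(DEFAULT_COVARIATE_LOG_HRS),
        crossover_probability=0.69,
        post_crossover_log_hr_os=np.log(0.70),
        censor_cutoff_months=30.0,
        ae_hazards={k: dict(v) for k, v in DEFAULT_AE_HAZARDS_COMPARATOR.items()},
        label="comparator_trial",
        seed=seed,
    )
    cfg.update(overrides)
    return TrialConfig(**cfg)


_AGE_SHIFT = 25.0


def _age_params(margins: dict[str, float]) -> tuple[float, float]:
    """Shape and scale of the shifted-gamma age law.

    Calibrated so the median equals ``age_median``; when an ``age_gt_64``
    margin is present the shape is additionally solved so the >64 tail
    probability matches (median matching, not mean matching, is what the
    weighting targets, so the median is exact by construction).
    """
    med = margins.get("age_median", 60.0) - _AGE_SHIFT
    tail = margins.get("age_gt_64")

    def theta_for(k):
        return med / stats.gamma.ppf(0.5, k)

    if tail is None:
        k = 8.0
        return k, theta_for(k)

    cut = 64.0 - _AGE_SHIFT

    def f(log_k):
        k = np.exp(log_k)
        return stats.gamma.sf(cut / theta_for(k), k) - tail

    lo, hi = np.log(1.05), np.log(400.0)
    if f(lo) * f(hi) > 0:  # tail target unreachable with this family
        k = 8.0
        return k, theta_for(k)
    k = np.exp(optimize.brentq(f, lo, hi, xtol=1e-10))
    return k, theta_for(k)


def simulate_trial(config: TrialConfig) -> pd.DataFrame:
    """Simulate one two-arm trial; returns the patient-level table.

    Columns follow :data:`crosstrial.covariates.PATIENT_COLUMNS`, plus one
    ``ae_<name>_onset`` column per configured adverse event (the latent
    onset time; an event is observed if the onset precedes follow-up).
    Reproducible: same config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    m = config.covariate_margins
    n = 2 * config.n_per_arm
    arm = np.repeat(["active", "placebo"], config.n_per_arm)

    k, theta = _age_params(m)
    age = _AGE_SHIFT + rng.gamma(k, theta, size=n)
    sex = np.where(rng.random(n) < m.get("female", 0.5), "F", "M")

    # ECOG: the configured ecog0 proportion refers to the eligible (grade
    # 0/1) subpopulation; grade 2 is drawn on top at ecog2_proportion.
    p2 = config.ecog2_proportion
    p0 = m.get("ecog0", 0.6) * (1.0 - p2)
    u = rng.random(n)
    ecog = np.where(u < p0, 0, np.where(u < 1.0 - p2, 1, 2))

    dx = (rng.random(n) < m.get("dx_ge3y", 0.5)).astype(int)
    p_sites = np.array(
        [
            1.0 - m.get("n_sites_2", 1 / 3) - m.get("n_sites_ge3", 1 / 3),
            m.get("n_sites_2", 1 / 3),
            m.get("n_sites_ge3", 1 / 3),
        ]
    )
    sites = rng.choice(np.array(SITE_LEVELS), size=n, p=p_sites)
    mets = (rng.random(n) < m.get("distant_mets", 0.9)).astype(int)
    ssa = (rng.random(n) < m.get("prior_ssa", 0.4)).astype(int)
    chemo = (rng.random(n) < m.get("prior_chemo", 0.5)).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": [f"{config.label}-{i:04d}" for i in range(n)],
            "arm": arm,
            "age": age,
            "sex": sex,
            "ecog": ecog,
            "time_since_dx_ge3y": dx,
            "n_disease_sites": sites,
            "distant_mets": mets,
            "prior_ssa": ssa,
            "prior_chemo": chemo,
        }
    )

    lp = linear_predictor(df, config.covariate_log_hrs)
    trt = (arm == "active").astype(float)
    h_prog = config.baseline_hazard_pfs * np.exp(lp + trt * config.log_hr_treatment_pfs)
    h_death = config.baseline_hazard_os * np.exp(lp + trt * config.log_hr_treatment_os)

    t_prog = rng.exponential(1.0 / h_prog)
    t_death = rng.exponential(1.0 / h_death)

    cutoff = config.censor_cutoff_months
    # crossover: placebo progressors, progression observed before cutoff
    can_cross = (arm == "placebo") & (t_prog < t_death) & (t_prog < cutoff)
    crosses = can_cross & (rng.random(n) < config.crossover_probability)
    # post-crossover residual death time: exponential at the boosted hazard
    h_post = h_death * np.exp(config.post_crossover_log_hr_os)
    residual = rng.exponential(1.0 / h_post)
    t_death = np.where(crosses, t_prog + residual, t_death)

    pfs_raw = np.minimum(t_prog, t_death)
    df["pfs_time"] = np.minimum(pfs_raw, cutoff)
    df["pfs_event"] = (pfs_raw <= cutoff).astype(int)
    df["os_time"] = np.minimum(t_death, cutoff)
    df["os_event"] = (t_death <= cutoff).astype(int)
    df["crossover_time"] = np.where(crosses, t_prog, np.nan)

    for name, rates in config.ae_hazards.items():
        rate = np.where(arm == "active", rates["active"], rates["placebo"])
        df[f"ae_{name}_onset"] = rng.exponential(1.0 / rate)

    return df


@dataclass
class AggregateSummary:
    """Published-style aggregates of a trial: margins, curves, HRs."""

    margins: "TargetMargins"
    km_curves: dict[tuple[str, str], DigitizedCurve]
    at_risk: dict[tuple[str, str], AtRiskTable]
    published_hr: dict[str, tuple[float, float, float]]
    n_per_arm: dict[str, int]
    event_counts: dict[tuple[str, str], int]
    max_followup: dict[str, float]
    label: str = ""


def summarize_as_aggregate(
    records: pd.DataFrame,
    config: TrialConfig,
    grid_step: float = 1.0,
    at_risk_step: float = 8.0,
) -> AggregateSummary:
    """Reduce a simulated trial to published-style aggregates.

    The KM curves are sampled on a regular ``grid_step`` time grid (a stand-in
    for digitizing a figure) and at-risk counts are tabulated every
    ``at_risk_step`` months, emulating the table beneath a published figure.
    The patient-level records remain available to the caller as ground truth.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter

    from .maic_weights import TargetMargins, margins_from_records

    for a in ("active", "placebo"):
        if (records["arm"] == a).sum() == 0:
            raise ValueError(f"empty {a} arm")

    margins = margins_from_records(records, source=config.label)
    km_curves: dict[tuple[str, str], DigitizedCurve] = {}
    at_risk: dict[tuple[str, str], AtRiskTable] = {}
    published: dict[str, tuple[float, float, float]] = {}
    events: dict[tuple[str, str], int] = {}
    followup: dict[str, float] = {}

    cutoff = config.censor_cutoff_months
    grid = np.arange(0.0, cutoff + grid_step / 2, grid_step)
    risk_grid = np.arange(0.0, cutoff + 1e-9, at_risk_step)

    for endpoint in ("pfs", "os"):
        tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
        for a in ("active", "placebo"):
            sub = records[records["arm"] == a]
            kmf = KaplanMeierFitter()
            kmf.fit(sub[tcol], sub[ecol])
            surv = kmf.survival_function_at_times(grid).to_numpy()
            surv = np.minimum.accumulate(np.clip(surv, 0.0, 1.0))
            surv[0] = 1.0
            km_curves[(a, endpoint)] = DigitizedCurve(
                times=grid, survival=surv, arm=a, endpoint=endpoint
            )
            counts = np.array(
                [(sub[tcol].to_numpy() >= tt).sum() for tt in risk_grid], dtype=int
            )
            at_risk[(a, endpoint)] = AtRiskTable(times=risk_grid, n_at_risk=counts)
            events[(a, endpoint)] = int(sub[ecol].sum())
            followup[a] = float(sub["os_time"].max())

        fit_df = pd.DataFrame(
            {
                "t": records[tcol],
                "e": records[ecol],
                "x": (records["arm"] == "active").astype(int),
            }
        )
        by_arm_events = fit_df.groupby("x")["e"].sum()
        if (by_arm_events == 0).any():  # HR non-estimable without events
            published[endpoint] = (float("nan"), float("nan"), float("nan"))
        else:
            cph = CoxPHFitter()
            cph.fit(fit_df, duration_col="t", event_col="e")
            hr = float(np.exp(cph.params_["x"]))
            lo, hi = np.exp(cph.confidence_intervals_.loc["x"]).to_numpy()
            published[endpoint] = (hr, float(lo), float(hi))

    return AggregateSummary(
        margins=margins,
        km_curves=km_curves,
        at_risk=at_risk,
        published_hr=published,
        n_per_arm={
            "active": int((records["arm"] == "active").sum()),
            "placebo": int((records["arm"] == "placebo").sum()),
        },
        event_counts=events,
        max_followup=followup,
        label=config.label,
    )
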