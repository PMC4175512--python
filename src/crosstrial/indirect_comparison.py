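"""Assembly of the cross-trial comparisons.

Four contrast types are built from the weighted IPD, the reconstructed
pseudo-IPD and published effects:

* **Anchored (Bucher)** — two relative effects versus the shared placebo
  comparator are combined on the log scale: ``log HR_AC = log HR_AB − log
  HR_CB`` with variances summed.  Valid for PFS, which crossover does not
  touch.
* **Unanchored active vs. active** — the weighted IPD active arm is pooled
  with the comparator trial's reconstructed active arm; placebo arms are
  dropped because crossover contaminates their overall survival in both
  trials.
* **External control** — the weighted IPD active arm versus the comparator
  trial's placebo arm (itself containing crossover), summarized as a hazard
  ratio and numbers needed to treat at fixed horizons.
* **Negative control** — placebo-arm PFS across trials; a hazard ratio away
  from 1 measures residual cross-trial imbalance after matching.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .km_reconstruction import PseudoIPD
from .weighted_survival import (
    Z_975,
    ComparisonResult,
    SurvivalSample,
    WeightedKMCurve,
    weighted_cox,
    weighted_km,
)


@dataclass(frozen=True)
class PublishedEffect:
    """A published hazard ratio with its 95% confidence interval."""

    hr: float
    ci_lower: float
    ci_upper: float
    endpoint: str = ""
    trial: str = ""

    def __post_init__(self):
        if not 0 < self.ci_lower <= self.hr <= self.ci_upper:
            raise ValueError("require 0 < ci_lower <= hr <= ci_upper")


def se_from_ci(effect: PublishedEffect) -> float:
    """Log-scale standard error back-calculated from a 95% CI."""
    if effect.ci_lower <= 0:
        raise ValueError("confidence bounds must be positive")
    return float((np.log(effect.ci_upper) - np.log(effect.ci_lower)) / (2 * Z_975))


def _log_effect_and_se(effect) -> tuple[float, float, str]:
    if isinstance(effect, PublishedEffect):
        return float(np.log(effect.hr)), se_from_ci(effect), effect.endpoint
    if isinstance(effect, ComparisonResult):
        return effect.log_effect, effect.log_se, ""
    raise TypeError(f"unsupported effect type {type(effect).__name__}")


def bucher(effect_ab, effect_cb, kind: str = "anchored", label: str = "") -> ComparisonResult:
    """Anchored indirect comparison of A vs C through common comparator B.

    ``effect_ab`` may be a fitted :class:`ComparisonResult` (the weighted IPD
    HR) or a :class:`PublishedEffect`; ``effect_cb`` is typically published.
    """
    la, sa, ep_a = _log_effect_and_se(effect_ab)
    lc, sc, ep_c = _log_effect_and_se(effect_cb)
    if ep_a and ep_c and ep_a != ep_c:
        raise ValueError(f"endpoint mismatch: {ep_a!r} vs {ep_c!r}")
    d = la - lc
    se = float(np.sqrt(sa**2 + sc**2))
    p = float(2 * stats.norm.sf(abs(d) / se)) if se > 0 else float(d == 0)
    return ComparisonResult(
        effect=float(np.exp(d)),
        ci_lower=float(np.exp(d - Z_975 * se)),
        ci_upper=float(np.exp(d + Z_975 * se)),
        p_value=p,
        log_se=se,
        kind=kind,
        label=label or "anchored (Bucher) indirect comparison",
    )


def _pooled_sample(
    ipd_times,
    ipd_events,
    weights,
    pseudo: PseudoIPD,
    endpoint: str,
    ipd_label: str = "ipd",
    pseudo_label: str = "comparator",
) -> SurvivalSample:
    if weights is None:
        raise ValueError("matching weights are required (estimate them first)")
    w = np.asarray(weights, dtype=float)
    # rescale to sum to the effective sample size: pins the IPD arm's total
    # mass to its information content relative to the unit-weight pseudo-IPD
    # arm, and makes the pooled fit invariant to the weights' input scale
    if w.sum() > 0:
        w = w * (w.sum() / (w**2).sum())
    ipd = pd.DataFrame(
        {
            "time": np.asarray(ipd_times, dtype=float),
            "event": np.asarray(ipd_events).astype(int),
            "group": ipd_label,
            "weight": w,
        }
    )
    rec = pd.DataFrame(
        {
            "time": pseudo.times,
            "event": pseudo.events.astype(int),
            "group": pseudo_label,
            "weight": 1.0,
        }
    )
    return SurvivalSample(pd.concat([ipd, rec], ignore_index=True), endpoint=endpoint)


def unanchored_active_comparison(
    ipd_times, ipd_events, weights, pseudo_active: PseudoIPD, endpoint: str = "os"
) -> ComparisonResult:
    """Weighted IPD active arm vs reconstructed comparator active arm.

    Placebo arms are excluded: with crossover in both trials they no longer
    provide a common comparator for overall survival.
    """
    sample = _pooled_sample(
        ipd_times, ipd_events, weights, pseudo_active, endpoint,
        ipd_label="ipd_active", pseudo_label="comparator_active",
    )
    res = weighted_cox(sample, reference_group="comparator_active", kind="unanchored_active")
    res.label = f"ipd active vs comparator active ({endpoint})"
    return res


def external_control_comparison(
    ipd_times, ipd_events, weights, pseudo_placebo: PseudoIPD, endpoint: str = "os"
) -> tuple[ComparisonResult, WeightedKMCurve, WeightedKMCurve]:
    """Weighted IPD active arm vs the comparator trial's placebo arm.

    The external placebo arm includes any crossover its trial allowed, so the
    contrast understates the effect versus a pure placebo.  Returns the
    comparison plus both weighted KM curves for NNT computation.
    """
    sample = _pooled_sample(
        ipd_times, ipd_events, weights, pseudo_placebo, endpoint,
        ipd_label="ipd_active", pseudo_label="external_placebo",
    )
    res = weighted_cox(sample, reference_group="external_placebo", kind="external_control")
    res.label = f"ipd active vs external placebo ({endpoint})"
    km_active = weighted_km(sample, "ipd_active")
    km_control = weighted_km(sample, "external_placebo")
    return res, km_active, km_control


def negative_control(
    ipd_placebo_times, ipd_placebo_events, weights, pseudo_placebo: PseudoIPD,
    endpoint: str = "pfs",
) -> ComparisonResult:
    """Placebo-arm PFS across trials as a residual-imbalance diagnostic.

    If matching removed all prognostic differences, the two placebo arms
    should show no PFS difference; a hazard ratio away from 1 indicates the
    magnitude and direction of residual imbalance.
    """
    sample = _pooled_sample(
        ipd_placebo_times, ipd_placebo_events, weights, pseudo_placebo, endpoint,
        ipd_label="ipd_placebo", pseudo_label="comparator_placebo",
    )
    res = weighted_cox(sample, reference_group="comparator_placebo", kind="negative_control")
    res.label = f"ipd placebo vs comparator placebo ({endpoint})"
    res.notes.append(
        "HR != 1 indicates the magnitude and direction of residual "
        "cross-trial imbalance impacting PFS"
    )
    return res


@dataclass
class NNTResult:
    """Number needed to treat at a fixed horizon.

    ``nnt = 1 / (S_active − S_control)``; when the active arm does worse the
    (negative) value is reported as number needed to harm via ``harm=True``,
    keeping the magnitude convention ``|nnt| = 1/|difference|``.
    """

    horizon: float
    surv_active: float
    surv_control: float
    nnt: float
    harm: bool = False
    extrapolated: bool = False
    finite: bool = True


def nnt_at(
    km_active: WeightedKMCurve, km_control: WeightedKMCurve, horizon: float
) -> NNTResult:
    """NNT from two survival curves at a horizon (months)."""
    s_a, ex_a = km_active.survival_at(horizon)
    s_c, ex_c = km_control.survival_at(horizon)
    diff = s_a - s_c
    if diff == 0:
        return NNTResult(horizon, s_a, s_c, float("inf"), finite=False,
                         extrapolated=ex_a or ex_c)
    return NNTResult(
        horizon=horizon,
        surv_active=s_a,
        surv_control=s_c,
        nnt=1.0 / diff,
        harm=diff < 0,
        extrapolated=ex_a or ex_c,
    )


def nnt_from_probabilities(surv_active: float, surv_control: float, horizon: float) -> NNTResult:
    """NNT directly from reported survival probabilities."""
    diff = surv_active - surv_control
    if diff == 0:
        return NNTResult(horizon, surv_active, surv_control, float("inf"), finite=False)
    return NNTResult(horizon, surv_active, surv_control, 1.0 / diff, harm=diff < 0)
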