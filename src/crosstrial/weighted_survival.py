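"""Weighted Kaplan–Meier and weighted Cox proportional-hazards estimation.

Thin, opinionated layer over lifelines: every cross-trial contrast in the
package funnels through :func:`weighted_cox` (Efron tie handling, robust
sandwich variance treating the MAIC weights as fixed, Wald inference on the
log scale) and :func:`weighted_km`.  Point estimates are invariant to a
positive rescaling of the weights; only the variance convention depends on
the weights being supplied on their estimation scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

Z_975 = 1.959964  # normal 97.5% quantile, fixed for determinism


class NonEstimableError(ValueError):
    """Monotone partial likelihood: a fitted group contributes no events."""


@dataclass
class SurvivalSample:
    """Per-patient (time, event, group, weight) rows for one endpoint."""

    data: pd.DataFrame
    endpoint: str = ""

    def __post_init__(self):
        required = {"time", "event", "group", "weight"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"sample missing columns {sorted(missing)}")
        if (self.data["weight"] < 0).any():
            raise ValueError("weights must be nonnegative")
        if (self.data["time"] < 0).any():
            raise ValueError("times must be nonnegative")

    @classmethod
    def from_arrays(cls, time, event, group, weight=None, endpoint="") -> "SurvivalSample":
        df = pd.DataFrame(
            {
                "time": np.asarray(time, dtype=float),
                "event": np.asarray(event).astype(int),
                "group": group,
                "weight": 1.0 if weight is None else np.asarray(weight, dtype=float),
            }
        )
        return cls(df, endpoint=endpoint)

    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())


@dataclass
class WeightedKMCurve:
    """Weighted product-limit estimate with pointwise CIs."""

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    group: str = ""
    endpoint: str = ""
    max_time: float = 0.0

    def survival_at(self, t: float) -> tuple[float, bool]:
        """Left-continuous step value at t; flags extrapolation beyond
        follow-up."""
        if t < 0:
            raise ValueError("t must be nonnegative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        value = 1.0 if idx < 0 else float(self.survival[idx])
        return value, bool(t > self.max_time)


def survival_at(curve: WeightedKMCurve, t: float) -> tuple[float, bool]:
    return curve.survival_at(t)


@dataclass
class ComparisonResult:
    """A hazard (or odds) ratio contrast with Wald inference."""

    effect: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_se: float
    kind: str
    n_effective: dict[str, float] = field(default_factory=dict)
    label: str = ""
    notes: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not (self.ci_lower <= self.effect <= self.ci_upper):
            raise ValueError("CI must bracket the point estimate")
        if min(self.effect, self.ci_lower) <= 0:
            raise ValueError("ratio effects must be positive")

    @property
    def log_effect(self) -> float:
        return float(np.log(self.effect))

    def to_dict(self) -> dict:
        return {
            "effect": self.effect,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "p_value": self.p_value,
            "log_se": self.log_se,
            "kind": self.kind,
            "label": self.label,
            "n_effective": self.n_effective,
            "notes": self.notes,
        }


def weighted_km(sample: SurvivalSample, group: str, alpha: float = 0.05) -> WeightedKMCurve:
    """Weighted Kaplan–Meier curve for one group of the sample."""
    sub = sample.data[sample.data["group"] == group]
    if len(sub) == 0:
        raise ValueError(f"group {group!r} not present in sample")
    kmf = KaplanMeierFitter(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kmf.fit(sub["time"], sub["event"], weights=sub["weight"].to_numpy())
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    return WeightedKMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        group=group,
        endpoint=sample.endpoint,
        max_time=float(sub["time"].max()),
    )


def effective_n(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum()) if w.sum() > 0 else 0.0


def weighted_cox(
    sample: SurvivalSample,
    reference_group: str,
    kind: str = "unanchored_active",
    label: str = "",
) -> ComparisonResult:
    """Weighted Cox PH fit of a two-group contrast versus the reference.

    The hazard ratio is for the non-reference group relative to
    ``reference_group``.  Variance is the weight-robust sandwich estimator;
    ties use Efron's convention.
    """
    groups = sample.groups()
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not in sample")
    other = next(g for g in groups if g != reference_group)

    df = sample.data.copy()
    for g in groups:
        sub = df[df["group"] == g]
        if (sub["event"] * sub["weight"]).sum() == 0:
            raise NonEstimableError(
                f"group {g!r} contributes no weighted events: "
                "hazard ratio non-estimable (monotone likelihood)"
            )
    fit = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"],
            "x": (df["group"] == other).astype(int),
            "w": df["weight"],
        }
    )
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit, duration_col="time", event_col="event", weights_col="w", robust=True)
    b = float(cph.params_["x"])
    se = float(cph.standard_errors_["x"])
    p = float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else float(b == 0)
    n_eff = {
        g: effective_n(df.loc[df["group"] == g, "weight"].to_numpy()) for g in groups
    }
    return ComparisonResult(
        effect=float(np.exp(b)),
        ci_lower=float(np.exp(b - Z_975 * se)),
        ci_upper=float(np.exp(b + Z_975 * se)),
        p_value=p,
        log_se=se,
        kind=kind,
        n_effective=n_eff,
        label=label or f"{other} vs {reference_group} ({sample.endpoint})",
    )
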