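"""Matching-adjusted indirect comparison (MAIC) weight estimation.

Individual patients from the IPD trial are reweighted so that, after
weighting, the baseline medians of continuous covariates and proportions of
binary covariates exactly match those reported for the comparator trial.
Each patient's weight is proportional to their relative propensity of
enrolling in the IPD trial versus the comparator; with no comparator IPD
available the propensity model reduces to exponential tilting estimated by
the method of moments:

    w_i = exp(a' (x_i - x_target))

with coefficients ``a`` minimizing the convex objective
``Q(a) = sum_i exp(a' (x_i - x_target))``.  The first-order condition of Q is
precisely the moment constraint that the weighted mean of every matched
column equals its target — the "exact balance" property.  Median targets are
matched by converting them to proportion targets: the indicator
``1{x > reported median}`` is balanced to 0.5 (ties at the median count as
below it).

The effective sample size ``ESS = (sum w)^2 / sum w^2`` quantifies the
information remaining after weighting; heavy down-weighting of patients
unlike the comparator population shrinks it well below n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .covariates import feature

#: proportion-type margins matched in the default analysis, in display order
DEFAULT_PROPORTION_MARGINS = [
    "age_gt_64",
    "female",
    "ecog0",
    "dx_ge3y",
    "n_sites_2",
    "n_sites_ge3",
    "distant_mets",
    "prior_ssa",
    "prior_chemo",
]


class ConvergenceError(RuntimeError):
    """Weight estimation failed; message distinguishes infeasibility
    (target outside the convex hull of the data — separation) from a plain
    tolerance failure."""


@dataclass(frozen=True)
class MarginEntry:
    name: str
    kind: str  # "proportion" | "median"
    value: float

    def __post_init__(self):
        if self.kind not in ("proportion", "median"):
            raise ValueError(f"unknown margin kind {self.kind!r}")
        if self.kind == "proportion" and not 0.0 <= self.value <= 1.0:
            raise ValueError(f"proportion target {self.name}={self.value} outside [0,1]")


@dataclass
class TargetMargins:
    """Reported baseline summaries of the comparator trial."""

    entries: list[MarginEntry]
    source: str = ""
    comparator_n: int | None = None

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("each covariate may appear only once")

    def __iter__(self):
        return iter(self.entries)

    @classmethod
    def from_dict(
        cls, margins: dict[str, float], source: str = "", comparator_n: int | None = None
    ) -> "TargetMargins":
        """Build from a flat mapping; the key ``age_median`` becomes a median
        entry on ``age``, everything else a proportion entry."""
        entries = []
        for name, value in margins.items():
            if name.endswith("_median"):
                entries.append(MarginEntry(name[: -len("_median")], "median", value))
            else:
                entries.append(MarginEntry(name, "proportion", value))
        return cls(entries=entries, source=source, comparator_n=comparator_n)


def margins_from_records(records: pd.DataFrame, source: str = "") -> TargetMargins:
    """Summarize a patient table into the margin set used for matching."""
    entries = [MarginEntry("age", "median", float(records["age"].median()))]
    for name in DEFAULT_PROPORTION_MARGINS:
        entries.append(MarginEntry(name, "proportion", float(feature(records, name).mean())))
    return TargetMargins(entries=entries, source=source, comparator_n=len(records))


def apply_eligibility(
    records: pd.DataFrame,
    excluded_ecog_levels: tuple[int, ...] = (2,),
    drop_missing: bool = True,
    matched_columns: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Harmonize trial eligibility before matching.

    Removes patients whose ECOG grade the comparator trial excluded, then
    (optionally) patients with any missing matched baseline covariate.
    Returns the retained table and per-reason exclusion counts.
    """
    counts = {"total": len(records)}
    kept = records
    mask_ecog = kept["ecog"].isin(excluded_ecog_levels)
    counts["excluded_ecog"] = int(mask_ecog.sum())
    kept = kept[~mask_ecog]
    if drop_missing:
        cols = list(
            matched_columns
            if matched_columns is not None
            else [
                "age",
                "sex",
                "ecog",
                "time_since_dx_ge3y",
                "n_disease_sites",
                "distant_mets",
                "prior_ssa",
                "prior_chemo",
            ]
        )
        mask_missing = kept[cols].isna().any(axis=1)
        counts["excluded_missing"] = int(mask_missing.sum())
        kept = kept[~mask_missing]
    else:
        counts["excluded_missing"] = 0
    counts["retained"] = len(kept)
    if len(kept) == 0:
        raise ValueError("eligibility harmonization excluded every patient")
    return kept.reset_index(drop=True), counts


def build_design(
    records: pd.DataFrame, margins: TargetMargins
) -> tuple[pd.DataFrame, pd.Series]:
    """Design matrix and target vector for the moment constraints.

    Proportion margins give the 0/1 feature with the reported proportion as
    target; median margins give the indicator ``1{x > median}`` with target
    0.5.  Multi-level categoricals enter as k−1 indicator margins with the
    omitted level as reference.
    """
    cols, targets = {}, {}
    for entry in margins:
        if entry.kind == "proportion":
            try:
                cols[entry.name] = feature(records, entry.name)
            except KeyError as err:
                raise KeyError(str(err)) from None
            targets[entry.name] = entry.value
        else:
            if entry.name not in records.columns:
                raise KeyError(
                    f"covariate {entry.name!r} cannot be resolved from the patient table"
                )
            key = f"{entry.name}_gt_median"
            cols[key] = (records[entry.name] > entry.value).astype(float)
            targets[key] = 0.5
    X = pd.DataFrame(cols, index=records.index)
    return X, pd.Series(targets, dtype=float)


@dataclass
class WeightVector:
    """Estimated MAIC weights plus diagnostics."""

    weights: np.ndarray
    coefficients: pd.Series
    ess: float
    converged: bool
    balance_report: pd.DataFrame
    index: pd.Index = field(default=None)  # type: ignore[assignment]

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def normalized(self) -> np.ndarray:
        """Weights rescaled to sum to the ESS (display convention; estimates
        are invariant to any positive rescaling)."""
        return self.weights * (self.ess / self.weights.sum())


def estimate_weights(
    design: pd.DataFrame,
    targets: pd.Series,
    grad_tol: float = 1e-10,
    balance_tol: float = 1e-8,
    max_iter: int = 200,
) -> WeightVector:
    """Method-of-moments exponential tilting.

    Newton iteration on the convex objective ``sum_i exp(a'(x_i - t))`` with
    analytic gradient and Hessian; converges quadratically whenever the
    target lies strictly inside the convex hull of the design rows.  A
    diverging coefficient norm signals an infeasible target (separation) and
    raises :class:`ConvergenceError` saying so.
    """
    X = design.to_numpy(dtype=float)
    t = targets.loc[design.columns].to_numpy(dtype=float)
    n, p = X.shape
    Xc = X - t
    a = np.zeros(p)

    def objective(a):
        return np.exp(Xc @ a).sum()

    for _ in range(max_iter):
        w = np.exp(Xc @ a)
        g = Xc.T @ w
        # g / sum(w) is the weighted-mean deviation from target per column
        if np.linalg.norm(g, ord=np.inf) / w.sum() <= grad_tol:
            break
        H = Xc.T @ (w[:, None] * Xc)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the objective decreases
        f0, lam = objective(a), 1.0
        for _ in range(60):
            a_new = a - lam * step
            if objective(a_new) < f0:
                break
            lam /= 2.0
        a = a_new
        if np.linalg.norm(a, ord=np.inf) > 200.0:
            raise ConvergenceError(
                "weight estimation diverged: target margins appear infeasible "
                "(outside the convex hull of the sample — separation)"
            )

    w = np.exp(Xc @ a)
    post = (w @ X) / w.sum()
    if np.max(np.abs(post - t)) > balance_tol:
        raise ConvergenceError(
            "weight estimation did not reach balance tolerance "
            f"(max deviation {np.max(np.abs(post - t)):.3g})"
        )

    ess = float(w.sum() ** 2 / (w**2).sum())
    report = pd.DataFrame(
        {
            "pre_match": X.mean(axis=0),
            "post_match": post,
            "target": t,
        },
        index=design.columns,
    )
    return WeightVector(
        weights=w,
        coefficients=pd.Series(a, index=design.columns),
        ess=ess,
        converged=True,
        balance_report=report,
        index=design.index,
    )


def balance_tests(
    records: pd.DataFrame, margins: TargetMargins, alpha: float = 0.05
) -> pd.DataFrame:
    """Pre-matching comparison of baseline covariates against reported values.

    Proportions: two-sample chi-square (pooled two-proportion test, no
    continuity correction) between the IPD sample and the comparator's
    reported proportion at its reported n.  Continuous covariates: a
    two-sample t approximation treating the reported median as the comparator
    mean and borrowing the IPD standard deviation, since published aggregates
    carry no dispersion.
    """
    if margins.comparator_n is None:
        raise ValueError("comparator sample size required for balance tests")
    n1, n2 = len(records), margins.comparator_n
    rows = []
    for entry in margins:
        if entry.kind == "proportion":
            p1 = float(feature(records, entry.name).mean())
            p2 = entry.value
            pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
            denom = pbar * (1 - pbar) * (1 / n1 + 1 / n2)
            chi2 = 0.0 if denom == 0 else (p1 - p2) ** 2 / denom
            pval = float(stats.chi2.sf(chi2, df=1))
            stat, ipd_value = chi2, p1
            test = "chi-square"
        else:
            x = records[entry.name].astype(float)
            sd = float(x.std(ddof=1))
            tstat = (x.mean() - entry.value) / (sd * np.sqrt(1 / n1 + 1 / n2))
            pval = float(2 * stats.t.sf(abs(tstat), df=n1 + n2 - 2))
            stat, ipd_value = float(tstat), float(x.mean())
            test = "t"
        rows.append(
            {
                "covariate": entry.name,
                "kind": entry.kind,
                "ipd_value": ipd_value,
                "reported_value": entry.value,
                "test": test,
                "statistic": stat,
                "p_value": pval,
                "significant": pval < alpha,
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
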