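"""Placebo-adjusted adverse-event odds ratios across trials.

Adverse events are monitored for as long as patients are followed, so a
trial with longer follow-up mechanically accrues more events.  Before
comparing, the IPD trial's AE observations are censored at the maximum
follow-up of the matching comparator arm.  The cross-trial contrast for each
event is then the ratio of within-trial odds ratios,

    OR_adj = OR(active vs placebo, weighted IPD) / OR(active vs placebo, comparator),

with a Woolf log-scale variance summed over the (effective) cell counts.
Weighted IPD cells are scaled to the arm's effective sample size so the
variance reflects the information actually present after weighting rather
than the raw weighted counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .weighted_survival import Z_975, ComparisonResult, effective_n


@dataclass
class AETable:
    """Per-event 2×2 counts (or rates) for one trial's two arms.

    ``counts`` is indexed by AE name with columns ``events_active``,
    ``n_active``, ``events_placebo``, ``n_placebo``.  For an IPD trial,
    ``patient_flags`` additionally carries the per-patient censored
    indicators (with an ``arm`` column) so that MAIC weights can be applied.
    """

    counts: pd.DataFrame
    cutoffs: dict[str, float] = field(default_factory=dict)
    trial: str = ""
    patient_flags: pd.DataFrame | None = None

    def __post_init__(self):
        need = {"events_active", "n_active", "events_placebo", "n_placebo"}
        if not need <= set(self.counts.columns):
            raise ValueError(f"counts must have columns {sorted(need)}")
        for arm in ("active", "placebo"):
            if (self.counts[f"events_{arm}"] > self.counts[f"n_{arm}"]).any():
                raise ValueError("events cannot exceed patients at risk")

    def rates(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.counts.index)
        for arm in ("active", "placebo"):
            out[arm] = self.counts[f"events_{arm}"] / self.counts[f"n_{arm}"]
        return out

    @classmethod
    def from_rates(
        cls, rates: dict[str, tuple[float, float]], n_active: int, n_placebo: int,
        cutoffs: dict[str, float] | None = None, trial: str = "",
    ) -> "AETable":
        """Build from reported (active, placebo) rate pairs."""
        rows = {
            name: {
                "events_active": round(ra * n_active),
                "n_active": n_active,
                "events_placebo": round(rp * n_placebo),
                "n_placebo": n_placebo,
            }
            for name, (ra, rp) in rates.items()
        }
        return cls(pd.DataFrame(rows).T, cutoffs=cutoffs or {}, trial=trial)


def censor_ae_followup(
    records: pd.DataFrame, cutoffs: dict[str, float], trial: str = ""
) -> AETable:
    """Censor IPD adverse events at the comparator's per-arm follow-up.

    An event counts only if its onset time (``ae_<name>_onset`` column)
    precedes both the patient's own follow-up and the matched arm's cutoff.
    """
    ae_cols = [c for c in records.columns if c.startswith("ae_") and c.endswith("_onset")]
    names = [c[3:-6] for c in ae_cols]
    if not names:
        raise ValueError("no adverse-event onset columns (ae_<name>_onset) found")
    missing = [n for n, c in zip(names, ae_cols) if records[c].isna().any()]
    if missing:
        raise ValueError(f"missing AE onset times for: {', '.join(missing)}")

    flags = pd.DataFrame({"arm": records["arm"].to_numpy()}, index=records.index)
    rows = {}
    for name, col in zip(names, ae_cols):
        cut = records["arm"].map(cutoffs).astype(float)
        observed = records[col].to_numpy() <= np.minimum(
            records["os_time"].to_numpy(), cut.to_numpy()
        )
        flags[name] = observed.astype(int)
        rows[name] = {
            "events_active": int(observed[records["arm"] == "active"].sum()),
            "n_active": int((records["arm"] == "active").sum()),
            "events_placebo": int(observed[records["arm"] == "placebo"].sum()),
            "n_placebo": int((records["arm"] == "placebo").sum()),
        }
    return AETable(
        counts=pd.DataFrame(rows).T,
        cutoffs=dict(cutoffs),
        trial=trial,
        patient_flags=flags,
    )


def _weighted_cells(flags: pd.DataFrame, name: str, weights: np.ndarray) -> dict[str, float]:
    """Effective 2×2 cells: weighted proportions scaled to per-arm ESS."""
    cells = {}
    for arm in ("active", "placebo"):
        mask = (flags["arm"] == arm).to_numpy()
        w = weights[mask]
        p = float((w * flags.loc[mask, name].to_numpy()).sum() / w.sum())
        ess = effective_n(w)
        cells[f"events_{arm}"] = p * ess
        cells[f"n_{arm}"] = ess
    return cells


def _log_or(cells: dict[str, float]) -> tuple[float, float, bool]:
    """Log odds ratio and Woolf variance from a 2×2; continuity-corrects
    zero cells by adding 0.5 to all four."""
    a = cells["events_active"]
    b = cells["n_active"] - a
    c = cells["events_placebo"]
    d = cells["n_placebo"] - c
    corrected = min(a, b, c, d) <= 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log((a * d) / (b * c)))
    var = 1 / a + 1 / b + 1 / c + 1 / d
    return log_or, float(var), corrected


def placebo_adjusted_or(
    ipd_table: AETable,
    comparator_table: AETable,
    weights: np.ndarray | None = None,
    reporting_threshold: float = 0.05,
) -> dict[str, ComparisonResult]:
    """Ratio of within-trial ORs for every AE present in both tables.

    ``weights`` (MAIC weights aligned with ``ipd_table.patient_flags``)
    reweight the IPD cells; omit for an unweighted comparison.  AEs whose
    comparator rate falls below the reporting threshold on every arm are
    flagged non-comparable (published sources omit rare events).
    """
    shared = [n for n in ipd_table.counts.index if n in comparator_table.counts.index]
    results: dict[str, ComparisonResult] = {}
    comp_rates = comparator_table.rates()
    for name in shared:
        if weights is not None:
            if ipd_table.patient_flags is None:
                raise ValueError("weighted comparison requires per-patient AE flags")
            ipd_cells = _weighted_cells(ipd_table.patient_flags, name, np.asarray(weights, float))
        else:
            ipd_cells = ipd_table.counts.loc[name].astype(float).to_dict()
        comp_cells = comparator_table.counts.loc[name].astype(float).to_dict()

        l1, v1, c1 = _log_or(ipd_cells)
        l2, v2, c2 = _log_or(comp_cells)
        d = l1 - l2
        se = float(np.sqrt(v1 + v2))
        p = float(2 * stats.norm.sf(abs(d) / se))
        res = ComparisonResult(
            effect=float(np.exp(d)),
            ci_lower=float(np.exp(d - Z_975 * se)),
            ci_upper=float(np.exp(d + Z_975 * se)),
            p_value=p,
            log_se=se,
            kind="adverse_event",
            label=name,
        )
        if c1 or c2:
            res.notes.append("continuity correction (0.5) applied to a zero cell")
        if (comp_rates.loc[name] < reporting_threshold).all():
            res.notes.append(
                f"comparator rates below the {reporting_threshold:.0%} reporting "
                "threshold: non-comparable"
            )
        results[name] = res
    return results
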