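"""End-to-end orchestration of the matching-adjusted indirect comparison.

``run_analysis`` executes, in order: eligibility harmonization → balance
tests → weight estimation → pseudo-IPD reconstruction with verification →
anchored (Bucher) PFS comparison → unanchored active-vs-active OS/PFS →
external-control OS with NNT → placebo-PFS negative control → adverse-event
odds ratios.  Every stage's output lands in a machine-readable results
bundle; a stage failure aborts with the stage name while preserving the
partial results written so far.

``write_synthetic_study`` materializes a complete synthetic input set (IPD
CSV plus published-style comparator files) so the pipeline can be exercised
without proprietary trial data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .ae_comparison import censor_ae_followup, placebo_adjusted_or
from .indirect_comparison import (
    PublishedEffect,
    bucher,
    external_control_comparison,
    negative_control,
    nnt_at,
    unanchored_active_comparison,
)
from .km_reconstruction import reconstruct_pseudo_ipd, verify_reconstruction
from .maic_weights import apply_eligibility, balance_tests, build_design, estimate_weights
from .synthetic_trials import (
    comparator_trial_config,
    ipd_trial_config,
    simulate_trial,
    summarize_as_aggregate,
)
from .weighted_survival import SurvivalSample, weighted_cox


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """File manifest and options for one full analysis run."""

    ipd_csv: str
    margins_json: str
    curves: list[dict]  # entries: arm, endpoint, curve_csv, at_risk_csv[, total_events]
    published_effects: list[dict]
    comparator_ae_json: str | None = None
    excluded_ecog_levels: tuple[int, ...] = (2,)
    drop_missing: bool = True
    horizons: tuple[float, ...] = (12.0, 24.0)
    seed: int = 0
    out_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = io.read_config_yaml(path)
        elig = raw.pop("eligibility", {})
        return cls(
            ipd_csv=raw["ipd_csv"],
            margins_json=raw["margins_json"],
            curves=raw["curves"],
            published_effects=raw.get("published_effects", []),
            comparator_ae_json=raw.get("comparator_ae_json"),
            excluded_ecog_levels=tuple(elig.get("excluded_ecog_levels", (2,))),
            drop_missing=bool(elig.get("drop_missing", True)),
            horizons=tuple(raw.get("horizons", (12.0, 24.0))),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir", "results"),
        )

    def validate(self) -> None:
        for p in [self.ipd_csv, self.margins_json, self.comparator_ae_json] + [
            c[k] for c in self.curves for k in ("curve_csv", "at_risk_csv")
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if any(h <= 0 for h in self.horizons):
            raise ValueError("horizons must be positive")


@dataclass
class ReportBundle:
    results: dict
    balance_table: pd.DataFrame
    comparisons: pd.DataFrame
    log: list[str] = field(default_factory=list)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    results: dict = {"seed": config.seed}

    def note(msg: str) -> None:
        log.append(f"{datetime.datetime.now().isoformat(timespec='seconds')} {msg}")

    def finalize_partial() -> None:
        io.write_results_json(results, out / "results.json")
        (out / "run.log").write_text("\n".join(log) + "\n")

    stage = "load_inputs"
    try:
        records = io.read_ipd_csv(config.ipd_csv)
        margins = io.read_margins_json(config.margins_json)
        published = {
            e["endpoint"]: PublishedEffect(
                hr=e["hr"], ci_lower=e["ci_lower"], ci_upper=e["ci_upper"],
                endpoint=e["endpoint"], trial=e.get("trial", ""),
            )
            for e in config.published_effects
        }
        note(f"loaded {len(records)} patients; {len(margins.entries)} target margins")

        stage = "eligibility"
        retained, excl = apply_eligibility(
            records, config.excluded_ecog_levels, config.drop_missing
        )
        results["eligibility"] = excl
        note(f"eligibility: {excl}")

        stage = "balance_tests"
        bal = balance_tests(retained, margins)
        results["balance_pre_match"] = bal.reset_index().to_dict(orient="records")

        stage = "weighting"
        X, targets = build_design(retained, margins)
        wv = estimate_weights(X, targets)
        results["weights"] = {
            "ess": wv.ess,
            "n": wv.n,
            "coefficients": wv.coefficients.to_dict(),
            "max_balance_deviation": float(
                (wv.balance_report["post_match"] - wv.balance_report["target"]).abs().max()
            ),
        }
        note(f"weights: ESS {wv.ess:.1f} of n={wv.n}")

        stage = "reconstruction"
        pseudo = {}
        verification = {}
        for spec_ in config.curves:
            key = (spec_["arm"], spec_["endpoint"])
            curve = io.read_curve_csv(spec_["curve_csv"], *key)
            table = io.read_at_risk_csv(spec_["at_risk_csv"])
            pseudo[key] = reconstruct_pseudo_ipd(curve, table, spec_.get("total_events"))
        for endpoint in {k[1] for k in pseudo}:
            if ("active", endpoint) in pseudo and ("placebo", endpoint) in pseudo and endpoint in published:
                rep = verify_reconstruction(
                    pseudo[("active", endpoint)],
                    published_hr=published[endpoint].hr,
                    comparison_arm=pseudo[("placebo", endpoint)],
                )
                verification[endpoint] = {
                    "recomputed_hr": rep.recomputed_hr,
                    "published_hr": rep.published_hr,
                    "relative_deviation": rep.hr_relative_deviation,
                    "passed": rep.passed,
                }
        results["reconstruction_verification"] = verification
        note(f"reconstructed {len(pseudo)} curves; verification: {verification}")

        comparisons: list[dict] = []

        stage = "anchored_pfs"
        if "pfs" in published:
            for matched, weights_vec in (
                (False, np.ones(len(retained))),
                (True, wv.weights),
            ):
                sample = SurvivalSample.from_arrays(
                    retained["pfs_time"], retained["pfs_event"], retained["arm"],
                    weights_vec, endpoint="pfs",
                )
                within = weighted_cox(sample, reference_group="placebo", kind="anchored")
                within.label = f"ipd active vs placebo (pfs, {'after' if matched else 'before'} matching)"
                anch = bucher(within, published["pfs"])
                anch.label = f"anchored active vs comparator-active (pfs, {'after' if matched else 'before'} matching)"
                comparisons.append({**within.to_dict(), "matched": matched})
                comparisons.append({**anch.to_dict(), "matched": matched})

        act = retained[retained["arm"] == "active"]
        plc = retained[retained["arm"] == "placebo"]
        w_act = wv.weights[(retained["arm"] == "active").to_numpy()]
        w_plc = wv.weights[(retained["arm"] == "placebo").to_numpy()]

        stage = "unanchored_active"
        for endpoint in ("os", "pfs"):
            key = ("active", endpoint)
            if key in pseudo:
                res = unanchored_active_comparison(
                    act[f"{endpoint}_time"], act[f"{endpoint}_event"], w_act,
                    pseudo[key], endpoint=endpoint,
                )
                comparisons.append({**res.to_dict(), "matched": True})

        stage = "external_control"
        if ("placebo", "os") in pseudo:
            res, km_a, km_c = external_control_comparison(
                act["os_time"], act["os_event"], w_act, pseudo[("placebo", "os")]
            )
            comparisons.append({**res.to_dict(), "matched": True})
            nnts = []
            for h in config.horizons:
                r = nnt_at(km_a, km_c, h)
                nnts.append(
                    {
                        "horizon_months": h,
                        "surv_active": r.surv_active,
                        "surv_control": r.surv_control,
                        "nnt": round(r.nnt, 1) if r.finite else None,
                        "harm": r.harm,
                        "extrapolated": r.extrapolated,
                    }
                )
            results["nnt"] = nnts
            pd.DataFrame(
                {"time": km_a.times, "survival": km_a.survival}
            ).to_csv(out / "km_external_active.csv", index=False)
            pd.DataFrame(
                {"time": km_c.times, "survival": km_c.survival}
            ).to_csv(out / "km_external_placebo.csv", index=False)

        stage = "negative_control"
        if ("placebo", "pfs") in pseudo:
            res = negative_control(
                plc["pfs_time"], plc["pfs_event"], w_plc, pseudo[("placebo", "pfs")]
            )
            comparisons.append({**res.to_dict(), "matched": True})

        stage = "ae_comparison"
        if config.comparator_ae_json is not None:
            comp_ae = io.read_comparator_ae_json(config.comparator_ae_json)
            ipd_ae = censor_ae_followup(retained, comp_ae.cutoffs or {"active": np.inf, "placebo": np.inf})
            ors = placebo_adjusted_or(ipd_ae, comp_ae, weights=wv.weights)
            for name, res in ors.items():
                comparisons.append({**res.to_dict(), "matched": True})

        results["comparisons"] = comparisons
        comp_df = pd.DataFrame(comparisons)
        bal_out = wv.balance_report.copy()
        bal_out.to_csv(out / "balance_table.csv")
        comp_df.to_csv(out / "comparisons.csv", index=False)
        finalize_partial()
        note("analysis complete")
        return ReportBundle(results=results, balance_table=bal_out, comparisons=comp_df, log=log)
    except Exception as err:  # noqa: BLE001 - annotate stage and preserve partials
        note(f"FAILED at stage {stage}: {err}")
        finalize_partial()
        if isinstance(err, PipelineError):
            raise
        raise PipelineError(stage, err) from err


def write_synthetic_study(out_dir, seed: int = 0, n_ipd_per_arm: int = 205,
                          n_comp_per_arm: int = 86) -> AnalysisConfig:
    """Generate a full synthetic two-trial study on disk and its config.

    The IPD trial is written as a patient CSV (with a small number of
    ECOG-2 patients so eligibility harmonization has work to do); the
    comparator trial is simulated, then reduced to published-style files:
    margin JSON, digitized curves, at-risk tables, HR+CI entries and an
    adverse-event summary.  The comparator's patient table is withheld from
    the config — it exists only as simulation ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)

    ipd_cfg = ipd_trial_config(seed=rng_seed, n_per_arm=n_ipd_per_arm,
                               ecog2_proportion=15 / 410)
    comp_cfg = comparator_trial_config(seed=rng_seed + 1, n_per_arm=n_comp_per_arm)

    ipd = simulate_trial(ipd_cfg)
    comp = simulate_trial(comp_cfg)
    io.write_ipd_csv(ipd, out / "ipd_trial.csv")

    agg = summarize_as_aggregate(comp, comp_cfg)
    io.write_margins_json(agg.margins, out / "comparator_margins.json")

    curves = []
    for (arm, endpoint), curve in agg.km_curves.items():
        cpath = out / f"comparator_{arm}_{endpoint}_curve.csv"
        apath = out / f"comparator_{arm}_{endpoint}_at_risk.csv"
        io.write_curve_csv(curve, cpath)
        io.write_at_risk_csv(agg.at_risk[(arm, endpoint)], apath)
        curves.append(
            {
                "arm": arm,
                "endpoint": endpoint,
                "curve_csv": str(cpath),
                "at_risk_csv": str(apath),
                "total_events": agg.event_counts[(arm, endpoint)],
            }
        )

    published = [
        {
            "endpoint": ep,
            "trial": comp_cfg.label,
            "hr": hr,
            "ci_lower": lo,
            "ci_upper": hi,
        }
        for ep, (hr, lo, hi) in agg.published_hr.items()
    ]

    comp_ae = censor_ae_followup(
        comp,
        {"active": agg.max_followup["active"], "placebo": agg.max_followup["placebo"]},
        trial=comp_cfg.label,
    )
    comp_ae.patient_flags = None  # published table only
    io.write_comparator_ae_json(comp_ae, out / "comparator_ae.json")

    config = AnalysisConfig(
        ipd_csv=str(out / "ipd_trial.csv"),
        margins_json=str(out / "comparator_margins.json"),
        curves=curves,
        published_effects=published,
        comparator_ae_json=str(out / "comparator_ae.json"),
        seed=rng_seed,
        out_dir=str(out / "results"),
    )
    io.write_config_yaml(
        {
            "ipd_csv": config.ipd_csv,
            "margins_json": config.margins_json,
            "curves": config.curves,
            "published_effects": config.published_effects,
            "comparator_ae_json": config.comparator_ae_json,
            "eligibility": {"excluded_ecog_levels": [2], "drop_missing": True},
            "horizons": [12, 24],
            "seed": config.seed,
            "out_dir": config.out_dir,
        },
        out / "analysis.yaml",
    )
    return config
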