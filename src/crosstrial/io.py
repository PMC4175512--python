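"""Readers and writers for the pipeline's on-disk formats.

Patient tables are CSV; target margins, published effects and comparator AE
summaries are JSON; digitized curves and at-risk tables are two-column CSV;
analysis configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ae_comparison import AETable
from .km_reconstruction import AtRiskTable, DigitizedCurve
from .maic_weights import MarginEntry, TargetMargins


def write_ipd_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_ipd_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "n_disease_sites" in df.columns:
        df["n_disease_sites"] = df["n_disease_sites"].astype(str)
    return df


def write_margins_json(margins: TargetMargins, path) -> None:
    payload = {
        "source": margins.source,
        "comparator_n": margins.comparator_n,
        "entries": [
            {"name": e.name, "kind": e.kind, "value": e.value} for e in margins
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_margins_json(path) -> TargetMargins:
    payload = json.loads(Path(path).read_text())
    return TargetMargins(
        entries=[MarginEntry(**e) for e in payload["entries"]],
        source=payload.get("source", ""),
        comparator_n=payload.get("comparator_n"),
    )


def write_curve_csv(curve: DigitizedCurve, path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve_csv(path, arm: str = "", endpoint: str = "") -> DigitizedCurve:
    df = pd.read_csv(path)
    return DigitizedCurve(
        times=df["time_months"].to_numpy(),
        survival=df["survival_probability"].to_numpy(),
        arm=arm,
        endpoint=endpoint,
    )


def write_at_risk_csv(table: AtRiskTable, path) -> None:
    pd.DataFrame({"time_months": table.times, "n_at_risk": table.n_at_risk}).to_csv(
        path, index=False
    )


def read_at_risk_csv(path) -> AtRiskTable:
    df = pd.read_csv(path)
    return AtRiskTable(times=df["time_months"].to_numpy(), n_at_risk=df["n_at_risk"].to_numpy())


def write_comparator_ae_json(table: AETable, path) -> None:
    payload = {
        "trial": table.trial,
        "cutoffs": table.cutoffs,
        "counts": {
            name: {k: float(v) for k, v in row.items()}
            for name, row in table.counts.iterrows()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_comparator_ae_json(path) -> AETable:
    payload = json.loads(Path(path).read_text())
    counts = pd.DataFrame(payload["counts"]).T
    return AETable(counts=counts, cutoffs=payload.get("cutoffs", {}), trial=payload.get("trial", ""))


def read_config_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def write_config_yaml(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def write_results_json(results: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(results), indent=2, sort_keys=True))
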