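import numpy as np
import pandas as pd
import pytest

import crosstrial as ct


@pytest.fixture(scope="session")
def ipd_394():
    """Simulated IPD trial with 394 eligible patients at the pre-match margins."""
    cfg = ct.ipd_trial_config(seed=42, n_per_arm=197)
    return ct.simulate_trial(cfg), cfg


@pytest.fixture(scope="session")
def comparator_aggregate():
    """Simulated comparator trial reduced to published-style aggregates,
    with its patient table kept as ground truth."""
    cfg = ct.comparator_trial_config(seed=43, n_per_arm=86)
    records = ct.simulate_trial(cfg)
    return records, ct.summarize_as_aggregate(records, cfg), cfg


@pytest.fixture(scope="session")
def synthetic_study(tmp_path_factory):
    """Small on-disk synthetic study plus its completed analysis run."""
    out = tmp_path_factory.mktemp("study")
    cfg = ct.write_synthetic_study(out, seed=7, n_ipd_per_arm=120, n_comp_per_arm=70)
    bundle = ct.run_analysis(cfg)
    return cfg, bundle


@pytest.fixture
def toy_survival():
    """Five patients, one weighted double, for hand-checked product limits."""
    return pd.DataFrame(
        {
            "time": [2.0, 4.0, 4.0, 7.0, 9.0],
            "event": [1, 1, 0, 1, 0],
            "group": "a",
            "weight": [2.0, 1.0, 1.0, 1.0, 1.0],
        }
    )


def km_oracle(times, events, weights, at_time):
    """Brute-force weighted product-limit estimate at a time point."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    weights = np.asarray(weights, float)
    s = 1.0
    for t in sorted(set(times[(events == 1) & (times <= at_time)])):
        at_risk = weights[times >= t].sum()
        d = weights[(times == t) & (events == 1)].sum()
        s *= 1.0 - d / at_risk
    return s
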