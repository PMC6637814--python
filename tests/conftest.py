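import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pulseqc as pq

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_panel(data: dict, step_minutes: int = 10) -> pq.HormonePanel:
    """Build a HormonePanel from {participant: {hormone: values}}."""
    frames = {}
    for p, cols in data.items():
        n = len(next(iter(cols.values())))
        frames[p] = pd.DataFrame(
            {h: np.asarray(v, dtype=float) for h, v in cols.items()},
            index=np.arange(n),
        )
    values = pd.concat(frames, names=["participant", "time"])
    return pq.HormonePanel(values=values, step_minutes=step_minutes)


@pytest.fixture
def tiny_panel() -> pq.HormonePanel:
    """One participant, 12 time points, glucose + insulin."""
    rng = np.random.default_rng(0)
    return make_panel(
        {
            "P1": {
                "glucose": 5.0 + 0.1 * rng.standard_normal(12),
                "insulin": 8.0 + 0.5 * rng.standard_normal(12),
            }
        }
    )


@pytest.fixture(scope="session")
def sim_panel_truth() -> tuple[pq.HormonePanel, pq.SimulationTruth]:
    """Two simulated participants with default error injection."""
    cfg = pq.SimulationConfig(n_participants=2)
    return pq.simulate_panel(cfg, seed=7)
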