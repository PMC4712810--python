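import numpy as np
import pandas as pd
import pytest

import driftdive as dd


def make_fragment(**overrides) -> dict:
    """A candidate fragment that satisfies all seven criteria."""
    base = dict(
        dive_id="d1", individual_id="s1", fragment_index=2,
        t_start_s=100.0, t_end_s=700.0, depth_start_m=150.0,
        depth_end_m=380.0, vspeed_ms=-0.3, duration_s=600.0,
        pct_duration=50.0, start_utc=pd.Timestamp("2009-02-01T05:30:00"),
        start_lt=5.5, mid_lt=5.6, prev_speed_ms=-1.0, next_speed_ms=0.5,
        candidate=True,
    )
    base.update(overrides)
    return base


def fragment_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([make_fragment(dive_id=f"d{i}", **r)
                         for i, r in enumerate(rows)])


@pytest.fixture(scope="session")
def month_pipeline():
    """One 30-day default deployment pushed through the whole stack."""
    cfg = dd.SimConfig(n_days=30, dives_per_day=40, seed=7)
    records, labels = dd.simulate_deployment(cfg, dd.BuoyancyTrajectory())
    results = dd.abstract_deployment(records)
    profiles = dd.prepare_dives([r.profile for r in results])
    frags = dd.fragment_dives(profiles)
    drift, report = dd.apply_filters(frags)
    return dict(config=cfg, records=records, labels=labels,
                profiles=profiles, fragments=frags, drift=drift,
                report=report)
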