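import numpy as np
import pandas as pd
import pytest

from bloomtrack import PipelineConfig, SimConfig, simulate_microcosm
from bloomtrack.datatypes import make_metadata
from bloomtrack.pipeline import detect_responders


@pytest.fixture(scope="session")
def sim():
    """One simulated microcosm bundle with truth, shared across tests."""
    ds, truth = simulate_microcosm(SimConfig(), seed=1)
    return ds, truth


@pytest.fixture(scope="session")
def sim_responders(sim):
    ds, _ = sim
    return detect_responders(ds, config=PipelineConfig(), seed=1)


def _microcosm_metadata(treatments=("control", "CIF", "HIF"), days=range(8)):
    ids, ts, reps, ds_ = [], [], [], []
    for t in treatments:
        for r in ("I", "II", "III"):
            for d in days:
                ids.append(f"{t}-{r}-d{d}")
                ts.append(t)
                reps.append(r)
                ds_.append(d)
    return make_metadata(ids, ts, reps, ds_)


@pytest.fixture
def microcosm_metadata():
    return _microcosm_metadata()


@pytest.fixture
def toy_riser_table():
    """Hand-built abundance table: 25 features, 1 treatment, 3 flasks, 8 days.

    20 background features sit at distinct constant levels 1000..1950
    (steps of 50).  Features riser0..riser4 start at 100 cells/mL and climb
    to 4000 by day 7 — into the top 20 in every flask and past the 2x
    day-0 rule.  Exactly those five satisfy the abundant-ASV criteria.
    """
    md = _microcosm_metadata(treatments=("CIF",))
    features = [f"bg{i:02d}" for i in range(20)] + [f"riser{i}" for i in range(5)]
    data = {}
    for s in md.index:
        d = int(md.at[s, "day"])
        col = [1000.0 + 50 * i for i in range(20)]
        col += [100.0 + 600.0 * d] * 5  # risers: 100 -> 4300
        data[s] = col
    table = pd.DataFrame(data, index=features)
    return table, md


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
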