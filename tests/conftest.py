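import io

import numpy as np
import pytest

import ambientropy as amb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def daily_real_entropy(preset: str, seed: int) -> np.ndarray:
    """Run a synthetic scenario through the full ingest+entropy path and
    return the chronological daily real-entropy values."""
    events_df, _ = amb.simulate(amb.make_fixture(preset, seed=seed))
    events = amb.read_events(io.StringIO(events_df.to_csv(index=False)))
    kept, _ = amb.filter_days(amb.build_daily_trajectories(events))
    return np.array([amb.entropy_record(t).s_real for t in kept])


@pytest.fixture(scope="session")
def markov_chain_sample():
    """A length-1e5 path of a 3-state chain with known transition matrix."""
    P = np.array([[0.1, 0.8, 0.1], [0.3, 0.1, 0.6], [0.5, 0.4, 0.1]])
    rng = np.random.default_rng(7)
    cum = np.cumsum(P, axis=1)
    n = 100_000
    seq = np.empty(n, dtype=np.int64)
    s = 0
    for i in range(n):
        s = int(np.searchsorted(cum[s], rng.random(), side="right"))
        seq[i] = s
    return P, seq
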