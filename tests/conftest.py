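import numpy as np
import pandas as pd
import pytest

from sealassoc.synthdata import SimConfig, simulate_latent_tracks


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A compact deployment: 4 animals, 4 days, strong bank attraction so
    dyads actually meet."""
    return SimConfig(n_seals=4, duration_days=4.0, bank_attraction=2.0,
                     n_males=2, seed=11)


@pytest.fixture(scope="session")
def small_tracks(small_config):
    return simulate_latent_tracks(small_config)


@pytest.fixture(scope="session")
def small_scenario_dir(tmp_path_factory, small_config):
    from sealassoc.synthdata import make_scenario
    outdir = tmp_path_factory.mktemp("scenario")
    make_scenario(small_config, outdir)
    return outdir


def make_random_events(rng, n, dyads=(("a", "b"), ("b", "c"))) -> pd.DataFrame:
    """Random detection-event stream used by clustering oracle tests."""
    dyad_idx = rng.integers(0, len(dyads), n)
    t = np.sort(rng.uniform(0, 5 * 86400.0, n))
    rows = [(dyads[k][0], dyads[k][1], float(ti), True)
            for k, ti in zip(dyad_idx, t)]
    return pd.DataFrame(rows, columns=["seal_a", "seal_b", "t", "two_way"])


def brute_force_associations(events: pd.DataFrame, gap_min: float = 30.0,
                             singleton_min: float = 3.0) -> list[tuple]:
    """Independent gap-rule splitter: inspects every inter-event gap of
    every dyad one by one.  Returns (seal_a, seal_b, start, end, n_events,
    duration_h) tuples sorted by dyad and start."""
    out = []
    for (a, b) in sorted({(r.seal_a, r.seal_b)
                          for r in events.itertuples(index=False)}):
        times = sorted(events[(events["seal_a"] == a)
                              & (events["seal_b"] == b)]["t"])
        run = [times[0]]
        for prev, cur in zip(times, times[1:]):
            if cur - prev > gap_min * 60.0:
                out.append(_finish(a, b, run, singleton_min))
                run = [cur]
            else:
                run.append(cur)
        out.append(_finish(a, b, run, singleton_min))
    return out


def _finish(a, b, run, singleton_min):
    dur = (run[-1] - run[0]) / 3600.0 if len(run) > 1 else singleton_min / 60.0
    return (a, b, run[0], run[-1], len(run), dur)
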