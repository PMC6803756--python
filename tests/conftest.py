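import numpy as np
import pytest
from hypothesis import settings

from igt_pvl import (
    PVLParameters,
    SessionLog,
    TaskConfig,
    build_standard_decks,
    play_session,
    simulate_agent,
)
from igt_pvl.igt_task import TrialRecord

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def decks():
    return build_standard_decks()


@pytest.fixture(scope="session")
def midrange_params():
    return PVLParameters(alpha=0.5, lam=2.5, recency_A=0.5, consistency_c=1.0)


@pytest.fixture(scope="session")
def sample_session(midrange_params):
    return simulate_agent(midrange_params, seed=42)


def constant_policy(deck_id):
    def chooser(history, available, rng):
        return deck_id

    return chooser


def make_session(choices, nets=None, rts=None, subject_id="fix", balance0=2000):
    """Hand-built session for fixtures (bypasses the payoff engine)."""
    nets = nets if nets is not None else [0] * len(choices)
    rts = rts if rts is not None else [1000.0] * len(choices)
    records = []
    bal = balance0
    for i, (d, n, r) in enumerate(zip(choices, nets, rts), start=1):
        bal += n
        gain = max(n, 0)
        records.append(
            TrialRecord(trial=i, deck=d, gain=gain, loss=gain - n, net=n, balance=bal, rt_ms=r)
        )
    n_tr = len(choices)
    block = n_tr if n_tr else 1
    for b in (20, 10, 5, 2, 1):
        if n_tr % b == 0:
            block = b if n_tr >= b else n_tr
            break
    cfg = TaskConfig(n_trials=n_tr, block_size=block) if n_tr else TaskConfig()
    return SessionLog(subject_id=subject_id, records=records, config=cfg)


def random_session(rng, n_trials=100):
    """Random-policy session on the real payoff engine."""
    seed = int(rng.integers(0, 2**31))

    def chooser(history, available, r):
        return available[int(r.integers(len(available)))]

    return play_session(chooser, TaskConfig(n_trials=n_trials, block_size=n_trials), seed=seed)


def random_params(rng, rule="decay"):
    return PVLParameters(
        alpha=float(rng.uniform(0.05, 0.95)),
        lam=float(rng.uniform(0.1, 4.9)),
        recency_A=float(rng.uniform(0.05, 0.95)),
        consistency_c=float(rng.uniform(0.05, 3.0)),
        rule=rule,
    )
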