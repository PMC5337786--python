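import numpy as np
import pandas as pd
import pytest

from hybridbci.core import CHANNELS, ContinuousRecording, EventTable
from hybridbci.pipelines import extract_trials
from hybridbci.synthetic import SyntheticConfig, generate, generate_split


def make_events(n_trials: int = 1, rate_hz: float = 250.0,
                trial_s: float = 12.0, cue_s: float = 4.0,
                tasks=None, rng=None) -> EventTable:
    """Minimal well-formed event table: one cue + 32 flashes per trial.

    Button order is a fixed rotation unless an rng is given.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    soa = int(0.120 * rate_hz)
    for tid in range(n_trials):
        start = int(tid * trial_s * rate_hz)
        cue = start + int(cue_s * rate_hz)
        task = (tasks[tid] if tasks is not None
                else ("p300" if tid % 2 == 0 else "mi"))
        rows.append(dict(trial_id=tid, kind="cue", onset_sample=cue,
                         task=task, button_id=0, round_index=0))
        k = 0
        for rnd in range(1, 5):
            for b in (rng.permutation(8) + 1):
                rows.append(dict(trial_id=tid, kind="flash",
                                 onset_sample=cue + k * soa, task="",
                                 button_id=int(b), round_index=rnd))
                k += 1
    return EventTable(pd.DataFrame(rows))


def make_recording(n_trials: int = 1, rate_hz: float = 250.0,
                   seed: int = 0, channel_names=None) -> ContinuousRecording:
    """Random-noise recording with a valid event table."""
    rng = np.random.default_rng(seed)
    events = make_events(n_trials, rate_hz=rate_hz, rng=rng)
    names = list(channel_names) if channel_names else list(CHANNELS)
    n_samples = int(n_trials * 12.0 * rate_hz) + int(rate_hz)
    samples = rng.standard_normal((len(names), n_samples))
    return ContinuousRecording(samples, rate_hz, names, events)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_trials_per_class=6, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_trials(small_recording):
    return extract_trials(small_recording)


@pytest.fixture(scope="session")
def small_split(small_config):
    return generate_split(small_config)


@pytest.fixture(scope="session")
def split_trials(small_split):
    train, test = small_split
    return extract_trials(train), extract_trials(test)


@pytest.fixture(scope="session")
def strong_config():
    """High-SNR world: both modalities far above the noise floor."""
    return SyntheticConfig(n_trials_per_class=12, seed=21,
                           erp_amplitude=25.0, erd_depth=0.9,
                           noise_std=6.0)


@pytest.fixture(scope="session")
def strong_split_trials(strong_config):
    train, test = generate_split(strong_config)
    return extract_trials(train), extract_trials(test)
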