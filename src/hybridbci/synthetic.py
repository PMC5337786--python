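"""Seeded generator of paradigm-faithful hybrid EEG.

Each 12 s trial follows the acquisition timeline: blank screen 0-2.25 s,
fixation cross 2.25-4 s, task cue 4-8 s, 4 s inter-trial interval. During
the cue window the 8 buttons flash in 4 rounds of per-round random order at
120 ms stimulus-onset asynchrony (32 flashes, one round = 960 ms).

Class structure (what the decoder must find):

* P300-task trials (+1): a Gaussian-windowed positive ERP deflection with a
  parieto-occipital channel profile is added after each target-button flash
  (first-order, time-locked signal).
* MI-task trials (-1): the ongoing 10 Hz mu rhythm, strongest at C3 (right
  hand imagery, left motor cortex), is attenuated by ``erd_depth`` during
  the cue window (second-order, band-power signal).

Background is per-channel AR(1) noise with Gaussian cross-channel mixing for
a realistic spatial covariance. Flash schedules are drawn identically for
both classes, so event timing never leaks the label.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    CHANNELS,
    ContinuousRecording,
    EventTable,
    N_BUTTONS,
    N_CHANNELS,
    N_ROUNDS,
    ParameterError,
    TARGET_BUTTON,
)

RATE_HZ = 250.0
TRIAL_S = 12.0
CUE_ONSET_S = 4.0
CUE_DURATION_S = 4.0
SOA_S = 0.120

_TRIAL_SAMPLES = int(TRIAL_S * RATE_HZ)          # 3000
_CUE_OFFSET = int(CUE_ONSET_S * RATE_HZ)         # 1000
_CUE_SAMPLES = int(CUE_DURATION_S * RATE_HZ)     # 1000
_SOA_SAMPLES = int(SOA_S * RATE_HZ)              # 30


def _weights(mapping: dict[str, float], default: float = 0.0) -> np.ndarray:
    return np.array([mapping.get(c, default) for c in CHANNELS])


def default_erp_weights() -> np.ndarray:
    """Parieto-occipital ERP scalp profile (unitless, max 1 at Pz)."""
    return _weights({"P3": 0.8, "Pz": 1.0, "P4": 0.8,
                     "CP3": 0.3, "CPz": 0.5, "CP4": 0.3,
                     "O1": 0.6, "Oz": 0.7, "O2": 0.6,
                     "Cz": 0.3}, default=0.1)


def default_mu_weights() -> np.ndarray:
    """C3-dominant mu-rhythm profile (right-hand imagery, left cortex)."""
    return _weights({"C3": 1.0, "FC3": 0.5, "CP3": 0.5,
                     "Cz": 0.2, "C4": 0.1}, default=0.05)


@dataclass
class SyntheticConfig:
    """Stated world of the simulated session.

    Amplitudes are in microvolts. Defaults reproduce one acquisition session
    (50 trials per task) at moderate signal-to-noise — an 8 uV ERP against
    ~10 uV broadband noise and 40% mu suppression of a 6 uV rhythm — chosen
    so that each modality alone decodes at roughly the 80% level reported
    for single-modality decoding on the real recordings.
    """

    n_trials_per_class: int = 50
    erp_amplitude: float = 8.0
    erp_latency_ms: float = 300.0
    erp_width_ms: float = 100.0
    erp_channel_weights: np.ndarray = field(default_factory=default_erp_weights)
    mu_freq_hz: float = 10.0
    mu_amplitude: float = 6.0
    erd_depth: float = 0.4
    mu_channel_weights: np.ndarray = field(default_factory=default_mu_weights)
    ar_coeff: float = 0.95
    noise_std: float = 10.0
    mixing_width: float = 1.0
    seed: int = 0

    @property
    def rate_hz(self) -> float:
        return RATE_HZ

    def validate(self) -> None:
        if self.n_trials_per_class < 1:
            raise ParameterError("n_trials_per_class must be >= 1")
        if self.erp_amplitude < 0 or self.mu_amplitude < 0:
            raise ParameterError("amplitudes must be nonnegative")
        if not (0.0 <= self.erd_depth <= 1.0):
            raise ParameterError("erd_depth must lie in [0, 1]")
        if not (0.0 <= self.ar_coeff < 1.0):
            raise ParameterError("ar_coeff must lie in [0, 1)")
        if self.noise_std <= 0:
            raise ParameterError("noise_std must be positive")
        for name, w in (("erp_channel_weights", self.erp_channel_weights),
                        ("mu_channel_weights", self.mu_channel_weights)):
            if np.asarray(w).shape != (N_CHANNELS,):
                raise ParameterError(f"{name} must be a 15-vector")


# Rough 2-D electrode grid (row, col) for the spatial mixing kernel.
_GRID = {name: (r, c)
         for r, row in enumerate((("FC3", "FCz", "FC4"),
                                  ("C3", "Cz", "C4"),
                                  ("CP3", "CPz", "CP4"),
                                  ("P3", "Pz", "P4"),
                                  ("O1", "Oz", "O2")))
         for c, name in enumerate(row)}


def _mixing_matrix(width: float) -> np.ndarray:
    """Row-normalized Gaussian kernel over the electrode grid."""
    pos = np.array([_GRID[c] for c in CHANNELS], dtype=float)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)
    M = np.exp(-d2 / (2.0 * width**2))
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def _erp_template(config: SyntheticConfig) -> np.ndarray:
    """Gaussian deflection over 0-600 ms at the acquisition rate."""
    t_ms = np.arange(int(0.6 * RATE_HZ)) * (1000.0 / RATE_HZ)
    sd = config.erp_width_ms / 2.0
    return config.erp_amplitude * np.exp(-0.5 * ((t_ms - config.erp_latency_ms) / sd) ** 2)


def generate(config: SyntheticConfig,
             seed: int | None = None) -> ContinuousRecording:
    """Simulate one session: continuous 15-channel EEG plus its event table.

    Deterministic given (config, seed); ``seed=None`` uses ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_trials = 2 * config.n_trials_per_class
    n_samples = n_trials * _TRIAL_SAMPLES + int(RATE_HZ)

    # -- background: AR(1) per channel, then spatial mixing -----------------
    a = config.ar_coeff
    innov_sd = config.noise_std * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal((N_CHANNELS, n_samples)) * innov_sd
    noise = sps.lfilter([1.0], [1.0, -a], noise, axis=1)
    samples = _mixing_matrix(config.mixing_width) @ noise

    # -- labels: 50/50, order shuffled (timing identical across classes) ----
    labels = np.array([+1] * config.n_trials_per_class
                      + [-1] * config.n_trials_per_class)
    rng.shuffle(labels)

    # -- mu rhythm with ERD in MI-trial cue windows -------------------------
    t = np.arange(n_samples) / RATE_HZ
    slow = sps.lfilter([1.0], [1.0, -0.999], rng.standard_normal(n_samples))
    slow /= max(slow.std(), 1e-12)
    envelope = np.clip(1.0 + 0.3 * slow, 0.2, None)
    for i, lab in enumerate(labels):
        if lab == -1:
            s = i * _TRIAL_SAMPLES + _CUE_OFFSET
            envelope[s:s + _CUE_SAMPLES] *= (1.0 - config.erd_depth)
    phase = rng.uniform(0, 2 * np.pi)
    mu = config.mu_amplitude * envelope * np.sin(2 * np.pi * config.mu_freq_hz * t + phase)
    samples += np.asarray(config.mu_channel_weights)[:, None] * mu[None, :]

    # -- events and the flash-locked ERP ------------------------------------
    template = _erp_template(config)
    w_erp = np.asarray(config.erp_channel_weights)
    rows = []
    for i, lab in enumerate(labels):
        start = i * _TRIAL_SAMPLES
        cue = start + _CUE_OFFSET
        rows.append({"trial_id": i, "kind": "cue", "onset_sample": cue,
                     "task": "p300" if lab == 1 else "mi",
                     "button_id": 0, "round_index": 0})
        k = 0
        for rnd in range(1, N_ROUNDS + 1):
            order = rng.permutation(N_BUTTONS) + 1
            for button in order:
                onset = cue + k * _SOA_SAMPLES
                rows.append({"trial_id": i, "kind": "flash",
                             "onset_sample": int(onset), "task": "",
                             "button_id": int(button), "round_index": rnd})
                if lab == 1 and button == TARGET_BUTTON:
                    samples[:, onset:onset + len(template)] += \
                        w_erp[:, None] * template[None, :]
                k += 1
    events = EventTable(pd.DataFrame(rows))
    rec = ContinuousRecording(samples, RATE_HZ, list(CHANNELS), events)
    rec.validate()
    return rec


def generate_split(config: SyntheticConfig
                   ) -> tuple[ContinuousRecording, ContinuousRecording]:
    """Two independent sessions (training, test) from one master seed."""
    children = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
    train = generate(config, seed=int(children[0]))
    test = generate(config, seed=int(children[1]))
    return train, test
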