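"""Band-pass filtering, resampling, and segmentation of continuous EEG.

The ERP stream is filtered 0.1-20 Hz and resampled to 60 Hz; each target
flash yields a 37x15 epoch covering 0-600 ms (37 = 0.6 s * 60 Hz + 1, both
window endpoints on the grid). The motor-imagery stream is filtered 8-30 Hz
and resampled to 100 Hz; each trial yields a 15x400 segment covering the 4 s
cue window.

Filtering and resampling act on the continuous recording before any
segmentation, so filter edge transients never fall inside an epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .core import (
    BoundaryError,
    ContinuousRecording,
    DataError,
    EventTable,
    N_CHANNELS,
    ParameterError,
    TARGET_BUTTON,
)

# Stream conventions
P300_BAND = (0.1, 20.0)
P300_RATE = 60.0
P300_EPOCH_SAMPLES = 37          # 0-600 ms inclusive at 60 Hz
MI_BAND = (8.0, 30.0)
MI_RATE = 100.0
MI_SEGMENT_SAMPLES = 400         # 4 s cue window at 100 Hz
FILTER_ORDER = 4


@dataclass
class FlashEpoch:
    """One target-flash ERP epoch: 37 time samples x 15 channels."""

    data: np.ndarray
    trial_id: int
    repeat_index: int  # 1..4

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (P300_EPOCH_SAMPLES, N_CHANNELS):
            raise ValueError(f"flash epoch must be "
                             f"{P300_EPOCH_SAMPLES}x{N_CHANNELS}")


@dataclass
class MISegment:
    """One motor-imagery trial segment: 15 channels x 400 time samples."""

    data: np.ndarray
    trial_id: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (N_CHANNELS, MI_SEGMENT_SAMPLES):
            raise ValueError(f"MI segment must be "
                             f"{N_CHANNELS}x{MI_SEGMENT_SAMPLES}")


def bandpass(recording: ContinuousRecording, low_hz: float,
             high_hz: float) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    A 4th-order filter is run forward and backward (``sosfiltfilt``), which
    doubles the effective order and cancels phase distortion so ERP
    latencies are preserved.
    """
    nyq = recording.rate_hz / 2.0
    if not (0 <= low_hz < high_hz):
        raise ParameterError("need 0 <= low < high")
    if high_hz >= nyq:
        raise ParameterError(f"high edge {high_hz} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(FILTER_ORDER, (low_hz, high_hz), btype="bandpass",
                        fs=recording.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return ContinuousRecording(filtered, recording.rate_hz,
                               list(recording.channel_names), recording.events)


def resample(recording: ContinuousRecording,
             target_hz: float) -> ContinuousRecording:
    """Rational polyphase resampling with anti-aliasing.

    Event onsets are rescaled by target/source with round-to-nearest.
    """
    if target_hz >= recording.rate_hz:
        raise ParameterError("target rate must be below the current rate")
    frac = Fraction(target_hz / recording.rate_hz).limit_denominator(1000)
    if abs(float(frac) - target_hz / recording.rate_hz) > 1e-9:
        raise ParameterError(
            f"rate ratio {target_hz}/{recording.rate_hz} is not rational "
            "within tolerance")
    out = signal.resample_poly(recording.samples, frac.numerator,
                               frac.denominator, axis=1)
    events = recording.events.scaled(float(frac))
    return ContinuousRecording(out, target_hz,
                               list(recording.channel_names), events)


def extract_flash_epochs(recording: ContinuousRecording,
                         target_button: int = TARGET_BUTTON
                         ) -> list[FlashEpoch]:
    """Cut one 37x15 epoch per target-button flash (4 per trial).

    Expects a recording already filtered 0.1-20 Hz and resampled to 60 Hz,
    with channels in canonical order. Rows are time (window start at the
    flash onset, half-open [onset, onset+37)), columns are channels.
    """
    if abs(recording.rate_hz - P300_RATE) > 1e-9:
        raise ParameterError(f"expected a {P300_RATE:g} Hz recording")
    flashes = recording.events.flashes
    targets = flashes[flashes["button_id"] == target_button]
    epochs: list[FlashEpoch] = []
    for tid, grp in targets.groupby("trial_id", sort=True):
        grp = grp.sort_values("onset_sample")
        for repeat, (_, row) in enumerate(grp.iterrows(), start=1):
            s = int(row["onset_sample"])
            e = s + P300_EPOCH_SAMPLES
            if e > recording.n_samples:
                raise BoundaryError(
                    f"trial {tid}: epoch [{s},{e}) exceeds recording end "
                    f"{recording.n_samples}")
            epochs.append(FlashEpoch(recording.samples[:, s:e].T,
                                     trial_id=int(tid), repeat_index=repeat))
    return epochs


def extract_mi_segments(recording: ContinuousRecording) -> list[MISegment]:
    """Cut one 15x400 segment per trial covering cue onset + 4 s.

    Expects a recording filtered 8-30 Hz and resampled to 100 Hz. Trials
    whose cue windows overlap are rejected.
    """
    if abs(recording.rate_hz - MI_RATE) > 1e-9:
        raise ParameterError(f"expected a {MI_RATE:g} Hz recording")
    cues = recording.events.cues.sort_values("onset_sample")
    if len(cues) == 0:
        raise DataError("no cue events")
    onsets = cues["onset_sample"].to_numpy()
    tids = cues["trial_id"].to_numpy()
    segments: list[MISegment] = []
    for i, (tid, s) in enumerate(zip(tids, onsets)):
        e = int(s) + MI_SEGMENT_SAMPLES
        if e > recording.n_samples:
            raise BoundaryError(
                f"trial {tid}: segment [{s},{e}) exceeds recording end "
                f"{recording.n_samples}")
        if i + 1 < len(onsets) and e > onsets[i + 1]:
            raise BoundaryError(
                f"trial {tid}: cue window overlaps trial {tids[i + 1]}")
        segments.append(MISegment(recording.samples[:, int(s):e],
                                  trial_id=int(tid)))
    return segments


def prepare_p300_stream(recording: ContinuousRecording) -> ContinuousRecording:
    """0.1-20 Hz zero-phase band-pass, then resample to 60 Hz."""
    return resample(bandpass(recording, *P300_BAND), P300_RATE)


def prepare_mi_stream(recording: ContinuousRecording) -> ContinuousRecording:
    """8-30 Hz zero-phase band-pass, then resample to 100 Hz."""
    return resample(bandpass(recording, *MI_BAND), MI_RATE)
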