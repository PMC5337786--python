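"""Second-order motor-imagery feature: spatially whitened trial covariance.

Each 15x400 band-passed (8-30 Hz) trial segment is summarized by its channel
covariance, then normalized by the congruence

    Gamma = Wmi @ cov(X) @ Wmi,   Wmi = Sigma_s^(-1/2),

with Sigma_s the mean trial covariance over the training set. By
construction the mean whitened covariance over the training trials is the
identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DataError, N_CHANNELS, ShapeError
from .p300 import sym_power
from .preprocessing import MISegment


@dataclass
class MICovariance:
    """Spatially whitened 15x15 trial covariance."""

    gamma: np.ndarray
    trial_id: int
    label: int

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (N_CHANNELS, N_CHANNELS):
            raise ShapeError("MI covariance must be 15x15")
        scale = max(float(np.abs(self.gamma).max()), 1.0)
        if np.abs(self.gamma - self.gamma.T).max() > 1e-10 * scale:
            raise ShapeError("MI covariance not symmetric")


def trial_covariance(segment: MISegment | np.ndarray) -> np.ndarray:
    """Channel covariance of one segment (time as observations, ddof=1).

    A constant channel simply yields a zero row/column; no error.
    """
    X = segment.data if isinstance(segment, MISegment) else np.asarray(segment, dtype=float)
    if X.ndim != 2 or X.shape[0] != N_CHANNELS:
        raise ShapeError(f"segment must be {N_CHANNELS}xT")
    C = np.cov(X, rowvar=True)
    return 0.5 * (C + C.T)


def fit_mi_whitener(segments: Sequence[MISegment] | Sequence[np.ndarray]
                    ) -> np.ndarray:
    """Wmi = (mean trial covariance)^(-1/2) from training segments."""
    if len(segments) < 2:
        raise DataError("need at least 2 training segments")
    sigma_s = np.mean([trial_covariance(s) for s in segments], axis=0)
    return sym_power(sigma_s, -0.5)


def whiten_mi(cov: np.ndarray, Wmi: np.ndarray, trial_id: int = -1,
              label: int = 0) -> MICovariance:
    """Congruence transform Gamma = Wmi @ cov @ Wmi (symmetry re-enforced)."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != Wmi.shape:
        raise ShapeError(f"shape mismatch: cov {cov.shape}, Wmi {Wmi.shape}")
    G = Wmi @ cov @ Wmi
    return MICovariance(0.5 * (G + G.T), trial_id=trial_id, label=label)
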