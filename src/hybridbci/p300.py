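"""First-order ERP feature: trial-average epoch with spatio-temporal whitening.

The four target-flash epochs of a trial are averaged element-wise into a raw
37x15 matrix X. Channels and time points are then normalized to comparable
scale by the two-sided transform

    Xbar = Pt @ X @ Ps,   Ps = Sigma_s^(-1/4),   Pt = Sigma_t^(-1/4),

where Sigma_s (15x15) and Sigma_t (37x37) are the spatial and temporal
covariance matrices averaged over the training trials. The -1/4 powers make
the product whiten both domains jointly. Whiteners are estimated from
training trials only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DataError, N_CHANNELS, ShapeError
from .preprocessing import FlashEpoch, P300_EPOCH_SAMPLES

#: Relative eigenvalue floor applied before negative fractional powers.
EIG_FLOOR = 1e-10


@dataclass
class P300Feature:
    """Whitened trial-average ERP matrix (37 time x 15 channels)."""

    xbar: np.ndarray
    trial_id: int
    label: int

    def __post_init__(self) -> None:
        self.xbar = np.asarray(self.xbar, dtype=float)
        if self.xbar.shape != (P300_EPOCH_SAMPLES, N_CHANNELS):
            raise ShapeError("P300 feature must be 37x15")
        if not np.all(np.isfinite(self.xbar)):
            raise ValueError("non-finite entries in P300 feature")


def average_epochs(epochs: Sequence[FlashEpoch] | Sequence[np.ndarray],
                   require: int = 4) -> np.ndarray:
    """Element-wise mean of a trial's flash epochs.

    ``require`` is 4 for the standard pipeline; per-repetition evaluation
    passes fewer (require=None disables the count check).
    """
    arrays = [e.data if isinstance(e, FlashEpoch) else np.asarray(e, dtype=float)
              for e in epochs]
    if require is not None and len(arrays) != require:
        raise DataError(f"expected {require} epochs, got {len(arrays)}")
    if not arrays:
        raise DataError("no epochs to average")
    tids = {e.trial_id for e in epochs if isinstance(e, FlashEpoch)}
    if len(tids) > 1:
        raise DataError(f"epochs from multiple trials {sorted(tids)}")
    return np.mean(arrays, axis=0)


def sym_power(A: np.ndarray, p: float, sym_tol: float = 1e-8,
              eig_floor: float = EIG_FLOOR) -> np.ndarray:
    """Fractional power of a symmetric PSD matrix via eigendecomposition.

    Eigenvalues below ``eig_floor * lambda_max`` are clamped to that floor
    before negative powers (rank-deficient covariances from few trials);
    for nonnegative powers they are clamped to zero.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ShapeError("sym_power needs a square matrix")
    scale = max(float(np.abs(A).max()), 1.0)
    if np.abs(A - A.T).max() > sym_tol * scale:
        raise ShapeError("matrix not symmetric within tolerance")
    w, V = np.linalg.eigh(0.5 * (A + A.T))
    lam_max = float(w[-1])
    if p < 0:
        if lam_max <= 0:
            raise DataError("matrix has no positive eigenvalues; "
                            "negative power undefined")
        w = np.maximum(w, eig_floor * lam_max)
    else:
        w = np.maximum(w, 0.0)
    out = (V * w**p) @ V.T
    return 0.5 * (out + out.T)


def fit_p300_whiteners(raw_trials: Sequence[np.ndarray]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Fit (Pt, Ps) = (Sigma_t^-1/4, Sigma_s^-1/4) from training trials.

    Sigma_s is the mean over trials of the 15x15 covariance with time points
    as observations; Sigma_t the mean 37x37 covariance with channels as
    observations (mean-subtracted, divisor n_obs - 1).
    """
    mats = [np.asarray(X, dtype=float) for X in raw_trials]
    if len(mats) < 2:
        raise DataError("need at least 2 training trials to fit whiteners")
    for X in mats:
        if X.shape != (P300_EPOCH_SAMPLES, N_CHANNELS):
            raise ShapeError("raw trial matrices must be 37x15")
    sigma_s = np.mean([np.cov(X, rowvar=False) for X in mats], axis=0)
    sigma_t = np.mean([np.cov(X, rowvar=True) for X in mats], axis=0)
    Ps = sym_power(sigma_s, -0.25)
    Pt = sym_power(sigma_t, -0.25)
    return Pt, Ps


def whiten_p300(raw: np.ndarray, Pt: np.ndarray, Ps: np.ndarray,
                trial_id: int = -1, label: int = 0) -> P300Feature:
    """Apply the two-sided normalization Xbar = Pt @ raw @ Ps."""
    raw = np.asarray(raw, dtype=float)
    if raw.shape != (Pt.shape[1], Ps.shape[0]):
        raise ShapeError(
            f"shape mismatch: raw {raw.shape}, Pt {Pt.shape}, Ps {Ps.shape}")
    return P300Feature(Pt @ raw @ Ps, trial_id=trial_id, label=label)
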