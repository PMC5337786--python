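"""Block-diagonal fusion of the ERP and MI features.

The two modality features are concatenated on the diagonal of one 52x30
matrix

    X_hybrid = [[ Xbar/xi1 ,    0     ],
                [    0     , Gamma/xi2 ]]

so that a single linear matrix classifier can weight, select, and combine
both modalities jointly. The scale factors xi1, xi2 standardize each block
to unit total variance: xi_k is the square root of the sum over the block's
entries of that entry's across-trial variance, estimated on training trials
only (``mean_variance`` mode divides by the entry count instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DataError, ShapeError
from .mi import MICovariance
from .p300 import P300Feature

HYBRID_SHAPE = (52, 30)
BLOCK_DIMS = ((37, 15), (15, 15))


@dataclass
class BlockScales:
    """Per-block standardization factors, fitted on training trials."""

    xi1: float
    xi2: float

    def __post_init__(self) -> None:
        for name, v in (("xi1", self.xi1), ("xi2", self.xi2)):
            if not np.isfinite(v) or v <= 0:
                raise DataError(f"{name} must be finite and positive, got {v}")


@dataclass
class HybridFeature:
    """52x30 block-diagonal trial feature; off-diagonal blocks exactly zero."""

    x: np.ndarray
    trial_id: int
    label: int

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.shape != HYBRID_SHAPE:
            raise ShapeError(f"hybrid feature must be {HYBRID_SHAPE}")
        if np.any(self.x[:37, 15:] != 0) or np.any(self.x[37:, :15] != 0):
            raise ShapeError("off-diagonal blocks must be exactly zero")


def _total_variance(stack: np.ndarray, mode: str) -> float:
    # stack: (n_trials, rows, cols); across-trial per-entry variance, ddof=1
    var = stack.var(axis=0, ddof=1)
    total = float(var.sum())
    # variance of numerically identical trials cancels to ~eps^2 residue
    scale = float((stack ** 2).mean())
    if total <= 1e-20 * max(scale, 1e-300):
        total = 0.0
    if mode == "mean_variance":
        total /= var.size
    elif mode != "sum_variance":
        raise ValueError(f"unknown scale mode {mode!r}")
    return total


def fit_block_scales(p300_feats: Sequence[P300Feature],
                     mi_feats: Sequence[MICovariance],
                     mode: str = "sum_variance") -> BlockScales:
    """Estimate xi1 (ERP block) and xi2 (MI block) on the training set."""
    if not p300_feats or not mi_feats:
        raise DataError("need nonempty training feature lists")
    ids1 = [f.trial_id for f in p300_feats]
    ids2 = [f.trial_id for f in mi_feats]
    if sorted(ids1) != sorted(ids2):
        raise DataError("P300 and MI feature trial ids do not match")
    v1 = _total_variance(np.stack([f.xbar for f in p300_feats]), mode)
    v2 = _total_variance(np.stack([f.gamma for f in mi_feats]), mode)
    if v1 <= 0 or v2 <= 0:
        raise DataError("zero total variance in a feature block; "
                        "cannot standardize degenerate data")
    return BlockScales(xi1=float(np.sqrt(v1)), xi2=float(np.sqrt(v2)))


def fuse(p300: P300Feature, mi: MICovariance,
         scales: BlockScales) -> HybridFeature:
    """Assemble the 52x30 block-diagonal hybrid feature of one trial."""
    if p300.xbar.shape != BLOCK_DIMS[0] or mi.gamma.shape != BLOCK_DIMS[1]:
        raise ShapeError("block shapes must be 37x15 and 15x15")
    if p300.trial_id != mi.trial_id:
        raise DataError(f"trial id mismatch: {p300.trial_id} vs {mi.trial_id}")
    x = np.zeros(HYBRID_SHAPE)
    x[:37, :15] = p300.xbar / scales.xi1
    x[37:, 15:] = mi.gamma / scales.xi2
    return HybridFeature(x, trial_id=p300.trial_id, label=p300.label)
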