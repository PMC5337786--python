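"""Linear matrix classifier under a nuclear-norm (dual spectral) constraint.

The decision function is f(X) = <W, X> + b with <.,.> the Frobenius inner
product. Training minimizes the average logistic loss

    (1/N) sum_i log(1 + exp(-y_i f(X_i)))   s.t.   ||W||_* <= C

by projected gradient descent with Armijo backtracking. ||W||_* is the sum
of singular values; its ball constraint drives W toward low rank, i.e. a few
spatial/temporal filter pairs per block.

Because every input feature has exactly-zero off-diagonal blocks, the loss
only reads the diagonal blocks of W, and by the pinching inequality
(||diag-blocks(W)||_* <= ||W||_*) there is always an optimal W that is
block-diagonal. W is therefore parameterized per block; the nuclear norm of
the assembled matrix is the sum over blocks, and the projection acts on the
concatenated singular values of all blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import DataError, DSModel, ParameterError, ShapeError, WhiteningSet

logger = logging.getLogger("hybridbci.classifier")


@dataclass
class SolverSettings:
    """Projected-gradient solver controls.

    ``seed`` is reserved (the solver is deterministic from W = 0, b = 0).
    """

    max_iter: int = 2000
    tol_obj: float = 1e-7
    tol_feas: float = 1e-6
    step_rule: str = "backtracking"
    armijo_c: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iter < 1:
            raise ParameterError("max_iter must be >= 1")
        for name in ("tol_obj", "tol_feas"):
            v = getattr(self, name)
            if not (0 < v <= 1e-2):
                raise ParameterError(f"{name} must lie in (0, 1e-2]")
        if self.step_rule != "backtracking":
            raise ParameterError("only the backtracking step rule is supported")


@dataclass
class SpectrumReport:
    """Singular structure of a fitted W, per diagonal block."""

    singular_values: np.ndarray          # all blocks, nonincreasing
    rank: int                            # count above 1e-8 * max
    block_singular_values: list[np.ndarray]
    block_left_vectors: list[np.ndarray]   # temporal filters (columns)
    block_right_vectors: list[np.ndarray]  # spatial filters (columns)

    @property
    def nuclear_norm(self) -> float:
        return float(self.singular_values.sum())


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _as_blocks(x, block_dims) -> list[np.ndarray]:
    """Split a feature (HybridFeature, full matrix, or block list) into blocks."""
    if hasattr(x, "x"):
        x = x.x
    if isinstance(x, (list, tuple)):
        return [np.asarray(B, dtype=float) for B in x]
    x = np.asarray(x, dtype=float)
    if len(block_dims) == 1:
        if x.shape != tuple(block_dims[0]):
            raise ShapeError(f"feature shape {x.shape} != {block_dims[0]}")
        return [x]
    rows = sum(d[0] for d in block_dims)
    cols = sum(d[1] for d in block_dims)
    if x.shape != (rows, cols):
        raise ShapeError(f"feature shape {x.shape} != {(rows, cols)}")
    out, r, c = [], 0, 0
    for dr, dc in block_dims:
        out.append(x[r:r + dr, c:c + dc])
        r, c = r + dr, c + dc
    return out


def decision_value(model: DSModel, x) -> float:
    """f(X) = sum_jk W(j,k) X(j,k) + b."""
    blocks = _as_blocks(x, model.block_dims)
    return float(sum(np.vdot(Wb, Xb) for Wb, Xb in zip(model.blocks, blocks))
                 + model.b)


def predict(model: DSModel, x) -> int:
    """Sign rule: +1 when f >= 0, -1 when f < 0 (ties map to +1)."""
    return 1 if decision_value(model, x) >= 0 else -1


def logistic_objective(model: DSModel, features: Sequence, labels) -> float:
    """Average logistic loss, evaluated in overflow-safe softplus form."""
    y = np.asarray(labels, dtype=float)
    f = np.array([decision_value(model, x) for x in features])
    return float(np.mean(np.logaddexp(0.0, -y * f)))


# ---------------------------------------------------------------------------
# Nuclear-ball projection
# ---------------------------------------------------------------------------

def _project_simplex_l1(s: np.ndarray, C: float) -> np.ndarray:
    """Euclidean projection of a nonnegative vector onto {x >= 0, sum x <= C}.

    Sort-and-threshold: if sum(s) <= C the point is feasible; otherwise the
    projection is max(s - tau, 0) with tau from the largest k keeping the
    thresholded values positive.
    """
    if s.sum() <= C:
        return s.copy()
    u = np.sort(s)[::-1]
    css = np.cumsum(u) - C
    ks = np.arange(1, len(u) + 1)
    valid = u - css / ks > 0
    k = int(np.nonzero(valid)[0].max()) + 1
    tau = css[k - 1] / k
    return np.maximum(s - tau, 0.0)


def project_nuclear_ball(W: np.ndarray, C: float) -> np.ndarray:
    """Frobenius projection of a matrix onto the nuclear-norm ball of radius C.

    SVD, project the singular values onto the l1 ball (they are nonnegative,
    so onto the simplex-bounded set), reassemble.
    """
    if C <= 0:
        raise ParameterError("C must be positive")
    W = np.asarray(W, dtype=float)
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    if s.sum() <= C:
        return W.copy()
    return (U * _project_simplex_l1(s, C)) @ Vt


def _project_blocks(blocks: list[np.ndarray], C: float) -> list[np.ndarray]:
    """Joint projection of a block-diagonal matrix onto the nuclear ball.

    The singular values of a block-diagonal matrix are the union of the
    blocks' singular values, so all blocks are projected through one shared
    l1 projection of the concatenated spectra.
    """
    svds = [np.linalg.svd(B, full_matrices=False) for B in blocks]
    s_all = np.concatenate([s for _, s, _ in svds])
    if s_all.sum() <= C:
        return [B.copy() for B in blocks]
    s_proj = _project_simplex_l1(s_all, C)
    out, k = [], 0
    for (U, s, Vt) in svds:
        sp = s_proj[k:k + len(s)]
        k += len(s)
        out.append((U * sp) @ Vt)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _stack_features(features: Sequence, block_dims) -> list[np.ndarray]:
    """Stack per-trial block matrices into per-block (N, r, c) arrays."""
    per_trial = [_as_blocks(x, block_dims) for x in features]
    return [np.stack([t[k] for t in per_trial])
            for k in range(len(block_dims))]


def train(features: Sequence, labels, C: float,
          settings: SolverSettings | None = None,
          block_dims: tuple[tuple[int, int], ...] | None = None,
          xi1: float | None = None, xi2: float | None = None,
          whiteners: WhiteningSet | None = None) -> DSModel:
    """Fit (W, b) by projected gradient descent on the constrained problem.

    The smooth logistic loss is descended jointly in (W, b); only W is
    projected (b is unconstrained and unregularized). Backtracking halves the
    step until the Armijo condition along the projection arc holds, which
    makes the recorded objective trace monotonically nonincreasing. Stops on
    relative objective decrease below ``tol_obj`` or at ``max_iter`` (the
    latter sets ``converged=False`` on the returned model; no exception).
    """
    settings = settings or SolverSettings()
    y = np.asarray(labels, dtype=float)
    if not (np.any(y > 0) and np.any(y < 0)):
        raise DataError("training set must contain both classes")
    if C <= 0:
        raise ParameterError("C must be positive")

    if block_dims is None:
        if hasattr(features[0], "x"):       # HybridFeature
            block_dims = ((37, 15), (15, 15))
        else:
            block_dims = (np.asarray(features[0]).shape,)
    block_dims = tuple(tuple(d) for d in block_dims)
    Xs = _stack_features(features, block_dims)
    N = len(y)

    blocks = [np.zeros(d) for d in block_dims]
    b = 0.0

    def f_values(blks, bb):
        f = np.full(N, bb)
        for Xk, Wk in zip(Xs, blks):
            f += np.einsum("nij,ij->n", Xk, Wk)
        return f

    def objective(blks, bb):
        return float(np.mean(np.logaddexp(0.0, -y * f_values(blks, bb))))

    def gradient(blks, bb):
        f = f_values(blks, bb)
        # d/df of mean softplus(-y f) = -y * sigmoid(-y f) / N
        coeff = -y * _sigmoid(-y * f) / N
        gW = [np.einsum("n,nij->ij", coeff, Xk) for Xk in Xs]
        gb = float(coeff.sum())
        return gW, gb

    obj = objective(blocks, b)
    trace = [obj]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, settings.max_iter + 1):
        gW, gb = gradient(blocks, b)
        accepted = False
        for _ in range(60):
            cand = [Wk - step * gk for Wk, gk in zip(blocks, gW)]
            cand = _project_blocks(cand, C)
            b_new = b - step * gb
            inner = sum(np.vdot(gk, ck - Wk)
                        for gk, ck, Wk in zip(gW, cand, blocks))
            inner += gb * (b_new - b)
            new_obj = objective(cand, b_new)
            if new_obj <= obj + settings.armijo_c * inner and new_obj <= obj:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True  # step collapsed: stationary to machine precision
            break
        rel_dec = (obj - new_obj) / max(abs(obj), 1e-12)
        blocks, b, obj = cand, b_new, new_obj
        trace.append(obj)
        step *= 1.5  # allow recovery after aggressive backtracking
        if rel_dec < settings.tol_obj:
            converged = True
            break
    if not converged:
        logger.warning("trainer hit max_iter=%d without meeting tol_obj",
                       settings.max_iter)

    model = DSModel(blocks=blocks, b=float(b), C=float(C),
                    block_dims=block_dims, xi1=xi1, xi2=xi2,
                    whiteners=whiteners or WhiteningSet(),
                    tol_feas=settings.tol_feas,
                    converged=converged, n_iter=it,
                    objective_trace=trace)
    model.validate()
    return model


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Weight-structure inspection
# ---------------------------------------------------------------------------

RANK_TOL = 1e-8


def spectrum(model: DSModel) -> SpectrumReport:
    """Per-block SVD of W: singular values and filter pairs.

    For the 37x15 ERP block the right singular vectors are spatial filters
    (channel weights) and the left singular vectors temporal filters; the
    symmetric 15x15 MI block yields spatial filters on both sides.
    """
    svds = [np.linalg.svd(B, full_matrices=False) for B in model.blocks]
    s_all = np.sort(np.concatenate([s for _, s, _ in svds]))[::-1]
    smax = s_all[0] if len(s_all) else 0.0
    rank = int((s_all > RANK_TOL * smax).sum()) if smax > 0 else 0
    return SpectrumReport(
        singular_values=s_all,
        rank=rank,
        block_singular_values=[s for _, s, _ in svds],
        block_left_vectors=[U for U, _, _ in svds],
        block_right_vectors=[Vt.T for _, _, Vt in svds],
    )


def topography(model: DSModel) -> dict[str, np.ndarray]:
    """First-filter channel loadings per block, normalized to [-1, 1].

    Returns {"p300": 15-vector, "mi": 15-vector} for hybrid models, or a
    single-key dict for single-modality models. A zero block yields a zero
    vector (normalization skipped).
    """
    rep = spectrum(model)
    out: dict[str, np.ndarray] = {}
    names = (["p300", "mi"] if len(model.blocks) == 2
             else ["p300" if model.block_dims[0][0] == 37 else "mi"])
    for name, s, V in zip(names, rep.block_singular_values,
                          rep.block_right_vectors):
        if len(s) == 0 or s[0] <= RANK_TOL * max(rep.singular_values[0], 1e-300):
            out[name] = np.zeros(V.shape[0])
            continue
        v = V[:, 0].copy()
        m = np.abs(v).max()
        out[name] = v / m if m > 0 else v
    return out
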