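"""Independent oracles for the convex pieces of the classifier.

These deliberately avoid the implementation's algorithms: the simplex/l1
projection is solved by exhaustive KKT active-set enumeration (exact for
small spectra) cross-checked by a dual root-finding solve; the constrained
logistic training problem is solved by Frank-Wolfe (conditional gradient),
a different first-order method whose duality gap certifies how far the
oracle itself is from the true optimum.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# Nuclear-ball projection oracle
# ---------------------------------------------------------------------------

def project_l1_enum(s: np.ndarray, C: float) -> np.ndarray:
    """Projection of nonnegative s onto {x >= 0, sum x <= C} by exhaustive
    KKT active-set enumeration (exact for small dimensions).

    For each candidate support A the stationarity condition gives
    tau = (sum_A s - C)/|A| and x = max(s - tau, 0); the unique KKT point is
    the candidate satisfying primal/dual feasibility and complementarity.
    """
    s = np.asarray(s, dtype=float)
    n = len(s)
    if s.sum() <= C:
        return s.copy()
    assert n <= 20, "enumeration oracle is for small problems"
    best = None
    for mask in range(1, 2 ** n):
        A = np.array([(mask >> i) & 1 for i in range(n)], dtype=bool)
        tau = (s[A].sum() - C) / A.sum()
        if tau < -1e-12:
            continue
        x = np.where(A, s - tau, 0.0)
        if np.any(x[A] < -1e-12):          # support must stay nonnegative
            continue
        if np.any(s[~A] - tau > 1e-12):    # inactive coords need s_i <= tau
            continue
        val = ((x - s) ** 2).sum()
        if best is None or val < best[0] - 1e-15:
            best = (val, np.maximum(x, 0.0))
    assert best is not None, "no KKT point found"
    return best[1]


def project_l1_dual(s: np.ndarray, C: float) -> np.ndarray:
    """Same projection via root-finding on the dual threshold tau."""
    s = np.asarray(s, dtype=float)
    if s.sum() <= C:
        return s.copy()
    g = lambda tau: np.maximum(s - tau, 0.0).sum() - C
    tau = optimize.brentq(g, 0.0, float(s.max()), xtol=1e-14, rtol=1e-15)
    return np.maximum(s - tau, 0.0)


def project_nuclear_oracle(A: np.ndarray, C: float) -> np.ndarray:
    """Frobenius projection onto the nuclear ball, built from the two
    independent l1 projections (which must agree with each other)."""
    U, s, Vt = np.linalg.svd(np.asarray(A, dtype=float), full_matrices=False)
    x_enum = project_l1_enum(s, C)
    x_dual = project_l1_dual(s, C)
    assert np.max(np.abs(x_enum - x_dual)) < 1e-9, "oracle self-check failed"
    return (U * x_dual) @ Vt


# ---------------------------------------------------------------------------
# Constrained-training oracle (Frank-Wolfe with gap certificate)
# ---------------------------------------------------------------------------

def fw_train_oracle(X: np.ndarray, y: np.ndarray, C: float,
                    tol_gap: float = 2e-6, max_iter: int = 200_000
                    ) -> tuple[float, float]:
    """Solve min_(||W||_* <= C, b) mean log(1+exp(-y(<W,X>+b))).

    Returns (objective, gap): the final objective and a duality-gap bound on
    its suboptimality. After the exact b-minimization the b-gradient
    vanishes, so f(W, b) - f* <= max_{||S||_* <= C} <G, W - S> = gap.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    N, r, c = X.shape
    Xf = X.reshape(N, -1)
    W = np.zeros(r * c)
    b = 0.0
    gap = np.inf

    def obj(f):
        return float(np.mean(np.logaddexp(0.0, -y * f)))

    for _ in range(max_iter):
        fW = Xf @ W
        # exact minimization over the unconstrained intercept (1-D Newton)
        for _ in range(100):
            s = _sigmoid(-y * (fW + b))
            g = float(np.mean(-y * s))
            h = float(np.mean(s * (1.0 - s)))
            if h < 1e-14 or abs(g) < 1e-15:
                break
            step = g / h
            b -= step
            if abs(step) < 1e-14:
                break
        f = fW + b
        coeff = -y * _sigmoid(-y * f) / N
        G = (coeff @ Xf).reshape(r, c)
        U, sv, Vt = np.linalg.svd(G, full_matrices=False)
        S = (-C) * np.outer(U[:, 0], Vt[0])          # argmin_<G,S> over the ball
        d = S.ravel() - W
        gap = float(-(G.ravel() @ d))
        if gap < tol_gap:
            break
        # exact line search: phi(t) convex, phi' nondecreasing -> bisection
        dd = Xf @ d
        def dphi(t):
            return float(np.mean(-y * dd * _sigmoid(-y * (f + t * dd))))
        if dphi(1.0) <= 0:
            t_star = 1.0
        elif dphi(0.0) >= 0:
            t_star = 0.0
        else:
            lo, hi = 0.0, 1.0
            for _ in range(50):
                mid = 0.5 * (lo + hi)
                if dphi(mid) < 0:
                    lo = mid
                else:
                    hi = mid
            t_star = 0.5 * (lo + hi)
        if t_star == 0.0:
            break
        W = W + t_star * d
    return obj(Xf @ W + b), gap
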