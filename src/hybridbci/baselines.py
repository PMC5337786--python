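"""Conventional comparison methods: CSP-LDA for MI, stepwise LDA for P300,
and PROB score-average fusion of the two.

CSP solves the generalized eigenproblem Sigma_+ w = lambda (Sigma_+ +
Sigma_-) w; filters are b-orthonormal (w' (Sigma_+ + Sigma_-) w = 1) and
ordered by descending eigenvalue, so the first filters maximize class +1
band-power ratio and the last maximize class -1. Features are normalized
log variances of the first/last m filtered time courses.

SWLDA performs forward-selection / backward-elimination stepwise regression
of the +-1 label on the flattened ERP feature, then uses least-squares
weights on the selected set.

PROB averages the two LDA scores (optionally standardized by their
training-set standard deviation) and assigns +1 only when the average is
strictly positive — note this differs from the DS classifier's ">= 0" tie
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import DataError, N_CHANNELS, ShapeError

#: Default number of CSP filter pairs.
CSP_PAIRS = 3
#: Stepwise-regression defaults (standard P300-speller convention).
SWLDA_P_ENTER = 0.10
SWLDA_P_REMOVE = 0.15
SWLDA_MAX_FEATURES = 60


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

@dataclass
class CSPModel:
    """Spatial filters (rows), ordered by descending generalized eigenvalue."""

    filters: np.ndarray
    eigenvalues: np.ndarray
    n_pairs: int = CSP_PAIRS


def csp_fit(covs_pos: Sequence[np.ndarray], covs_neg: Sequence[np.ndarray],
            n_pairs: int = CSP_PAIRS) -> CSPModel:
    """Fit CSP filters from per-class trial covariances.

    Solves eigh(Sigma_+, Sigma_+ + Sigma_-); a singular composite covariance
    is ridge-regularized with 1e-6 * trace / n_channels.
    """
    if not covs_pos or not covs_neg:
        raise DataError("both classes must be present for CSP")
    Sp = np.mean(covs_pos, axis=0)
    Sm = np.mean(covs_neg, axis=0)
    St = Sp + Sm
    St = 0.5 * (St + St.T)
    n = St.shape[0]
    eigvals = np.linalg.eigvalsh(St)
    if eigvals[0] <= 1e-12 * max(eigvals[-1], 1.0):
        St = St + (1e-6 * np.trace(St) / n) * np.eye(n)
    w, V = linalg.eigh(0.5 * (Sp + Sp.T), St)
    order = np.argsort(w)[::-1]
    return CSPModel(filters=V[:, order].T, eigenvalues=w[order],
                    n_pairs=n_pairs)


def csp_features(segment, model: CSPModel, m: int | None = None) -> np.ndarray:
    """Normalized log-variance features of the first/last m CSP filters.

    Variances are normalized by their sum across the 2m retained filters, so
    the features are invariant to an overall scaling of the segment.
    """
    m = model.n_pairs if m is None else m
    X = segment.data if hasattr(segment, "data") else np.asarray(segment, dtype=float)
    F = np.vstack([model.filters[:m], model.filters[-m:]])
    Z = F @ X
    v = Z.var(axis=1, ddof=1)
    total = v.sum()
    if total <= 0:
        raise DataError("zero-variance segment in CSP feature computation")
    return np.log(v / total)


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Fisher discriminant with pooled covariance, equal priors.

    The score is w'x + b with the class-mean midpoint mapped to 0; its sign
    follows the +-1 label convention. ``score_scale`` is the training-set
    standard deviation of the scores, used by PROB standardization.
    """

    weights: np.ndarray
    bias: float
    score_scale: float = 1.0


def lda_fit(features: np.ndarray, labels, shrinkage: float | None = None
            ) -> LDAModel:
    """Fit LDA on row-vector features (wraps scikit-learn, lsqr solver)."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DataError("LDA needs both classes")
    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage,
                                     priors=(0.5, 0.5))
    clf.fit(X, y)
    w = clf.coef_.ravel().copy()
    b = float(clf.intercept_[0])
    # sklearn orders classes ascending (-1, +1): positive scores => class +1,
    # already our convention.
    scores = X @ w + b
    scale = float(scores.std(ddof=1))
    return LDAModel(weights=w, bias=b, score_scale=scale if scale > 0 else 1.0)


def lda_score(model: LDAModel, feature: np.ndarray) -> float:
    feature = np.asarray(feature, dtype=float).ravel()
    if feature.shape != model.weights.shape:
        raise ShapeError("feature dimension mismatch")
    return float(feature @ model.weights + model.bias)


# ---------------------------------------------------------------------------
# Stepwise LDA
# ---------------------------------------------------------------------------

@dataclass
class SWLDAModel:
    """Stepwise-selected least-squares discriminant on flattened features."""

    selected: list[int]
    weights: np.ndarray          # aligned with ``selected``
    intercept: float
    score_scale: float = 1.0
    p_enter: float = SWLDA_P_ENTER
    p_remove: float = SWLDA_P_REMOVE
    max_features: int = SWLDA_MAX_FEATURES
    intercept_only: bool = False


def _ols(D: np.ndarray, y: np.ndarray):
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return beta, resid, float(resid @ resid)


def swlda_fit(features: np.ndarray, labels, p_enter: float = SWLDA_P_ENTER,
              p_remove: float = SWLDA_P_REMOVE,
              max_features: int = SWLDA_MAX_FEATURES) -> SWLDAModel:
    """Forward/backward stepwise regression of the +-1 label on the features.

    Forward step: among excluded features, add the one with the smallest
    partial-F p-value if below ``p_enter``. Backward step: drop any included
    feature whose p-value rises above ``p_remove``. Stops when no move is
    possible or ``max_features`` is reached. If nothing is ever admitted, an
    intercept-only model is returned (flagged, no exception).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=float)
    n, p = X.shape
    if len(np.unique(y)) < 2:
        raise DataError("SWLDA needs both classes")
    if n < 10:
        raise DataError("SWLDA needs at least 10 samples")

    selected: list[int] = []
    changed = True
    while changed and len(selected) < max_features:
        changed = False
        D = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
        q = D.shape[1]
        if n - q - 1 < 1:
            break
        Q, _ = np.linalg.qr(D)
        r = y - Q @ (Q.T @ y)
        rss0 = float(r @ r)
        cand = np.array([j for j in range(p) if j not in selected])
        if len(cand):
            Xc = X[:, cand]
            Xt = Xc - Q @ (Q.T @ Xc)              # orthogonalized candidates
            denom = np.einsum("ij,ij->j", Xt, Xt)
            ok = denom > 1e-12 * max(np.abs(Xc).max() ** 2, 1.0) * n
            num = np.zeros(len(cand))
            num[ok] = (Xt[:, ok].T @ r) ** 2 / denom[ok]
            rss1 = rss0 - num
            df = n - q - 1
            with np.errstate(divide="ignore", invalid="ignore"):
                F = np.where(rss1 > 0, num / (rss1 / df), np.inf)
            pvals = stats.f.sf(F, 1, df)
            pvals[~ok] = 1.0
            jbest = int(np.argmin(pvals))
            if pvals[jbest] < p_enter:
                selected.append(int(cand[jbest]))
                changed = True
        # backward elimination on the current set
        removed = True
        while removed and selected:
            removed = False
            D = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
            q = D.shape[1]
            if n - q < 1:
                break
            beta, resid, rss = _ols(D, y)
            dof = n - q
            sigma2 = rss / dof if dof > 0 else np.inf
            XtX_inv = np.linalg.pinv(D.T @ D)
            se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
            tstat = beta / se
            pv = 2 * stats.t.sf(np.abs(tstat), dof)
            pv_feat = pv[1:]                       # skip intercept
            worst = int(np.argmax(pv_feat))
            if pv_feat[worst] > p_remove:
                del selected[worst]
                removed = True
                changed = True

    if not selected:
        b0 = float(y.mean())
        return SWLDAModel(selected=[], weights=np.zeros(0), intercept=b0,
                          score_scale=1.0, p_enter=p_enter,
                          p_remove=p_remove, max_features=max_features,
                          intercept_only=True)
    D = np.column_stack([np.ones(n)] + [X[:, j] for j in selected])
    beta, _, _ = _ols(D, y)
    scores = D @ beta
    scale = float(scores.std(ddof=1))
    return SWLDAModel(selected=list(selected), weights=beta[1:],
                      intercept=float(beta[0]),
                      score_scale=scale if scale > 0 else 1.0,
                      p_enter=p_enter, p_remove=p_remove,
                      max_features=max_features)


def swlda_score(model: SWLDAModel, feature: np.ndarray) -> float:
    feature = np.asarray(feature, dtype=float).ravel()
    if model.intercept_only:
        return model.intercept
    return float(feature[model.selected] @ model.weights + model.intercept)


# ---------------------------------------------------------------------------
# PROB fusion
# ---------------------------------------------------------------------------

def prob_fuse(score_mi: float, score_p300: float) -> int:
    """+1 iff the average score is strictly positive, else -1."""
    return 1 if 0.5 * (score_mi + score_p300) > 0 else -1
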