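"""Model selection and held-out evaluation.

The regularization budget C is chosen by stratified 10-fold cross-validation
on the training session over the grid 0.1, 0.3, ..., 9.9 (50 values); ties
break toward the smaller C (stronger regularization). All fitted statistics
(whiteners, block scales, CSP filters, stepwise selection) are refit inside
each fold from the fold's training part only.

Per-repetition curves re-score the test trials with the ERP block built from
the average of the first r flash epochs (r = 1..4); the MI block is
unaffected by r and the r = 4 point reproduces the standard pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classifier import SolverSettings
from .core import DataError, ParameterError
from .pipelines import DS_METHODS, DSMethod, N_REPEATS, TrialData, make_method

C_GRID_START = 0.1
C_GRID_STEP = 0.2
C_GRID_STOP = 10.0


def make_c_grid() -> np.ndarray:
    """The search grid for C: 0.1 to 10 in steps of 0.2 (50 values)."""
    n = int(np.floor((C_GRID_STOP - C_GRID_START) / C_GRID_STEP)) + 1
    return np.round(C_GRID_START + C_GRID_STEP * np.arange(n), 10)


@dataclass
class CVResult:
    grid: np.ndarray
    mean_accuracy: np.ndarray
    fold_assignments: np.ndarray   # fold index per trial, sorted by trial_id
    chosen_C: float

    def as_table(self) -> list[dict]:
        return [{"C": float(c), "mean_accuracy": float(a)}
                for c, a in zip(self.grid, self.mean_accuracy)]


def evaluate(method, trials: list[TrialData], r: int = N_REPEATS) -> float:
    """Fraction of correctly predicted trials."""
    if not trials:
        raise DataError("empty test set")
    hits = sum(method.predict(t, r) == t.label for t in trials)
    return hits / len(trials)


def cross_validate(trials: list[TrialData], grid=None, k: int = 10,
                   seed: int = 0, method: str = "ds_hybrid",
                   settings: SolverSettings | None = None,
                   scale_mode: str = "sum_variance") -> CVResult:
    """Stratified k-fold search over the C grid for a DS-family method.

    Within each fold the whiteners, scales and model are fitted on the
    training part only; features are prepared once per fold and shared
    across the C grid (only the constrained training is repeated).
    """
    if method not in DS_METHODS:
        raise ParameterError(f"cross_validate selects C for DS methods, got {method!r}")
    grid = make_c_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(grid <= 0):
        raise ParameterError("C grid must be a nonempty positive vector")
    # canonical order: fold assignment depends on (trial ids, labels, seed),
    # never on the order the caller happened to pass the trials in
    trials = sorted(trials, key=lambda t: t.trial_id)
    y = np.array([t.label for t in trials])
    for cls in (+1, -1):
        if (y == cls).sum() < k:
            raise DataError(f"class {cls:+d} has fewer than k={k} trials")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(trials), dtype=int)
    acc = np.zeros((k, len(grid)))
    for f, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[te_idx] = f
        m = DSMethod(variant=method, settings=settings or SolverSettings(),
                     scale_mode=scale_mode)
        m.prepare([trials[i] for i in tr_idx])
        held_out = [trials[i] for i in te_idx]
        for j, C in enumerate(grid):
            m.train_with_C(float(C))
            acc[f, j] = evaluate(m, held_out)
    mean_acc = acc.mean(axis=0)
    # argmax returns the first maximizer; the grid is ascending, so ties
    # resolve toward the smaller C.
    chosen = float(grid[int(np.argmax(mean_acc))])
    return CVResult(grid=grid, mean_accuracy=mean_acc,
                    fold_assignments=folds, chosen_C=chosen)


@dataclass
class RepetitionCurve:
    accuracy: np.ndarray   # index r-1 -> accuracy using the first r epochs

    def __post_init__(self) -> None:
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracies must lie in [0, 1]")


def repetition_curve(method, trials: list[TrialData],
                     repeats: int = N_REPEATS) -> RepetitionCurve:
    """Accuracy as a function of the number of flash repetitions used."""
    if repeats < 1 or repeats > N_REPEATS:
        raise ParameterError(f"repeats must lie in 1..{N_REPEATS}")
    return RepetitionCurve(np.array(
        [evaluate(method, trials, r=r) for r in range(1, repeats + 1)]))
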