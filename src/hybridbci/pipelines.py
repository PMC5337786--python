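"""The six decoding pipelines operating on recording-derived trials.

``extract_trials`` runs both preprocessing streams once and packages, per
trial, the four target-flash ERP epochs (kept separately so per-repetition
evaluation can average the first r of them) and the MI segment.

Methods (the six columns of the comparison):

* ``ds_hybrid``  — block-diagonal ERP + MI feature, DS-constrained trainer
* ``ds_p300``    — ERP block alone, same trainer
* ``ds_mi``      — MI covariance block alone, same trainer
* ``csp_mi``     — CSP log-variance features + LDA
* ``sl_p300``    — flattened raw trial-average ERP + stepwise LDA
* ``prob_hybrid``— average of the two standardized LDA scores

Every fitted statistic (whiteners, block scales, CSP filters, LDA weights,
stepwise selection) is computed inside ``fit`` from the trials it receives,
so cross-validation refits them per fold by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baselines
from .classifier import SolverSettings, decision_value, predict, train
from .core import ContinuousRecording, DataError, ParameterError, WhiteningSet
from .fusion import BLOCK_DIMS, BlockScales, fit_block_scales, fuse
from .mi import MICovariance, fit_mi_whitener, trial_covariance, whiten_mi
from .p300 import P300Feature, average_epochs, fit_p300_whiteners, whiten_p300
from .preprocessing import (extract_flash_epochs, extract_mi_segments,
                            prepare_mi_stream, prepare_p300_stream)

N_REPEATS = 4

METHODS = ("ds_hybrid", "ds_mi", "ds_p300", "csp_mi", "sl_p300", "prob_hybrid")
DS_METHODS = ("ds_hybrid", "ds_mi", "ds_p300")


@dataclass
class TrialData:
    """Preprocessed per-trial material for every pipeline."""

    trial_id: int
    label: int
    epochs: np.ndarray    # (4, 37, 15) target-flash ERP epochs, 60 Hz
    segment: np.ndarray   # (15, 400) band-passed MI segment, 100 Hz

    def p300_raw(self, r: int = N_REPEATS) -> np.ndarray:
        """Average of the first r flash epochs (the r=4 case is standard)."""
        if not (1 <= r <= self.epochs.shape[0]):
            raise ParameterError(f"r={r} outside 1..{self.epochs.shape[0]}")
        return average_epochs(list(self.epochs[:r]), require=None)


def extract_trials(recording: ContinuousRecording) -> list[TrialData]:
    """Run both preprocessing streams and package per-trial data."""
    rec = recording.normalized()
    rec.validate()
    labels = rec.labels()
    p300_stream = prepare_p300_stream(rec)
    mi_stream = prepare_mi_stream(rec)
    epochs = extract_flash_epochs(p300_stream)
    segments = extract_mi_segments(mi_stream)
    by_trial: dict[int, list[np.ndarray]] = {}
    for e in epochs:
        by_trial.setdefault(e.trial_id, []).append(e.data)
    seg_by_trial = {s.trial_id: s.data for s in segments}
    trials = []
    for tid in sorted(labels):
        if len(by_trial.get(tid, [])) != N_REPEATS:
            raise DataError(f"trial {tid}: expected {N_REPEATS} target epochs")
        trials.append(TrialData(trial_id=tid, label=labels[tid],
                                epochs=np.stack(by_trial[tid]),
                                segment=seg_by_trial[tid]))
    return trials


# ---------------------------------------------------------------------------
# DS-family methods
# ---------------------------------------------------------------------------

@dataclass
class DSMethod:
    """DS-constrained matrix classifier in hybrid or single-modality form.

    ``prepare``/``train_with_C`` are split so model selection can reuse one
    fold's fitted whiteners and features across the whole C grid.
    """

    variant: str = "ds_hybrid"
    C: float = 2.0
    settings: SolverSettings = field(default_factory=SolverSettings)
    scale_mode: str = "sum_variance"

    def __post_init__(self) -> None:
        if self.variant not in DS_METHODS:
            raise ParameterError(f"unknown DS variant {self.variant!r}")

    @property
    def name(self) -> str:
        return self.variant

    # -- phase 1: fit whiteners/scales and build training features ----------
    def prepare(self, trials: list[TrialData]) -> None:
        self._labels = np.array([t.label for t in trials])
        self.whiteners = WhiteningSet()
        use_p300 = self.variant in ("ds_hybrid", "ds_p300")
        use_mi = self.variant in ("ds_hybrid", "ds_mi")

        if use_p300:
            raws = {r: [t.p300_raw(r) for t in trials]
                    for r in range(1, N_REPEATS + 1)}
            self.whiteners.Pt, self.whiteners.Ps = fit_p300_whiteners(raws[N_REPEATS])
            feats_by_r = {r: [whiten_p300(x, self.whiteners.Pt, self.whiteners.Ps,
                                          t.trial_id, t.label)
                              for x, t in zip(raws[r], trials)]
                          for r in raws}
            self._p300_feats = feats_by_r[N_REPEATS]
            # the variance of an r-epoch average depends on r: refit xi per r
            self._xi1_by_r = {
                r: float(np.sqrt(max(
                    np.stack([f.xbar for f in feats_by_r[r]]).var(axis=0, ddof=1).sum()
                    / (1.0 if self.scale_mode == "sum_variance"
                       else feats_by_r[r][0].xbar.size),
                    1e-300)))
                for r in feats_by_r}
        if use_mi:
            covs = [trial_covariance(t.segment) for t in trials]
            self.whiteners.Wmi = fit_mi_whitener([t.segment for t in trials])
            self._mi_feats = [whiten_mi(c, self.whiteners.Wmi, t.trial_id, t.label)
                              for c, t in zip(covs, trials)]

        if self.variant == "ds_hybrid":
            self.scales = fit_block_scales(self._p300_feats, self._mi_feats,
                                           mode=self.scale_mode)
            self._features = [fuse(p, m, self.scales)
                              for p, m in zip(self._p300_feats, self._mi_feats)]
            self._block_dims = BLOCK_DIMS
        elif self.variant == "ds_p300":
            self.scales = BlockScales(xi1=self._xi1_by_r[N_REPEATS], xi2=1.0)
            self._features = [f.xbar / self.scales.xi1 for f in self._p300_feats]
            self._block_dims = (BLOCK_DIMS[0],)
        else:  # ds_mi
            stack = np.stack([f.gamma for f in self._mi_feats])
            v = stack.var(axis=0, ddof=1).sum()
            if self.scale_mode == "mean_variance":
                v /= stack[0].size
            if v <= 0:
                raise DataError("degenerate MI features: zero total variance")
            self.scales = BlockScales(xi1=1.0, xi2=float(np.sqrt(v)))
            self._features = [f.gamma / self.scales.xi2 for f in self._mi_feats]
            self._block_dims = (BLOCK_DIMS[1],)

    # -- phase 2: constrained training --------------------------------------
    def train_with_C(self, C: float) -> None:
        self.C = float(C)
        self.model = train(self._features, self._labels, self.C,
                           settings=self.settings, block_dims=self._block_dims,
                           xi1=self.scales.xi1, xi2=self.scales.xi2,
                           whiteners=self.whiteners)

    def fit(self, trials: list[TrialData]) -> "DSMethod":
        self.prepare(trials)
        self.train_with_C(self.C)
        return self

    # -- prediction ----------------------------------------------------------
    def _feature_of(self, trial: TrialData, r: int = N_REPEATS):
        if self.variant == "ds_mi":
            gamma = whiten_mi(trial_covariance(trial.segment),
                              self.whiteners.Wmi, trial.trial_id, trial.label)
            return gamma.gamma / self.scales.xi2
        xbar = whiten_p300(trial.p300_raw(r), self.whiteners.Pt,
                           self.whiteners.Ps, trial.trial_id, trial.label)
        xi1 = self._xi1_by_r[r]
        if self.variant == "ds_p300":
            return xbar.xbar / xi1
        gamma = whiten_mi(trial_covariance(trial.segment),
                          self.whiteners.Wmi, trial.trial_id, trial.label)
        return fuse(xbar, gamma,
                    BlockScales(xi1=xi1, xi2=self.scales.xi2))

    def decision(self, trial: TrialData, r: int = N_REPEATS) -> float:
        return decision_value(self.model, self._feature_of(trial, r))

    def predict(self, trial: TrialData, r: int = N_REPEATS) -> int:
        return predict(self.model, self._feature_of(trial, r))


# ---------------------------------------------------------------------------
# Baseline methods
# ---------------------------------------------------------------------------

@dataclass
class CSPMIMethod:
    """CSP log-variance features + LDA on the MI segments."""

    n_pairs: int = baselines.CSP_PAIRS
    name: str = "csp_mi"

    def fit(self, trials: list[TrialData]) -> "CSPMIMethod":
        covs_pos = [trial_covariance(t.segment) for t in trials if t.label == 1]
        covs_neg = [trial_covariance(t.segment) for t in trials if t.label == -1]
        self.csp = baselines.csp_fit(covs_pos, covs_neg, n_pairs=self.n_pairs)
        feats = np.array([baselines.csp_features(t.segment, self.csp)
                          for t in trials])
        self.lda = baselines.lda_fit(feats, [t.label for t in trials])
        return self

    def decision(self, trial: TrialData, r: int = N_REPEATS) -> float:
        return baselines.lda_score(
            self.lda, baselines.csp_features(trial.segment, self.csp))

    def predict(self, trial: TrialData, r: int = N_REPEATS) -> int:
        return 1 if self.decision(trial) >= 0 else -1


@dataclass
class SLP300Method:
    """Stepwise LDA on the flattened raw trial-average ERP (555 dims)."""

    p_enter: float = baselines.SWLDA_P_ENTER
    p_remove: float = baselines.SWLDA_P_REMOVE
    max_features: int = baselines.SWLDA_MAX_FEATURES
    name: str = "sl_p300"

    def fit(self, trials: list[TrialData]) -> "SLP300Method":
        X = np.array([t.p300_raw().ravel() for t in trials])
        self.swlda = baselines.swlda_fit(
            X, [t.label for t in trials], p_enter=self.p_enter,
            p_remove=self.p_remove, max_features=self.max_features)
        return self

    def decision(self, trial: TrialData, r: int = N_REPEATS) -> float:
        return baselines.swlda_score(self.swlda, trial.p300_raw(r).ravel())

    def predict(self, trial: TrialData, r: int = N_REPEATS) -> int:
        return 1 if self.decision(trial, r) >= 0 else -1


@dataclass
class PROBMethod:
    """Average of the CSP-LDA and SWLDA scores, thresholded strictly at 0.

    ``score_norm="standardized"`` divides each score by its training-set
    standard deviation so the modalities are commensurate.
    """

    score_norm: str = "standardized"
    n_pairs: int = baselines.CSP_PAIRS
    name: str = "prob_hybrid"

    def fit(self, trials: list[TrialData]) -> "PROBMethod":
        self.mi = CSPMIMethod(n_pairs=self.n_pairs).fit(trials)
        self.p300 = SLP300Method().fit(trials)
        return self

    def _scores(self, trial: TrialData, r: int) -> tuple[float, float]:
        s_mi = self.mi.decision(trial)
        s_p3 = self.p300.decision(trial, r)
        if self.score_norm == "standardized":
            s_mi /= self.mi.lda.score_scale
            s_p3 /= self.p300.swlda.score_scale
        elif self.score_norm != "raw":
            raise ParameterError(f"unknown score_norm {self.score_norm!r}")
        return s_mi, s_p3

    def decision(self, trial: TrialData, r: int = N_REPEATS) -> float:
        s_mi, s_p3 = self._scores(trial, r)
        return 0.5 * (s_mi + s_p3)

    def predict(self, trial: TrialData, r: int = N_REPEATS) -> int:
        return baselines.prob_fuse(*self._scores(trial, r))


def make_method(name: str, C: float = 2.0,
                settings: SolverSettings | None = None, **kwargs):
    """Factory over the six method names."""
    if name in DS_METHODS:
        return DSMethod(variant=name, C=C,
                        settings=settings or SolverSettings(), **kwargs)
    if name == "csp_mi":
        return CSPMIMethod(**kwargs)
    if name == "sl_p300":
        return SLP300Method(**kwargs)
    if name == "prob_hybrid":
        return PROBMethod(**kwargs)
    raise ParameterError(f"unknown method {name!r}; choose from {METHODS}")
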