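"""Shared domain types, label conventions, and file I/O.

The pipeline works on continuous multichannel EEG plus an event table.
Fifteen sensorimotor/parieto-occipital channels are analysed; each trial
carries one task cue (P300 attention task -> label +1, right-hand motor
imagery -> label -1) and 32 button flashes (8 buttons x 4 rounds).

Native interchange format is text-first: a delimited samples matrix
(channels x samples), a delimited event table, and a JSON metadata sidecar.
Fitted models are stored as a single JSON document (JSON round-trips
float64 exactly in Python).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridbci")

#: Canonical analysis channels, in canonical order.
CHANNELS = (
    "FC3", "FCz", "FC4",
    "C3", "Cz", "C4",
    "CP3", "CPz", "CP4",
    "P3", "Pz", "P4",
    "O1", "Oz", "O2",
)
N_CHANNELS = len(CHANNELS)

#: Paradigm constants: 8 buttons flash in 4 rounds per trial.
N_BUTTONS = 8
N_ROUNDS = 4
N_FLASHES_PER_TRIAL = N_BUTTONS * N_ROUNDS
#: The attended button (up-center) in the P300 task.
TARGET_BUTTON = 1

#: Label convention: +1 = P300 (button attention) trial, -1 = motor imagery.
LABEL_P300 = +1
LABEL_MI = -1

MODEL_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ChannelError(ValueError):
    """A required analysis channel is missing."""


class FormatError(ValueError):
    """A file or table does not conform to the expected layout."""


class ParameterError(ValueError):
    """An argument is outside its valid range."""


class BoundaryError(ValueError):
    """An epoch or segment window falls outside the recording."""


class DataError(ValueError):
    """Input data is insufficient or degenerate for the requested fit."""


class ShapeError(ValueError):
    """An array has the wrong shape or violates a structural requirement."""


# ---------------------------------------------------------------------------
# Event table
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ("trial_id", "kind", "onset_sample", "task", "button_id", "round_index")


@dataclass
class EventTable:
    """Sample-indexed cue and flash events.

    One row per event. Cue rows carry ``task`` in {"p300", "mi"}; flash rows
    carry ``button_id`` (1..8) and ``round_index`` (1..4). Sample indices are
    0-based.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"event table missing columns {missing}")
        self.df = self.df.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        self.df["trial_id"] = self.df["trial_id"].astype(int)
        self.df["onset_sample"] = self.df["onset_sample"].astype(int)
        self.df["button_id"] = self.df["button_id"].fillna(0).astype(int)
        self.df["round_index"] = self.df["round_index"].fillna(0).astype(int)
        self.df["task"] = self.df["task"].fillna("").astype(str)
        self.df["kind"] = self.df["kind"].astype(str)

    # -- accessors ---------------------------------------------------------
    @property
    def cues(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "cue"]

    @property
    def flashes(self) -> pd.DataFrame:
        return self.df[self.df["kind"] == "flash"]

    @property
    def trial_ids(self) -> list[int]:
        return sorted(self.df["trial_id"].unique().tolist())

    def labels(self) -> dict[int, int]:
        """Map trial_id -> label (+1 P300 task, -1 MI task)."""
        out: dict[int, int] = {}
        for _, row in self.cues.iterrows():
            out[int(row["trial_id"])] = LABEL_P300 if row["task"] == "p300" else LABEL_MI
        return out

    # -- validation --------------------------------------------------------
    def validate(self, n_samples: int | None = None,
                 target_button: int = TARGET_BUTTON) -> None:
        bad_kind = set(self.df["kind"]) - {"cue", "flash"}
        if bad_kind:
            raise FormatError(f"unknown event kinds {sorted(bad_kind)}")
        if (self.df["onset_sample"] < 0).any():
            raise FormatError("negative event onset")
        if n_samples is not None and (self.df["onset_sample"] >= n_samples).any():
            raise FormatError("event onset beyond end of recording")
        for tid, grp in self.df.groupby("trial_id"):
            cues = grp[grp["kind"] == "cue"]
            flashes = grp[grp["kind"] == "flash"]
            if len(cues) != 1:
                raise FormatError(f"trial {tid}: expected 1 cue, found {len(cues)}")
            if cues.iloc[0]["task"] not in ("p300", "mi"):
                raise FormatError(f"trial {tid}: cue task must be 'p300' or 'mi'")
            if len(flashes) != N_FLASHES_PER_TRIAL:
                raise FormatError(
                    f"trial {tid}: expected {N_FLASHES_PER_TRIAL} flashes, "
                    f"found {len(flashes)}")
            n_target = int((flashes["button_id"] == target_button).sum())
            if n_target != N_ROUNDS:
                raise FormatError(
                    f"trial {tid}: expected {N_ROUNDS} target-button flashes, "
                    f"found {n_target}")

    def scaled(self, factor: float) -> "EventTable":
        """Return a copy with onsets rescaled (round-to-nearest)."""
        df = self.df.copy()
        df["onset_sample"] = np.rint(df["onset_sample"] * factor).astype(int)
        return EventTable(df)


# ---------------------------------------------------------------------------
# Continuous recording
# ---------------------------------------------------------------------------

@dataclass
class ContinuousRecording:
    """Multichannel EEG (microvolts), channels x samples, plus events."""

    samples: np.ndarray
    rate_hz: float
    channel_names: list[str]
    events: EventTable

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ShapeError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channel_names):
            raise ShapeError("n_channels != len(channel_names)")
        if self.rate_hz <= 0:
            raise ParameterError("rate_hz must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def validate(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channel_names]
        if missing:
            raise ChannelError(f"missing analysis channels {missing}")
        self.events.validate(n_samples=self.n_samples)

    def normalized(self) -> "ContinuousRecording":
        """Restrict to the 15 analysis channels in canonical order.

        Extra channels (e.g. EOG) are dropped with a logged warning.
        """
        missing = [c for c in CHANNELS if c not in self.channel_names]
        if missing:
            raise ChannelError(f"missing analysis channels {missing}")
        extra = [c for c in self.channel_names if c not in CHANNELS]
        if extra:
            logger.warning("dropping non-analysis channels %s", extra)
        idx = [self.channel_names.index(c) for c in CHANNELS]
        return ContinuousRecording(self.samples[idx], self.rate_hz,
                                   list(CHANNELS), self.events)

    def labels(self) -> dict[int, int]:
        return self.events.labels()


# ---------------------------------------------------------------------------
# Whiteners and the fitted model
# ---------------------------------------------------------------------------

@dataclass
class WhiteningSet:
    """Training-fitted normalizers: Sigma^-1/4 pair for the ERP feature and
    Sigma^-1/2 for the MI covariance."""

    Ps: np.ndarray | None = None   # 15x15 spatial, power -1/4
    Pt: np.ndarray | None = None   # 37x37 temporal, power -1/4
    Wmi: np.ndarray | None = None  # 15x15 spatial, power -1/2

    def validate(self, tol: float = 1e-10) -> None:
        for name, M in (("Ps", self.Ps), ("Pt", self.Pt), ("Wmi", self.Wmi)):
            if M is None:
                continue
            if M.ndim != 2 or M.shape[0] != M.shape[1]:
                raise ShapeError(f"{name} must be square")
            scale = max(np.abs(M).max(), 1.0)
            if np.abs(M - M.T).max() > tol * scale:
                raise ShapeError(f"{name} not symmetric within tolerance")


@dataclass
class DSModel:
    """Linear matrix classifier f(X) = <W, X> + b with nuclear norm of W
    bounded by the budget C.

    ``blocks`` holds the diagonal blocks of W (one entry for single-modality
    models, two -- ERP then MI -- for the hybrid); off-diagonal blocks of the
    assembled W are exactly zero by construction.
    """

    blocks: list[np.ndarray]
    b: float
    C: float
    block_dims: tuple[tuple[int, int], ...]
    xi1: float | None = None
    xi2: float | None = None
    whiteners: WhiteningSet = field(default_factory=WhiteningSet)
    tol_feas: float = 1e-6
    converged: bool = True
    n_iter: int = 0
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(B, dtype=float) for B in self.blocks]
        dims = tuple(B.shape for B in self.blocks)
        if tuple(map(tuple, self.block_dims)) != dims:
            raise ShapeError(f"block_dims {self.block_dims} != block shapes {dims}")
        if self.C <= 0:
            raise ParameterError("C must be positive")

    @property
    def W(self) -> np.ndarray:
        """Assembled block-diagonal weight matrix (zero off-diagonal blocks)."""
        rows = sum(B.shape[0] for B in self.blocks)
        cols = sum(B.shape[1] for B in self.blocks)
        W = np.zeros((rows, cols))
        r = c = 0
        for B in self.blocks:
            W[r:r + B.shape[0], c:c + B.shape[1]] = B
            r += B.shape[0]
            c += B.shape[1]
        return W

    def nuclear_norm(self) -> float:
        return float(sum(np.linalg.svd(B, compute_uv=False).sum()
                         for B in self.blocks))

    def validate(self) -> None:
        if self.nuclear_norm() > self.C * (1.0 + self.tol_feas) + 1e-12:
            raise FormatError(
                f"nuclear norm {self.nuclear_norm():.6g} exceeds budget "
                f"C={self.C} beyond tolerance")
        self.whiteners.validate()


# ---------------------------------------------------------------------------
# Recording I/O (text-first interchange format)
# ---------------------------------------------------------------------------

def _paths(path: str | Path) -> tuple[Path, Path, Path]:
    base = Path(path)
    if base.suffix == ".json":
        base = base.with_suffix("")
    return (base.with_suffix(".samples.tsv"),
            base.with_suffix(".events.tsv"),
            base.with_suffix(".meta.json"))


def write_recording(recording: ContinuousRecording, path: str | Path) -> None:
    """Write a recording as samples TSV + events TSV + JSON metadata.

    ``path`` is a stem; three sidecar files are produced. Samples are written
    with %.17g so float64 values round-trip bit-exactly.
    """
    samples_p, events_p, meta_p = _paths(path)
    samples_p.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(samples_p, recording.samples, fmt="%.17g", delimiter="\t")
    recording.events.df.to_csv(events_p, sep="\t", index=False)
    meta_p.write_text(json.dumps(
        {"rate_hz": recording.rate_hz,
         "channel_names": list(recording.channel_names)}, indent=1))


def read_recording(path: str | Path) -> ContinuousRecording:
    """Read a recording written by :func:`write_recording` and validate it."""
    samples_p, events_p, meta_p = _paths(path)
    for p in (samples_p, events_p, meta_p):
        if not p.exists():
            raise FileNotFoundError(f"missing recording file {p}")
    try:
        meta = json.loads(meta_p.read_text())
        samples = np.loadtxt(samples_p, delimiter="\t", ndmin=2)
        events_df = pd.read_csv(events_p, sep="\t")
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"malformed recording at {path}: {exc}") from exc
    try:
        events = EventTable(events_df)
    except FormatError:
        raise
    rec = ContinuousRecording(samples, float(meta["rate_hz"]),
                              list(meta["channel_names"]), events)
    rec.validate()
    return rec


# ---------------------------------------------------------------------------
# Model I/O
# ---------------------------------------------------------------------------

def _arr(x: np.ndarray | None):
    return None if x is None else np.asarray(x, dtype=float).tolist()


def _unarr(x) -> np.ndarray | None:
    return None if x is None else np.asarray(x, dtype=float)


def write_model(model: DSModel, path: str | Path) -> None:
    """Serialize a fitted model to JSON (lossless for float64)."""
    model.validate()
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "blocks": [_arr(B) for B in model.blocks],
        "b": model.b,
        "C": model.C,
        "block_dims": [list(d) for d in model.block_dims],
        "xi1": model.xi1,
        "xi2": model.xi2,
        "tol_feas": model.tol_feas,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "whiteners": {
            "Ps": _arr(model.whiteners.Ps),
            "Pt": _arr(model.whiteners.Pt),
            "Wmi": _arr(model.whiteners.Wmi),
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(doc))


def read_model(path: str | Path) -> DSModel:
    """Load a model, re-checking the nuclear-norm feasibility invariant."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"malformed model file: {exc}") from exc
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"model format version {doc.get('format_version')!r} not supported")
    wh = doc.get("whiteners", {})
    model = DSModel(
        blocks=[np.asarray(B, dtype=float) for B in doc["blocks"]],
        b=float(doc["b"]),
        C=float(doc["C"]),
        block_dims=tuple(tuple(d) for d in doc["block_dims"]),
        xi1=doc.get("xi1"),
        xi2=doc.get("xi2"),
        tol_feas=float(doc.get("tol_feas", 1e-6)),
        converged=bool(doc.get("converged", True)),
        n_iter=int(doc.get("n_iter", 0)),
        whiteners=WhiteningSet(Ps=_unarr(wh.get("Ps")),
                               Pt=_unarr(wh.get("Pt")),
                               Wmi=_unarr(wh.get("Wmi"))),
    )
    model.validate()
    return model
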