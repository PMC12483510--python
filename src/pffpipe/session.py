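"""Core in-memory containers: behavior traces, ground truth, and sessions."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .config import CorridorSpec

__all__ = ["BehaviorTrace", "TruthEvent", "GroundTruth", "SessionData"]

#: Ground-truth event kinds the generator can implant.
EVENT_KINDS = ("BTSP", "NON_BTSP", "SOLITARY", "PREEXISTING_PF")


@dataclass
class BehaviorTrace:
    """Per-frame behavior of one session.

    ``lap_index`` is 1-based and non-decreasing; position resets to zero at
    each teleport (lap boundary) and is non-decreasing within a lap.
    """

    time_s: np.ndarray
    position_cm: np.ndarray
    speed_cm_s: np.ndarray
    lap_index: np.ndarray
    frame_rate_hz: float = 31.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.position_cm = np.asarray(self.position_cm, dtype=np.float64)
        self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=np.float64)
        self.lap_index = np.asarray(self.lap_index, dtype=np.int64)
        n = len(self.time_s)
        for name in ("position_cm", "speed_cm_s", "lap_index"):
            if len(getattr(self, name)) != n:
                raise ValueError(
                    f"behavior length mismatch: {name} has {len(getattr(self, name))} "
                    f"frames, time_s has {n}"
                )
        if n and np.any(np.diff(self.lap_index) < 0):
            raise ValueError("lap_index must be non-decreasing")
        if n and np.any(self.speed_cm_s < 0):
            raise ValueError("speed must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    @property
    def n_laps(self) -> int:
        return int(self.lap_index.max()) if self.n_frames else 0

    def lap_slices(self) -> list[slice]:
        """Frame slice of each lap, index 0 holding lap 1."""
        out = []
        bounds = np.flatnonzero(np.diff(self.lap_index)) + 1
        starts = np.concatenate([[0], bounds])
        ends = np.concatenate([bounds, [self.n_frames]])
        for s, e in zip(starts, ends):
            out.append(slice(int(s), int(e)))
        return out


@dataclass
class TruthEvent:
    """One implanted event of the synthetic ground truth."""

    roi_id: int
    kind: str                       # one of EVENT_KINDS
    formation_lap: int              # 1-based
    center_cm: float
    formation_amplitude_au: float
    post_amplitude_au: float
    com_shift_cm: float = 0.0       # positive = backward shift magnitude
    drift_cm_per_lap: float = 0.0   # positive = continuous backward drift
    end_lap: Optional[int] = None   # None = active to session end

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.formation_lap < 1:
            raise ValueError("formation_lap must be >= 1")
        if self.formation_amplitude_au < 0 or self.post_amplitude_au < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class GroundTruth:
    """Implanted events plus optional population switch lap."""

    n_rois: int
    events: list[TruthEvent] = field(default_factory=list)
    switch_lap: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "n_rois": self.n_rois,
            "switch_lap": self.switch_lap,
            "events": [asdict(e) for e in self.events],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            n_rois=int(d["n_rois"]),
            events=[TruthEvent(**e) for e in d.get("events", [])],
            switch_lap=d.get("switch_lap"),
        )


@dataclass
class SessionData:
    """A complete session: fluorescence, deconvolved activity, and behavior.

    This is the universal input of the pipeline; synthetic sessions carry
    their :class:`GroundTruth` in ``truth``.
    """

    behavior: BehaviorTrace
    F_raw: np.ndarray               # frames x ROIs, a.u.
    F_neu: np.ndarray               # frames x ROIs, a.u.
    deconvolved: np.ndarray         # frames x ROIs, a.u., >= 0
    corridor: CorridorSpec = field(default_factory=CorridorSpec)
    truth: Optional[GroundTruth] = None
    seed: Optional[int] = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        n = self.behavior.n_frames
        for name in ("F_raw", "F_neu", "deconvolved"):
            m = getattr(self, name)
            if m.shape[0] != n:
                raise ValueError(
                    f"{name} has {m.shape[0]} frames but behavior has {n}"
                )
        shapes = {self.F_raw.shape, self.F_neu.shape, self.deconvolved.shape}
        if len(shapes) != 1:
            raise ValueError(f"matrix shapes differ: {shapes}")
        if np.any(self.deconvolved < 0):
            raise ValueError("deconvolved activity must be non-negative")

    @property
    def n_rois(self) -> int:
        return self.F_raw.shape[1]

    @property
    def n_frames(self) -> int:
        return self.F_raw.shape[0]


# Spec-facing alias: a SessionData whose ``truth`` is populated.
SyntheticSession = SessionData
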