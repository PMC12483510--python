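"""Session readers/writers: HDF5 container (canonical) and NPY triplets.

HDF5 layout (version 1):

    /F_raw, /F_neu, /deconvolved          frames x ROIs float64
    /behavior/{time,position,speed,lap}   per-frame vectors
    attrs: corridor geometry, frame rate, seed, source, layout_version,
           truth (ground truth as a JSON string, when present)

The NPY-triplet layout mirrors common segmentation-suite outputs: a
directory with ``F_raw.npy``, ``F_neu.npy``, ``deconvolved.npy``,
``behavior.npz`` and ``meta.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .config import CorridorSpec
from .session import BehaviorTrace, GroundTruth, SessionData

__all__ = ["save_session", "load_session", "LAYOUT_VERSION"]

LAYOUT_VERSION = 1


def _corridor_meta(spec: CorridorSpec) -> dict:
    return {
        "length_cm": spec.length_cm,
        "bin_width_cm": spec.bin_width_cm,
        "landmark_centroids_cm": list(spec.landmark_centroids_cm),
        "reward_zone_cm": list(spec.reward_zone_cm),
    }


def _corridor_from_meta(d: dict) -> CorridorSpec:
    return CorridorSpec(
        length_cm=float(d["length_cm"]),
        bin_width_cm=float(d["bin_width_cm"]),
        landmark_centroids_cm=tuple(d["landmark_centroids_cm"]),
        reward_zone_cm=tuple(d["reward_zone_cm"]),
    )


def save_session(session: SessionData, path: str | Path, format: str = "hdf5") -> Path:
    """Write a session to disk; returns the path written."""
    path = Path(path)
    if format == "hdf5":
        return _save_hdf5(session, path)
    if format == "npy-triplet":
        return _save_npy(session, path)
    raise ValueError(f"unknown format {format!r}")


def _save_hdf5(session: SessionData, path: Path) -> Path:
    with h5py.File(path, "w", track_order=True) as f:
        opts = dict(track_times=False)  # reproducible bytes for fixed inputs
        f.create_dataset("F_raw", data=session.F_raw, **opts)
        f.create_dataset("F_neu", data=session.F_neu, **opts)
        f.create_dataset("deconvolved", data=session.deconvolved, **opts)
        g = f.create_group("behavior")
        b = session.behavior
        g.create_dataset("time", data=b.time_s, **opts)
        g.create_dataset("position", data=b.position_cm, **opts)
        g.create_dataset("speed", data=b.speed_cm_s, **opts)
        g.create_dataset("lap", data=b.lap_index, **opts)
        f.attrs["frame_rate_hz"] = b.frame_rate_hz
        f.attrs["corridor"] = json.dumps(_corridor_meta(session.corridor))
        f.attrs["layout_version"] = LAYOUT_VERSION
        f.attrs["source"] = session.source
        if session.seed is not None:
            f.attrs["seed"] = session.seed
        if session.truth is not None:
            f.attrs["truth"] = json.dumps(session.truth.to_dict())
    return path


def _save_npy(session: SessionData, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "F_raw.npy", session.F_raw)
    np.save(path / "F_neu.npy", session.F_neu)
    np.save(path / "deconvolved.npy", session.deconvolved)
    b = session.behavior
    np.savez(
        path / "behavior.npz",
        time=b.time_s, position=b.position_cm, speed=b.speed_cm_s, lap=b.lap_index,
    )
    meta = {
        "frame_rate_hz": b.frame_rate_hz,
        "corridor": _corridor_meta(session.corridor),
        "layout_version": LAYOUT_VERSION,
        "source": session.source,
        "seed": session.seed,
        "truth": session.truth.to_dict() if session.truth is not None else None,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def load_session(path: str | Path, format: str | None = None) -> SessionData:
    """Load a session, validating shape consistency.

    ``format`` is inferred from the path when not given (directory ->
    npy-triplet, file -> hdf5).
    """
    path = Path(path)
    if format is None:
        format = "npy-triplet" if path.is_dir() else "hdf5"
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "npy-triplet":
        return _load_npy(path)
    raise ValueError(f"unknown format {format!r}")


def _behavior(time, position, speed, lap, frame_rate) -> BehaviorTrace:
    return BehaviorTrace(
        time_s=time, position_cm=position, speed_cm_s=speed,
        lap_index=lap, frame_rate_hz=frame_rate,
    )


def _load_hdf5(path: Path) -> SessionData:
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for key in ("F_raw", "F_neu", "deconvolved"):
            if key not in f:
                raise ValueError(f"missing dataset /{key} in {path}")
        if "behavior" not in f:
            raise ValueError(f"missing group /behavior in {path}")
        b = f["behavior"]
        behavior = _behavior(
            b["time"][:], b["position"][:], b["speed"][:], b["lap"][:],
            float(f.attrs.get("frame_rate_hz", 31.0)),
        )
        truth = None
        if "truth" in f.attrs:
            truth = GroundTruth.from_dict(json.loads(f.attrs["truth"]))
        seed = int(f.attrs["seed"]) if "seed" in f.attrs else None
        return SessionData(
            behavior=behavior,
            F_raw=f["F_raw"][:],
            F_neu=f["F_neu"][:],
            deconvolved=f["deconvolved"][:],
            corridor=_corridor_from_meta(json.loads(f.attrs["corridor"])),
            truth=truth,
            seed=seed,
            source=str(f.attrs.get("source", "unknown")),
        )


def _load_npy(path: Path) -> SessionData:
    for name in ("F_raw.npy", "F_neu.npy", "deconvolved.npy", "behavior.npz", "meta.json"):
        if not (path / name).exists():
            raise FileNotFoundError(path / name)
    meta = json.loads((path / "meta.json").read_text())
    beh = np.load(path / "behavior.npz")
    behavior = _behavior(
        beh["time"], beh["position"], beh["speed"], beh["lap"],
        float(meta.get("frame_rate_hz", 31.0)),
    )
    truth = GroundTruth.from_dict(meta["truth"]) if meta.get("truth") else None
    return SessionData(
        behavior=behavior,
        F_raw=np.load(path / "F_raw.npy"),
        F_neu=np.load(path / "F_neu.npy"),
        deconvolved=np.load(path / "deconvolved.npy"),
        corridor=_corridor_from_meta(meta["corridor"]),
        truth=truth,
        seed=meta.get("seed"),
        source=meta.get("source", "unknown"),
    )
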