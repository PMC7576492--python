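"""Containers and file I/O for multi-channel surface-EMG recordings.

A :class:`Recording` holds one trial: the raw EMG matrix (monopolar or
differential), the wrist-force channel at its own sampling rate, and the
trial metadata (elbow angle, forearm posture, channel-to-muscle map).
A :class:`EnvelopeSet` is the pre-processed product consumed by channel
selection and force modelling: normalized linear envelopes, the aligned
force, the constant-force plateau segments, and the filtered differential
EMG the envelopes were derived from.

Two on-disk encodings are supported:

* CSV — one column per EMG channel with a ``muscle:index`` header, the force
  stream in a ``<stem>.force.csv`` sidecar and metadata in UTF-8 ``key=value``
  lines in ``<stem>.meta.txt``.  Human-inspectable; used for small fixtures.
* HDF5 — one dataset per stream, metadata as root attributes.  Compact bulk
  storage for cohorts.

Force and EMG are stored at their native rates; alignment happens in the
pre-processing pipeline, not here.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import h5py
import numpy as np

from .errors import FormatError, SchemaError

MUSCLES = ("biceps_long", "biceps_short", "brachioradialis")
POSTURES = ("neutral", "supinated")
MONOPOLAR_PER_MUSCLE = 8
DIFFERENTIAL_PER_MUSCLE = 7

_META_KEYS = ("fs_emg", "fs_force", "angle_deg", "posture", "channel_kind",
              "subject_id", "trial_id")


class Segment(NamedTuple):
    """Half-open sample range [start, stop) at one constant-force level.

    ``level`` is the target force as a fraction of MVC (0.20 / 0.35 / 0.50).
    """

    start: int
    stop: int
    level: float


@dataclass
class Recording:
    """One trial of multi-array HD-EMG plus the simultaneously recorded force.

    Parameters
    ----------
    emg : ndarray, shape (n_samples, n_channels)
        EMG in volts, one column per channel.
    fs_emg : float
        EMG sampling rate in Hz (2048 for the linear-array hardware).
    force : ndarray, shape (n_force,)
        Wrist force in newtons at ``fs_force`` Hz (1000 by default); the two
        streams cover the same wall-clock span.
    muscle_map : sequence of str
        Muscle label of each EMG column.  Every muscle must contribute
        exactly 8 channels when monopolar and 7 when differential.
    channel_kind : {"monopolar", "differential"}
    angle_deg : float
        Elbow joint angle (60/90/120 in the protocol, arbitrary allowed).
    posture : {"neutral", "supinated"}
    """

    emg: np.ndarray
    fs_emg: float
    force: np.ndarray
    fs_force: float
    muscle_map: tuple[str, ...]
    channel_kind: str = "monopolar"
    angle_deg: float = 90.0
    posture: str = "neutral"
    subject_id: str = "S01"
    trial_id: str = "T1"

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.muscle_map = tuple(str(m) for m in self.muscle_map)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.emg.shape[0]

    @property
    def n_channels(self) -> int:
        return self.emg.shape[1]

    @property
    def muscles(self) -> tuple[str, ...]:
        """Muscle labels in order of first appearance."""
        seen: list[str] = []
        for m in self.muscle_map:
            if m not in seen:
                seen.append(m)
        return tuple(seen)

    def channels_of(self, muscle: str) -> np.ndarray:
        """Column indices of ``muscle`` in electrode (array) order."""
        return np.flatnonzero(np.asarray(self.muscle_map) == muscle)

    def validate(self) -> None:
        if self.emg.ndim != 2 or self.emg.shape[0] == 0 or self.emg.shape[1] == 0:
            raise SchemaError("emg must be a non-empty 2-D array (samples x channels)")
        if self.force.ndim != 1 or self.force.size < 2:
            raise SchemaError("force must be a 1-D array with at least 2 samples")
        if self.channel_kind not in ("monopolar", "differential"):
            raise SchemaError(f"unknown channel_kind {self.channel_kind!r}")
        if len(self.muscle_map) != self.n_channels:
            raise SchemaError("muscle_map length does not match channel count")
        if self.fs_emg <= 2 * 500.0:
            raise SchemaError("fs_emg must exceed twice the 500 Hz EMG bandwidth")
        per = MONOPOLAR_PER_MUSCLE if self.channel_kind == "monopolar" else DIFFERENTIAL_PER_MUSCLE
        for m in self.muscles:
            got = self.channels_of(m).size
            if got != per:
                raise SchemaError(
                    f"muscle {m!r} has {got} channels, expected {per} for "
                    f"{self.channel_kind} recordings")
        expected = self.n_samples * self.fs_force / self.fs_emg
        if abs(self.force.size - expected) > 1.5:
            raise SchemaError(
                f"force length {self.force.size} inconsistent with EMG length "
                f"{self.n_samples} (expected about {expected:.1f})")


@dataclass
class EnvelopeSet:
    """Pre-processed trial: normalized envelopes aligned with force.

    ``le`` holds the per-channel normalized linear envelopes (dimensionless,
    1.0 on average at the 50 %MVC reference plateau of the trial that
    supplied ``norm_ref``).  ``emg_filtered`` keeps the band-passed
    differential EMG the envelopes were computed from — the spectral channel
    scores operate on it.  ``force`` is the measured force up-sampled to the
    EMG rate and ``segments`` the extracted 3 s constant-force windows.
    """

    le: np.ndarray
    fs: float
    force: np.ndarray
    segments: list[Segment]
    norm_ref: np.ndarray
    muscle_map: tuple[str, ...]
    emg_filtered: np.ndarray
    angle_deg: float = 90.0
    posture: str = "neutral"
    subject_id: str = "S01"
    trial_id: str = "T1"

    def __post_init__(self) -> None:
        self.le = np.asarray(self.le, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.norm_ref = np.atleast_1d(np.asarray(self.norm_ref, dtype=float))
        self.muscle_map = tuple(str(m) for m in self.muscle_map)
        self.segments = [Segment(int(s[0]), int(s[1]), float(s[2])) for s in self.segments]
        if self.le.shape != self.emg_filtered.shape:
            raise SchemaError("le and emg_filtered must have identical shape")
        if self.force.shape[0] != self.le.shape[0]:
            raise SchemaError("force must be aligned with the envelopes")
        if np.any(self.le < -1e-12):
            raise SchemaError("linear envelopes must be nonnegative")

    @property
    def muscles(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in self.muscle_map:
            if m not in seen:
                seen.append(m)
        return tuple(seen)

    def channels_of(self, muscle: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.muscle_map) == muscle)

    def segment_samples(self, level: float | None = None) -> np.ndarray:
        """Concatenated sample indices of the plateau segments, in time order."""
        segs = sorted(self.segments, key=lambda s: s.start)
        if level is not None:
            segs = [s for s in segs if np.isclose(s.level, level)]
        if not segs:
            raise SchemaError(f"no segment at level {level!r}")
        return np.concatenate([np.arange(s.start, s.stop) for s in segs])


# ---------------------------------------------------------------------------
# Recording I/O
# ---------------------------------------------------------------------------

def _infer_format(path: os.PathLike | str, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "hdf5"):
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".h5", ".hdf5"):
        return "hdf5"
    raise FormatError(f"cannot infer format from suffix {suffix!r}")


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.force.csv"), Path(f"{stem}.meta.txt")


def write_recording(rec: Recording, path: os.PathLike | str, fmt: str | None = None) -> Path:
    """Serialize ``rec`` to ``path`` (CSV triplet or single HDF5 file)."""
    rec.validate()
    path = Path(path)
    fmt = _infer_format(path, fmt)
    meta = {
        "fs_emg": repr(float(rec.fs_emg)),
        "fs_force": repr(float(rec.fs_force)),
        "angle_deg": repr(float(rec.angle_deg)),
        "posture": rec.posture,
        "channel_kind": rec.channel_kind,
        "subject_id": rec.subject_id,
        "trial_id": rec.trial_id,
    }
    if fmt == "csv":
        local_idx: dict[str, int] = {}
        headers = []
        for m in rec.muscle_map:
            headers.append(f"{m}:{local_idx.get(m, 0)}")
            local_idx[m] = local_idx.get(m, 0) + 1
        np.savetxt(path, rec.emg, delimiter=",", fmt="%.17g",
                   header=",".join(headers), comments="")
        force_path, meta_path = _sidecar_paths(path)
        np.savetxt(force_path, rec.force, delimiter=",", fmt="%.17g",
                   header="force_N", comments="")
        meta_path.write_text("".join(f"{k}={v}\n" for k, v in meta.items()),
                             encoding="utf-8")
    else:
        with h5py.File(path, "w") as f:
            f.create_dataset("emg", data=rec.emg)
            f.create_dataset("force", data=rec.force)
            f.attrs["muscle_map"] = list(rec.muscle_map)
            for k, v in meta.items():
                f.attrs[k] = v
    return path


def read_recording(path: os.PathLike | str, fmt: str | None = None) -> Recording:
    """Load a :class:`Recording`; raises :class:`FormatError` on missing metadata."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        force_path, meta_path = _sidecar_paths(path)
        if not force_path.exists() or not meta_path.exists():
            raise FormatError(f"missing sidecar files for {path}")
        meta: dict[str, str] = {}
        for line in meta_path.read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if line and "=" in line:
                k, _, v = line.partition("=")
                meta[k.strip()] = v.strip()
        missing = [k for k in _META_KEYS if k not in meta]
        if missing:
            raise FormatError(f"metadata keys missing from {meta_path}: {missing}")
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().strip()
        if not header or ":" not in header:
            raise FormatError(f"{path} lacks a muscle:index header row")
        muscle_map = tuple(col.split(":")[0] for col in header.split(","))
        emg = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        force = np.loadtxt(force_path, delimiter=",", skiprows=1, ndmin=1)
    else:
        with h5py.File(path, "r") as f:
            if "emg" not in f or "force" not in f:
                raise FormatError(f"{path} lacks emg/force datasets")
            missing = [k for k in _META_KEYS if k not in f.attrs]
            if missing or "muscle_map" not in f.attrs:
                raise FormatError(f"metadata attributes missing from {path}: {missing}")
            emg = f["emg"][...]
            force = f["force"][...]
            muscle_map = tuple(str(m) for m in np.asarray(f.attrs["muscle_map"]).tolist())
            meta = {k: str(f.attrs[k]) for k in _META_KEYS}
    return Recording(
        emg=emg,
        fs_emg=float(meta["fs_emg"]),
        force=force,
        fs_force=float(meta["fs_force"]),
        muscle_map=muscle_map,
        channel_kind=meta["channel_kind"],
        angle_deg=float(meta["angle_deg"]),
        posture=meta["posture"],
        subject_id=meta["subject_id"],
        trial_id=meta["trial_id"],
    )


# ---------------------------------------------------------------------------
# EnvelopeSet I/O (HDF5 only; this is an intermediate pipeline artifact)
# ---------------------------------------------------------------------------

def write_envelopes(env: EnvelopeSet, path: os.PathLike | str) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("le", data=env.le)
        f.create_dataset("force", data=env.force)
        f.create_dataset("emg_filtered", data=env.emg_filtered)
        f.create_dataset("norm_ref", data=env.norm_ref)
        f.create_dataset("segments", data=np.array(
            [[s.start, s.stop, s.level] for s in env.segments], dtype=float))
        f.attrs["fs"] = float(env.fs)
        f.attrs["muscle_map"] = list(env.muscle_map)
        f.attrs["angle_deg"] = float(env.angle_deg)
        f.attrs["posture"] = env.posture
        f.attrs["subject_id"] = env.subject_id
        f.attrs["trial_id"] = env.trial_id
    return path


def read_envelopes(path: os.PathLike | str) -> EnvelopeSet:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        try:
            return EnvelopeSet(
                le=f["le"][...],
                fs=float(f.attrs["fs"]),
                force=f["force"][...],
                segments=[tuple(row) for row in f["segments"][...]],
                norm_ref=f["norm_ref"][...],
                muscle_map=tuple(str(m) for m in np.asarray(f.attrs["muscle_map"]).tolist()),
                emg_filtered=f["emg_filtered"][...],
                angle_deg=float(f.attrs["angle_deg"]),
                posture=str(f.attrs["posture"]),
                subject_id=str(f.attrs["subject_id"]),
                trial_id=str(f.attrs["trial_id"]),
            )
        except KeyError as exc:
            raise FormatError(f"{path} is not an envelope file: {exc}") from exc


__all__ = [
    "MUSCLES", "POSTURES", "MONOPOLAR_PER_MUSCLE", "DIFFERENTIAL_PER_MUSCLE",
    "Segment", "Recording", "EnvelopeSet",
    "read_recording", "write_recording", "read_envelopes", "write_envelopes",
]
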