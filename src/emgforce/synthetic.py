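"""Synthetic HD-sEMG + force cohort generator with planted ground truth.

The generator emulates the isometric elbow-flexion protocol used for
HD-array force estimation: per trial a force profile with three 5 s
plateaus at 20/35/50 %MVC in seeded-random order (1 s ramps, short rests),
force sampled at 1000 Hz, and three 8-channel monopolar arrays at 2048 Hz
(one per muscle).

EMG model, per muscle:

* a band-limited (10–500 Hz) Gaussian carrier per monopolar channel, mixed
  from latent sources — one *shared* source per muscle plus one *private*
  source per channel; the mixing row of channel ``i`` is
  ``sqrt(1-rho_i) * private_i + (-1)^i * sqrt(rho_i) * shared`` (unit norm).
  The sign of the shared weight alternates along the array so that
  neighbor differencing retains the shared component and the planted
  redundancy survives at the differential level;
* the carrier is amplitude-modulated by the envelope law
  ``A(t) = alpha * f(t) + beta * f(t)^2`` (``f`` = force as MVC fraction)
  and scaled by the channel gain;
* band-limited additive noise per channel.

The first ``n_informative + 1`` monopolar channels form the *informative
zone* (high gain, mostly private mixing, low noise), so the first
``n_informative`` differential channels are the planted informative set
{0, ..., n_informative-1}; the remaining channels form the *redundant
zone* (lower gain, mostly shared mixing, higher noise, and a per-trial
lognormal gain jitter emulating electrode-contact instability).

The carrier is amplitude-modulated noise, not a motor-unit action-potential
train: sufficient for exercising amplitude/correlation-based selection and
FOS, and documented as such.  All randomness flows from ``spec.seed``
through named independent substreams, so one spec + trial key reproduces a
trial bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.signal

from .io import MUSCLES, Recording, write_recording

# substream tags (mixed into the SeedSequence entropy)
_S_PROFILE, _S_CARRIER, _S_NOISE, _S_FORCE, _S_SUBJECT, _S_JITTER = range(1, 7)
_POSTURE_INDEX = {"neutral": 0, "supinated": 1}


@dataclass
class SyntheticSpec:
    """All generator parameters; the seed fully determines every output."""

    n_subjects: int = 2
    angles: tuple[float, ...] = (60.0, 90.0, 120.0)
    postures: tuple[str, ...] = ("neutral", "supinated")
    n_trials: int = 3

    levels: tuple[float, ...] = (0.20, 0.35, 0.50)
    plateau_s: float = 5.0
    ramp_s: float = 1.0
    rest_s: float = 0.5
    fs_emg: float = 2048.0
    fs_force: float = 1000.0

    n_informative: int = 3
    gain_informative: float = 1.0
    gain_redundant: float = 0.5
    shared_frac_informative: float = 0.1
    shared_frac_redundant: float = 0.9
    noise_sd_informative: float = 0.025
    noise_sd_redundant: float = 0.12
    gain_jitter_redundant: float = 0.2

    alpha: float | tuple[float, ...] = 1.0
    beta: float | tuple[float, ...] = 0.25

    mvc_newtons: float = 250.0
    mvc_subject_sd: float = 25.0
    force_noise_sd: float = 0.3

    #: optional explicit per-muscle monopolar gains, e.g. {"biceps_long": (...8)}
    monopolar_gains: Mapping[str, Sequence[float]] | None = None

    seed: int = 0

    def validate(self) -> None:
        if not 1 <= self.n_informative <= 6:
            raise ValueError("n_informative must be in 1..6")
        if min(self.gain_informative, self.gain_redundant) < 0:
            raise ValueError("gains must be nonnegative")
        if min(self.noise_sd_informative, self.noise_sd_redundant,
               self.force_noise_sd) < 0:
            raise ValueError("noise SDs must be nonnegative")
        for frac in (self.shared_frac_informative, self.shared_frac_redundant):
            if not 0 <= frac <= 1:
                raise ValueError("shared fractions must lie in [0, 1]")
        if len(self.levels) < 1 or min(self.levels) <= 0 or max(self.levels) > 1:
            raise ValueError("levels must be MVC fractions in (0, 1]")

    def per_muscle(self, value: float | tuple[float, ...]) -> np.ndarray:
        arr = np.atleast_1d(np.asarray(value, dtype=float))
        if arr.size == 1:
            arr = np.repeat(arr, len(MUSCLES))
        if arr.size != len(MUSCLES):
            raise ValueError("per-muscle parameter needs 1 or 3 values")
        return arr

    @property
    def duration_s(self) -> float:
        return (2 * self.rest_s + len(self.levels) * (self.ramp_s + self.plateau_s)
                + self.ramp_s)


def _rng(spec: SyntheticSpec, *keys: int) -> np.random.Generator:
    entropy = [int(spec.seed) & 0x7FFFFFFF] + [int(k) & 0x7FFFFFFF for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _trial_key(subject: int, angle: float, posture: str, trial_idx: int) -> tuple:
    return (int(subject), int(round(angle)), _POSTURE_INDEX[posture], int(trial_idx))


def force_fraction(spec: SyntheticSpec, order: Sequence[int],
                   t: np.ndarray) -> np.ndarray:
    """Piecewise-linear MVC-fraction profile for one plateau ordering."""
    times = [0.0, spec.rest_s]
    values = [0.0, 0.0]
    tcur = spec.rest_s
    for li in order:
        level = spec.levels[li]
        times += [tcur + spec.ramp_s, tcur + spec.ramp_s + spec.plateau_s]
        values += [level, level]
        tcur = times[-1]
    times += [tcur + spec.ramp_s, tcur + spec.ramp_s + spec.rest_s]
    values += [0.0, 0.0]
    return np.interp(t, times, values)


def _bandlimited(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to 10–500 Hz.

    Uses a steeper (8th-order, zero-phase) Butterworth than the analysis
    filter so that the generated content is band-limited well beyond the
    transition skirts of the pipeline's own 4th-order filter.
    """
    sos = scipy.signal.butter(8, [10.0, 500.0], btype="bandpass", fs=fs,
                              output="sos")
    x = scipy.signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_trial(spec: SyntheticSpec, subject: int, angle: float,
                   posture: str, trial_idx: int) -> Recording:
    """One monopolar 3-array trial for the given condition and trial index."""
    spec.validate()
    key = _trial_key(subject, angle, posture, trial_idx)
    n_emg = round(spec.duration_s * spec.fs_emg)
    n_force = round(spec.duration_s * spec.fs_force)
    t_emg = np.arange(n_emg) / spec.fs_emg
    t_force = np.arange(n_force) / spec.fs_force

    order = _rng(spec, *key, _S_PROFILE).permutation(len(spec.levels))
    mvc = spec.mvc_newtons + spec.mvc_subject_sd * _rng(
        spec, subject, _S_SUBJECT).standard_normal()
    f_emg = force_fraction(spec, order, t_emg)
    force = mvc * force_fraction(spec, order, t_force)
    if spec.force_noise_sd > 0:
        force = force + spec.force_noise_sd * _rng(
            spec, *key, _S_FORCE).standard_normal(n_force)

    alphas = spec.per_muscle(spec.alpha)
    betas = spec.per_muscle(spec.beta)
    rng_car = _rng(spec, *key, _S_CARRIER)
    rng_noise = _rng(spec, *key, _S_NOISE)
    rng_jit = _rng(spec, *key, _S_JITTER)

    n_mono = 8
    inf_zone = spec.n_informative + 1  # monopolar channels 0..n_informative
    blocks: list[np.ndarray] = []
    muscle_map: list[str] = []
    for mi, muscle in enumerate(MUSCLES):
        envelope = alphas[mi] * f_emg + betas[mi] * f_emg ** 2
        shared = _bandlimited(rng_car, n_emg, spec.fs_emg)
        block = np.empty((n_emg, n_mono))
        for i in range(n_mono):
            informative = i < inf_zone
            rho = (spec.shared_frac_informative if informative
                   else spec.shared_frac_redundant)
            gain = (spec.gain_informative if informative
                    else spec.gain_redundant)
            if spec.monopolar_gains is not None and muscle in spec.monopolar_gains:
                gain = float(spec.monopolar_gains[muscle][i])
            if not informative and spec.gain_jitter_redundant > 0:
                gain *= float(np.exp(spec.gain_jitter_redundant
                                     * rng_jit.standard_normal()))
            private = _bandlimited(rng_car, n_emg, spec.fs_emg)
            carrier = (np.sqrt(1.0 - rho) * private
                       + (-1.0) ** i * np.sqrt(rho) * shared)
            noise_sd = (spec.noise_sd_informative if informative
                        else spec.noise_sd_redundant)
            col = gain * envelope * carrier
            if noise_sd > 0:
                col = col + noise_sd * _bandlimited(rng_noise, n_emg, spec.fs_emg)
            block[:, i] = col
        blocks.append(block)
        muscle_map.extend([muscle] * n_mono)

    return Recording(
        emg=np.hstack(blocks), fs_emg=spec.fs_emg, force=force,
        fs_force=spec.fs_force, muscle_map=tuple(muscle_map),
        channel_kind="monopolar", angle_deg=float(angle), posture=posture,
        subject_id=f"S{subject:02d}", trial_id=f"T{trial_idx}")


def generate_cohort(spec: SyntheticSpec, outdir: str | Path | None = None,
                    fmt: str = "hdf5") -> dict[tuple, list[Recording]]:
    """Full factorial cohort: n_trials x angles x postures x subjects.

    Returns the trials grouped by condition; when ``outdir`` is given every
    recording is also written there (one file per trial).
    """
    spec.validate()
    ext = ".h5" if fmt == "hdf5" else ".csv"
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    cohort: dict[tuple, list[Recording]] = {}
    for subject in range(1, spec.n_subjects + 1):
        for angle in spec.angles:
            for posture in spec.postures:
                trials = [generate_trial(spec, subject, angle, posture, j)
                          for j in range(1, spec.n_trials + 1)]
                cohort[(f"S{subject:02d}", float(angle), posture)] = trials
                if outdir is not None:
                    for j, rec in enumerate(trials, start=1):
                        name = (f"sub{subject:02d}_ang{int(round(angle)):03d}"
                                f"_{posture}_t{j}{ext}")
                        write_recording(rec, outdir / name, fmt)
    return cohort


__all__ = ["SyntheticSpec", "force_fraction", "generate_trial", "generate_cohort"]
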