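"""Pre-processing: differential derivation, filtering, envelopes, plateaus.

The pipeline mirrors standard HD-sEMG practice for isometric force
estimation:

1. subtract neighboring monopolar channels (8 -> 7 differential per array);
2. band-pass each differential channel 10–500 Hz with a 4th-order
   Butterworth filter, applied forward–backward (zero phase — the analysis
   is offline and phase is irrelevant downstream, at the cost of the
   magnitude response being squared);
3. full-wave rectify and smooth with a 300-point (~147 ms at 2048 Hz)
   centered moving average to obtain the linear envelope (LE);
4. normalize each channel's LE by its mean over the 50 %MVC plateau of the
   reference (training) trial;
5. up-sample the 1000 Hz force channel to the EMG rate by linear
   interpolation;
6. locate the three constant-force plateaus and extract the centered 3 s of
   each.

Edge samples of the moving average use the truncated window; envelopes are
only consumed inside plateau segments, which never touch the edges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import scipy.signal

from .errors import DegenerateChannelError, SchemaError, SegmentationError
from .io import EnvelopeSet, MONOPOLAR_PER_MUSCLE, Recording, Segment


@dataclass
class PreprocessConfig:
    """Tunables for the pre-processing pipeline (defaults match the protocol)."""

    low_hz: float = 10.0
    high_hz: float = 500.0
    order: int = 4
    envelope_window: int = 300
    plateau_levels: tuple[float, ...] = (0.20, 0.35, 0.50)
    extract_duration_s: float = 3.0
    std_window_s: float = 0.5
    std_frac: float = 0.02
    norm_level: float = 0.50


def differentiate(rec: Recording) -> Recording:
    """Neighbor-difference derivation: 8 monopolar -> 7 differential per muscle.

    Output channel ``i`` of a muscle is ``monopolar[i+1] - monopolar[i]``.
    """
    if rec.channel_kind != "monopolar":
        raise SchemaError("differentiate expects a monopolar recording")
    cols: list[np.ndarray] = []
    muscle_map: list[str] = []
    for m in rec.muscles:
        idx = rec.channels_of(m)
        if idx.size != MONOPOLAR_PER_MUSCLE:
            raise SchemaError(f"muscle {m!r} must have 8 monopolar channels")
        block = rec.emg[:, idx]
        cols.append(block[:, 1:] - block[:, :-1])
        muscle_map.extend([m] * (MONOPOLAR_PER_MUSCLE - 1))
    return replace(rec, emg=np.hstack(cols), muscle_map=tuple(muscle_map),
                   channel_kind="differential")


def bandpass(x: np.ndarray, fs: float, low: float = 10.0, high: float = 500.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along axis 0."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("bandpass input contains non-finite samples")
    if fs <= 2 * high:
        raise ValueError(f"fs={fs} too low for a {high} Hz upper cut-off")
    if x.shape[0] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return scipy.signal.sosfiltfilt(sos, x, axis=0)


def linear_envelope(x: np.ndarray, window: int = 300) -> np.ndarray:
    """Full-wave rectification + centered moving average along axis 0.

    Edge samples average over the part of the window inside the signal, so
    the output has the same length as the input.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window ({window}) exceeds signal length ({n})")
    a = np.abs(x)
    csum = np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(a, axis=0)], axis=0)
    half_l = (window - 1) // 2
    half_r = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, n)
    counts = (hi - lo).astype(float)
    if x.ndim > 1:
        counts = counts[:, None]
    return (csum[hi] - csum[lo]) / counts


def compute_norm_ref(le: np.ndarray, segments: list[Segment],
                     level: float = 0.50) -> np.ndarray:
    """Per-channel mean of the LE pooled over all segments at ``level``."""
    segs = [s for s in segments if np.isclose(s.level, level)]
    if not segs:
        raise SegmentationError(f"no plateau segment at level {level}")
    idx = np.concatenate([np.arange(s.start, s.stop) for s in segs])
    le = np.asarray(le, dtype=float)
    return np.atleast_1d(le[idx].mean(axis=0))


def normalize_envelope(le: np.ndarray, ref: float | np.ndarray) -> np.ndarray:
    """Divide each channel's LE by its (positive) reference amplitude."""
    ref = np.atleast_1d(np.asarray(ref, dtype=float))
    if np.any(ref <= 0):
        raise DegenerateChannelError("normalization reference must be > 0")
    le = np.asarray(le, dtype=float)
    return le / (ref if le.ndim > 1 else ref.item() if ref.size == 1 else ref)


def upsample_force(force: np.ndarray, fs_in: float, fs_out: float,
                   n_out: int | None = None) -> np.ndarray:
    """Linear-interpolation resampling of the force channel.

    Values at the original sample times are preserved exactly; queries past
    the last input sample clamp to it.
    """
    force = np.asarray(force, dtype=float)
    if force.size < 2:
        raise ValueError("need at least 2 force samples to interpolate")
    if fs_out < fs_in:
        raise ValueError("upsample_force expects fs_out >= fs_in")
    if n_out is None:
        n_out = round(force.size * fs_out / fs_in)
    t_in = np.arange(force.size) / fs_in
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_in, force)


def _rolling_mean_std(x: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    s1 = c1[w:] - c1[:-w]
    s2 = c2[w:] - c2[:-w]
    mean = s1 / w
    var = np.maximum(s2 / w - mean * mean, 0.0)
    return mean, np.sqrt(var)


def extract_plateaus(force: np.ndarray, fs: float,
                     cfg: PreprocessConfig | None = None) -> list[Segment]:
    """Locate constant-force plateaus and return the centered 3 s of each.

    A sliding-window standard deviation below ``std_frac`` of the local mean
    marks flat regions; flat runs long enough to contain the extraction
    window and with a mean above 10 % of the trace maximum are plateau
    candidates.  Levels are assigned by scaling the largest plateau mean to
    the largest nominal level (MVC estimate) and matching the nearest level;
    the assignment must use each nominal level exactly once.
    """
    cfg = cfg or PreprocessConfig()
    force = np.asarray(force, dtype=float)
    n_ex = round(cfg.extract_duration_s * fs)
    w = max(2, round(cfg.std_window_s * fs))
    if force.size < n_ex + w:
        raise SegmentationError("force trace too short for plateau extraction")
    fmax = float(force.max(initial=0.0))
    if fmax <= 0:
        raise SegmentationError("force trace is non-positive everywhere")
    mean, std = _rolling_mean_std(force, w)
    flat = std <= cfg.std_frac * np.maximum(mean, 0.05 * fmax)

    # contiguous flat runs, converted from window-start coords to sample spans
    runs: list[tuple[int, int]] = []
    i = 0
    while i < flat.size:
        if flat[i]:
            j = i
            while j < flat.size and flat[j]:
                j += 1
            start, stop = i, j - 1 + w  # samples covered by flat windows
            if stop - start >= n_ex and force[start:stop].mean() >= 0.1 * fmax:
                runs.append((start, stop))
            i = j
        else:
            i += 1
    levels = sorted(cfg.plateau_levels)
    if len(runs) != len(levels):
        raise SegmentationError(
            f"found {len(runs)} plateau(s), expected {len(levels)}")

    means = [force[a:b].mean() for a, b in runs]
    mvc = max(means) / max(levels)
    assigned = [min(levels, key=lambda lv: abs(m / mvc - lv)) for m in means]
    if sorted(assigned) != levels:
        raise SegmentationError(
            f"plateau means {means} do not match nominal levels {levels}")

    segments: list[Segment] = []
    for (a, b), lv in zip(runs, assigned):
        center = (a + b) // 2
        start = center - n_ex // 2
        segments.append(Segment(start, start + n_ex, lv))
    segments.sort(key=lambda s: s.start)
    for s, t in zip(segments, segments[1:]):
        if s.stop > t.start:
            raise SegmentationError("extracted segments overlap")
    return segments


def preprocess_recording(rec: Recording, cfg: PreprocessConfig | None = None,
                         norm_ref: np.ndarray | None = None) -> EnvelopeSet:
    """Run the full pipeline on one trial.

    ``norm_ref`` carries the per-channel normalization reference of the
    training trial; when omitted it is computed from this trial's own
    50 %MVC plateau (i.e. this trial acts as the reference).
    """
    cfg = cfg or PreprocessConfig()
    rec_d = differentiate(rec) if rec.channel_kind == "monopolar" else rec
    filt = bandpass(rec_d.emg, rec_d.fs_emg, cfg.low_hz, cfg.high_hz, cfg.order)
    le = linear_envelope(filt, cfg.envelope_window)
    force_up = upsample_force(rec.force, rec.fs_force, rec.fs_emg,
                              n_out=rec_d.n_samples)
    segments = extract_plateaus(force_up, rec_d.fs_emg, cfg)
    if norm_ref is None:
        norm_ref = compute_norm_ref(le, segments, cfg.norm_level)
    le_n = normalize_envelope(le, norm_ref)
    return EnvelopeSet(
        le=le_n, fs=rec_d.fs_emg, force=force_up, segments=segments,
        norm_ref=np.atleast_1d(norm_ref), muscle_map=rec_d.muscle_map,
        emg_filtered=filt, angle_deg=rec.angle_deg, posture=rec.posture,
        subject_id=rec.subject_id, trial_id=rec.trial_id)


__all__ = [
    "PreprocessConfig", "differentiate", "bandpass", "linear_envelope",
    "compute_norm_ref", "normalize_envelope", "upsample_force",
    "extract_plateaus", "preprocess_recording",
]
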