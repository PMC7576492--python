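"""Shared fixtures: small randomized recordings and one synthetic trial."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from emgforce import EnvelopeSet, Recording, Segment, preprocess_recording
from emgforce.io import MUSCLES
from emgforce.synthetic import SyntheticSpec, generate_trial

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture])
settings.load_profile("suite")


@pytest.fixture
def make_recording():
    """Factory for small random (but valid) monopolar recordings."""

    def _make(seed: int = 0, n_emg: int = 4096, fs_emg: float = 2048.0,
              fs_force: float = 1000.0, channel_kind: str = "monopolar"):
        rng = np.random.default_rng(seed)
        per = 8 if channel_kind == "monopolar" else 7
        emg = rng.standard_normal((n_emg, per * len(MUSCLES))) * 1e-4
        n_force = round(n_emg * fs_force / fs_emg)
        force = 50.0 + 5.0 * rng.standard_normal(n_force)
        muscle_map = tuple(m for m in MUSCLES for _ in range(per))
        return Recording(emg=emg, fs_emg=fs_emg, force=force, fs_force=fs_force,
                         muscle_map=muscle_map, channel_kind=channel_kind,
                         angle_deg=90.0, posture="neutral",
                         subject_id="S01", trial_id=f"T{seed}")

    return _make


@pytest.fixture
def make_env():
    """Factory for hand-built EnvelopeSets (selection unit tests).

    ``emg`` supplies the band-passed differential signals; the envelopes
    default to ``|emg|`` smoothed trivially (abs), which keeps them
    nonnegative without invoking the pipeline.
    """

    def _make(emg: np.ndarray, le: np.ndarray | None = None,
              muscle_map=None, fs: float = 2048.0, angle_deg: float = 90.0):
        emg = np.asarray(emg, dtype=float)
        n, n_ch = emg.shape
        if muscle_map is None:
            if n_ch % 7:
                raise ValueError("default muscle_map needs a multiple of 7 channels")
            muscle_map = tuple(m for m in MUSCLES[: n_ch // 7] for _ in range(7))
        le = np.abs(emg) if le is None else np.asarray(le, dtype=float)
        return EnvelopeSet(
            le=le, fs=fs, force=np.full(n, 60.0),
            segments=[Segment(0, n, 0.50)], norm_ref=np.ones(n_ch),
            muscle_map=muscle_map, emg_filtered=emg, angle_deg=angle_deg)

    return _make


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def trial(default_spec):
    """One default-condition synthetic trial (monopolar, 24 channels)."""
    return generate_trial(default_spec, 1, 90.0, "neutral", 1)


@pytest.fixture(scope="session")
def env(trial):
    """The session trial pre-processed with default settings."""
    return preprocess_recording(trial)


@pytest.fixture(scope="session")
def mini_cohort(default_spec):
    """Three trials of a single condition (train + two test)."""
    return [generate_trial(default_spec, 1, 60.0, "supinated", j) for j in (1, 2, 3)]
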