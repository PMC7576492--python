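"""HD-EMG channel selection: power-correlation ratio and PCA loadings.

Three redundancy-aware selectors rank the 7 differential channels of each
muscle and keep the top ``k``:

* **PCR** — the power-correlation ratio.  Per muscle, each channel's band
  power (10–500 Hz, Welch estimate) is normalized by the per-muscle maximum
  (``norm_power``, max = 1); its redundancy is the mean absolute Pearson
  correlation with the other channels of the muscle (``mean_abs_corr``).
  ``PCR = norm_power / mean_abs_corr`` favours channels that carry much
  spectral power while sharing little information with their neighbours.
* **PCA (time domain)** — PCA on the covariance of the per-muscle linear
  envelopes over time; channels are ranked by their absolute loading on the
  retained principal components.
* **PCA (frequency domain)** — PCA on the FFT magnitude spectra (phase
  discarded) of all 21 differential channels jointly, observations being
  frequency bins; channels are then ranked per muscle.

With ``n_pcs > 1`` the rank score is a variance-weighted vote
``score_c = sum_i evf_i * |loading_{i,c}|`` over the first ``n_pcs``
components, which reduces to ``|loading on PC1|`` for ``n_pcs = 1``.
Ties are broken deterministically by the lower channel index.

Scores are computed on the band-passed differential EMG (correlations on
envelopes would be inflated by smoothing), concatenated over the trial's
extracted constant-force plateaus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
from sklearn.decomposition import PCA

from .errors import DegenerateChannelError, SchemaError, UndefinedCorrelationError
from .io import DIFFERENTIAL_PER_MUSCLE, EnvelopeSet


# ---------------------------------------------------------------------------
# score primitives
# ---------------------------------------------------------------------------

def band_power(x: np.ndarray, fs: float, low: float = 10.0, high: float = 500.0,
               nperseg: int = 1024) -> float:
    """Total signal power in [low, high] Hz from a Welch-averaged periodogram.

    Hann window, 50 % overlap, 1024-sample segments (or the full signal if
    shorter).  The PSD is integrated over the band with the trapezoidal
    rule, so for a sinusoid inside the band the result approximates half
    the squared amplitude and for broadband noise the sample variance.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("band_power expects a single channel")
    nper = min(nperseg, x.size)
    f, psd = scipy.signal.welch(x, fs=fs, window="hann", nperseg=nper)
    mask = (f >= low) & (f <= high)
    if mask.sum() < 2:
        raise ValueError("band contains fewer than 2 PSD bins")
    return float(np.trapezoid(psd[mask], f[mask]))


def normalized_power(powers: np.ndarray) -> np.ndarray:
    """Divide per-channel band powers by the per-muscle maximum (max -> 1)."""
    powers = np.asarray(powers, dtype=float)
    if powers.size == 0:
        raise ValueError("empty power vector")
    top = powers.max()
    if top <= 0:
        raise DegenerateChannelError("all channels of the muscle have zero power")
    return powers / top


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length signals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson_r expects two equal-length 1-D signals, n >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float((xc @ yc) / denom)


def _abs_corr_matrix(signals: np.ndarray) -> np.ndarray:
    """|r| matrix of the columns of ``signals`` (observations x channels)."""
    stds = signals.std(axis=0)
    if np.any(stds == 0):
        raise UndefinedCorrelationError(
            f"zero-variance channel(s) {np.flatnonzero(stds == 0).tolist()}")
    return np.abs(np.corrcoef(signals, rowvar=False))


def mean_abs_corr(channel: int, signals: np.ndarray) -> float:
    """Mean |Pearson r| of one channel against the other channels of the muscle."""
    signals = np.asarray(signals, dtype=float)
    n_ch = signals.shape[1]
    if n_ch < 2:
        raise ValueError("need at least 2 channels")
    r = _abs_corr_matrix(signals)
    return float((r[channel].sum() - r[channel, channel]) / (n_ch - 1))


def pcr_scores(signals: np.ndarray, fs: float, muscle: str = "") -> pd.DataFrame:
    """Per-channel score table for one muscle.

    ``signals`` holds the band-passed differential EMG of the muscle's
    channels in columns.  A channel that is perfectly uncorrelated with all
    others (``mean_abs_corr = 0``) gets ``PCR = +inf`` — zero redundancy is
    the index's ideal — and therefore ranks first.
    """
    signals = np.asarray(signals, dtype=float)
    n_ch = signals.shape[1]
    powers = np.array([band_power(signals[:, c], fs) for c in range(n_ch)])
    norm_pow = normalized_power(powers)
    r = _abs_corr_matrix(signals)
    m = (r.sum(axis=1) - np.diag(r)) / (n_ch - 1)
    # a mean |r| at rounding-error level counts as exactly uncorrelated
    m = np.where(m < 1e-12, 0.0, m)
    with np.errstate(divide="ignore"):
        pcr = np.where(m > 0, norm_pow / np.where(m > 0, m, 1.0), np.inf)
    return pd.DataFrame({
        "muscle": muscle, "channel": np.arange(n_ch), "power": powers,
        "norm_power": norm_pow, "mean_abs_corr": m, "pcr": pcr,
    })


def pca_loadings(data: np.ndarray, n_pcs: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Principal-axis loadings of mean-centered (not standardized) columns.

    Returns ``(loadings, explained_variance_frac)`` where ``loadings`` has
    one unit-norm row per retained component, ordered by descending
    eigenvalue of the channel covariance, and the variance fractions are
    relative to the total variance.
    """
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("pca_loadings requires finite data")
    n_pcs = int(n_pcs)
    if not 1 <= n_pcs <= data.shape[1]:
        raise ValueError("n_pcs out of range")
    p = PCA(n_components=n_pcs, svd_solver="full").fit(data)
    return p.components_.copy(), p.explained_variance_ratio_.copy()


# ---------------------------------------------------------------------------
# selection results
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of one channel-selection method on one trial.

    ``selected`` maps each muscle to its top-``k`` within-muscle channel
    indices ordered by descending score; ``ranking`` keeps the full ordering
    so selections for k and k+1 are nested by construction.
    """

    method: str
    k: int
    selected: dict[str, list[int]]
    ranking: dict[str, list[int]]
    score_table: pd.DataFrame
    n_pcs: int | None = None

    def __post_init__(self) -> None:
        for m, chans in self.selected.items():
            if len(chans) != self.k or len(set(chans)) != self.k:
                raise SchemaError(f"selection for {m!r} must have k={self.k} distinct channels")

    def channel_labels(self) -> list[tuple[str, int]]:
        """(muscle, local index) pairs of all selected channels, muscle-major."""
        return [(m, c) for m in self.selected for c in sorted(self.selected[m])]

    def global_indices(self, env: EnvelopeSet) -> np.ndarray:
        """Column indices of the selected channels in ``env`` (muscle-major)."""
        out = []
        for m, c in self.channel_labels():
            out.append(int(env.channels_of(m)[c]))
        return np.array(out, dtype=int)

    # -- JSON serialization ------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "method": self.method, "k": self.k, "n_pcs": self.n_pcs,
            "selected": {m: [int(c) for c in v] for m, v in self.selected.items()},
            "ranking": {m: [int(c) for c in v] for m, v in self.ranking.items()},
            "score_table": self.score_table.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "SelectionResult":
        p = Path(text_or_path)
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(method=d["method"], k=d["k"],
                   selected={m: list(v) for m, v in d["selected"].items()},
                   ranking={m: list(v) for m, v in d["ranking"].items()},
                   score_table=pd.DataFrame(d["score_table"]), n_pcs=d.get("n_pcs"))


def _rank_descending(scores: np.ndarray) -> list[int]:
    """Indices sorted by descending score, ties to the lowest index."""
    scores = np.asarray(scores, dtype=float)
    order = np.lexsort((np.arange(scores.size), -scores))
    return [int(i) for i in order]


def _check_k(k: int, n_ch: int) -> None:
    if not 1 <= k <= n_ch:
        raise ValueError(f"k={k} out of range for {n_ch} channels per muscle")


def _vote_scores(data: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    loadings, evf = pca_loadings(data, n_pcs)
    return evf @ np.abs(loadings), loadings, evf


def select_pcr(env: EnvelopeSet, k: int, fs: float | None = None) -> SelectionResult:
    """Top-``k`` channels per muscle by descending power-correlation ratio."""
    fs = fs or env.fs
    idx = env.segment_samples()
    tables, selected, ranking = [], {}, {}
    for m in env.muscles:
        cols = env.channels_of(m)
        _check_k(k, cols.size)
        tab = pcr_scores(env.emg_filtered[np.ix_(idx, cols)], fs, muscle=m)
        order = _rank_descending(tab["pcr"].to_numpy())
        ranking[m] = order
        selected[m] = order[:k]
        tables.append(tab)
    return SelectionResult("pcr", k, selected, ranking, pd.concat(tables, ignore_index=True))


def select_pca_time(env: EnvelopeSet, k: int, n_pcs: int = 1) -> SelectionResult:
    """Per-muscle PCA of the linear envelopes over time; rank by loading vote."""
    idx = env.segment_samples()
    tables, selected, ranking = [], {}, {}
    for m in env.muscles:
        cols = env.channels_of(m)
        _check_k(k, cols.size)
        scores, loadings, evf = _vote_scores(env.le[np.ix_(idx, cols)], n_pcs)
        order = _rank_descending(scores)
        ranking[m] = order
        selected[m] = order[:k]
        tab = pd.DataFrame({"muscle": m, "channel": np.arange(cols.size),
                            "score": scores})
        for i in range(n_pcs):
            tab[f"loading_pc{i + 1}"] = loadings[i]
            tab[f"evf_pc{i + 1}"] = evf[i]
        tables.append(tab)
    return SelectionResult("pca_time", k, selected, ranking,
                           pd.concat(tables, ignore_index=True), n_pcs=n_pcs)


def select_pca_freq(env: EnvelopeSet, k: int, n_pcs: int = 1,
                    fs: float | None = None) -> SelectionResult:
    """Joint PCA of all channels' FFT magnitude spectra; rank per muscle.

    The magnitude spectrum of each band-passed differential channel over the
    concatenated plateaus is computed (phase discarded), restricted to the
    10–500 Hz band, and PCA is applied to all channels jointly with
    frequency bins as observations.
    """
    fs = fs or env.fs
    idx = env.segment_samples()
    x = env.emg_filtered[idx]
    freqs = np.fft.rfftfreq(x.shape[0], d=1.0 / fs)
    band = (freqs >= 10.0) & (freqs <= 500.0)
    spectra = np.abs(np.fft.rfft(x, axis=0))[band]
    scores_all, loadings, evf = _vote_scores(spectra, n_pcs)
    tables, selected, ranking = [], {}, {}
    for m in env.muscles:
        cols = env.channels_of(m)
        _check_k(k, cols.size)
        scores = scores_all[cols]
        order = _rank_descending(scores)
        ranking[m] = order
        selected[m] = order[:k]
        tab = pd.DataFrame({"muscle": m, "channel": np.arange(cols.size),
                            "score": scores})
        for i in range(n_pcs):
            tab[f"loading_pc{i + 1}"] = loadings[i, cols]
            tab[f"evf_pc{i + 1}"] = evf[i]
        tables.append(tab)
    return SelectionResult("pca_freq", k, selected, ranking,
                           pd.concat(tables, ignore_index=True), n_pcs=n_pcs)


_METHODS = {"pcr": select_pcr, "pca_time": select_pca_time, "pca_freq": select_pca_freq}


def select_channels(env: EnvelopeSet, method: str, k: int,
                    n_pcs: int = 1) -> SelectionResult:
    """Dispatch to one of the selection methods by name."""
    name = method.replace("-", "_")
    if name not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    if name == "pcr":
        return select_pcr(env, k)
    return _METHODS[name](env, k, n_pcs=n_pcs)


def dimensionality_reduction_pct(k: int, total: int = DIFFERENTIAL_PER_MUSCLE) -> float:
    """Percentage reduction in channel count when keeping k of ``total``."""
    if not 1 <= k <= total:
        raise ValueError("k out of range")
    return 100.0 * (1.0 - k / total)


__all__ = [
    "band_power", "normalized_power", "pearson_r", "mean_abs_corr",
    "pcr_scores", "pca_loadings", "SelectionResult", "select_pcr",
    "select_pca_time", "select_pca_freq", "select_channels",
    "dimensionality_reduction_pct",
]
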