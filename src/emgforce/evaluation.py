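"""Evaluation: %NMSE metric and the subject-specific train/test protocol.

Force-estimation accuracy is the normalized mean squared error in percent,

    %NMSE = 100 * sum (F_meas - F_est)^2 / sum F_meas^2,

computed over the concatenated extracted plateau segments of a test trial.
The protocol is subject- and condition-specific: for each (subject, elbow
angle, forearm posture) the first trial trains everything — normalization
references, channel selection, and the FOS model — and the next two trials
are scored with those frozen choices; their errors are averaged.
Condition-level aggregates report the mean and the standard error
(sample SD across subjects / sqrt(n_subjects)).
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import EmgForceError, SchemaError
from .fos import BasisConfig, fos_fit, pool_from_envelopes
from .io import Recording, read_recording
from .preprocess import PreprocessConfig, preprocess_recording
from .selection import SelectionResult, select_channels


def nmse(measured: np.ndarray, estimated: np.ndarray) -> float:
    """Percent normalized mean squared error between two force signals."""
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape or measured.ndim != 1:
        raise ValueError("nmse expects two equal-length 1-D signals")
    denom = float(measured @ measured)
    if denom == 0:
        raise EmgForceError("undefined %NMSE: measured force is identically zero")
    diff = measured - estimated
    return 100.0 * float(diff @ diff) / denom


def run_protocol(trials: Sequence[Recording], method: str = "all", k: int = 7,
                 n_pcs: int = 1, pre_cfg: PreprocessConfig | None = None,
                 basis_cfg: BasisConfig | None = None,
                 max_terms: int = 9) -> dict:
    """Train on the first trial, test on the next two; return one record.

    ``method`` is one of ``all`` (no selection, every channel) or
    ``pcr`` / ``pca_time`` / ``pca_freq`` with ``k`` channels per muscle.
    """
    if len(trials) < 3:
        raise SchemaError("protocol needs at least 3 trials per condition")
    train, tests = trials[0], trials[1:3]
    for t in tests:
        if (t.subject_id != train.subject_id or t.posture != train.posture
                or t.angle_deg != train.angle_deg):
            raise SchemaError("trials of one protocol run must share the condition")

    env_train = preprocess_recording(train, pre_cfg)
    selection: SelectionResult | None = None
    if method not in ("all", "full"):
        selection = select_channels(env_train, method, k, n_pcs=n_pcs)
    pool_train, y_train = pool_from_envelopes(env_train, selection, basis_cfg)
    res = fos_fit(pool_train, y_train, max_terms=max_terms)

    per_trial: list[float] = []
    for t in tests:
        env_t = preprocess_recording(t, pre_cfg, norm_ref=env_train.norm_ref)
        pool_t, y_t = pool_from_envelopes(env_t, selection, basis_cfg)
        per_trial.append(nmse(y_t, res.predict(pool_t)))

    return {
        "subject": train.subject_id,
        "angle": float(train.angle_deg),
        "posture": train.posture,
        "method": method,
        "k": k if method not in ("all", "full") else pool_train_k(env_train),
        "n_pcs": n_pcs if method.startswith("pca") else None,
        "nmse_pct": float(np.mean(per_trial)),
        "nmse_per_trial": per_trial,
        "training_mse": res.training_mse,
        "n_terms": res.n_terms,
    }


def pool_train_k(env) -> int:
    """Channels per muscle when no selection is applied."""
    return int(env.channels_of(env.muscles[0]).size)


def standard_error(values: np.ndarray) -> float:
    """Sample SD / sqrt(n); NaN for fewer than two values."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / np.sqrt(values.size))


@dataclass
class EvaluationReport:
    """Per-run %NMSE table with condition-level and grand aggregates."""

    table: pd.DataFrame

    def by_condition(self) -> pd.DataFrame:
        """Mean and SE across subjects for each (angle, posture, method, k)."""
        grouped = self.table.groupby(["method", "k", "angle", "posture"])["nmse_pct"]
        out = grouped.agg(mean="mean", se=standard_error, n_subjects="count")
        return out.reset_index()

    def grand_means(self) -> pd.DataFrame:
        """Mean of the condition means for each (method, k)."""
        cond = self.by_condition()
        out = cond.groupby(["method", "k"])["mean"].mean().rename("grand_mean_nmse_pct")
        return out.reset_index()

    def summary(self) -> str:
        cond = self.by_condition()
        grand = self.grand_means()
        return ("Per-condition %NMSE (mean +/- SE across subjects)\n"
                + cond.to_string(index=False)
                + "\n\nGrand means across conditions\n"
                + grand.to_string(index=False))

    def to_csv(self, path: str | Path) -> None:
        self.by_condition().to_csv(path, index=False)


def evaluate_cohort(cohort: Mapping[tuple, Sequence[Recording]] | str | Path,
                    methods: Iterable[str] = ("pcr", "pca_time", "pca_freq"),
                    ks: Iterable[int] = (1, 2, 3),
                    include_all_channels: bool = True,
                    n_pcs: int = 1,
                    pre_cfg: PreprocessConfig | None = None,
                    basis_cfg: BasisConfig | None = None,
                    max_terms: int = 9) -> EvaluationReport:
    """Run the protocol over every condition of a cohort.

    ``cohort`` is either a mapping ``(subject, angle, posture) -> [trials]``
    (trial order = recording order) or a directory of recording files, which
    are grouped by their metadata and ordered by ``trial_id``.
    """
    if isinstance(cohort, (str, Path)):
        cohort = load_cohort(cohort)
    rows = []
    for key in sorted(cohort):
        trials = list(cohort[key])
        combos = [("all", 7, 1)] if include_all_channels else []
        combos += [(m, k, n_pcs) for m in methods for k in ks]
        for method, k, npc in combos:
            rows.append(run_protocol(trials, method=method, k=k, n_pcs=npc,
                                     pre_cfg=pre_cfg, basis_cfg=basis_cfg,
                                     max_terms=max_terms))
    return EvaluationReport(pd.DataFrame(rows))


def load_cohort(directory: str | Path) -> dict[tuple, list[Recording]]:
    """Read every recording file in ``directory`` and group it by condition."""
    directory = Path(directory)
    grouped: dict[tuple, list[Recording]] = defaultdict(list)
    files = sorted(list(directory.glob("*.h5")) + list(directory.glob("*.hdf5"))
                   + list(directory.glob("*.csv")))
    files = [f for f in files if not f.name.endswith(".force.csv")]
    if not files:
        raise EmgForceError(f"no recording files found in {directory}")
    for f in files:
        rec = read_recording(f)
        grouped[(rec.subject_id, float(rec.angle_deg), rec.posture)].append(rec)
    key = lambda r: [int(s) if s.isdigit() else s
                     for s in re.split(r"(\d+)", r.trial_id)]
    return {cond: sorted(trials, key=key) for cond, trials in grouped.items()}


def stats_report(table: pd.DataFrame, alpha: float = 0.05) -> str:
    """Thin significance helper: one-way ANOVA + pairwise Welch t-tests.

    Compares %NMSE across methods (per k) using standard statistical
    routines, with a Bonferroni-adjusted threshold for the pairwise tests.
    Reporting convenience only — no bespoke statistics.
    """
    lines = []
    reference = table.loc[table["method"].isin(("all", "full")), "nmse_pct"].to_numpy()
    for k, sub in table[~table["method"].isin(("all", "full"))].groupby("k"):
        methods = sorted(sub["method"].unique())
        groups = [sub.loc[sub["method"] == m, "nmse_pct"].to_numpy() for m in methods]
        if reference.size:  # all-channels runs join as the reference group
            methods = methods + ["all"]
            groups = groups + [reference]
        if len(groups) < 2 or any(g.size < 2 for g in groups):
            continue
        f_stat, p = scipy.stats.f_oneway(*groups)
        lines.append(f"k={k}: one-way ANOVA across {methods}: "
                     f"F={f_stat:.3g}, p={p:.3g}")
        pairs = [(i, j) for i in range(len(methods)) for j in range(i + 1, len(methods))]
        thr = alpha / max(len(pairs), 1)
        for i, j in pairs:
            t_stat, p = scipy.stats.ttest_ind(groups[i], groups[j], equal_var=False)
            flag = "*" if p < thr else " "
            lines.append(f"  {methods[i]} vs {methods[j]}: Welch t={t_stat:.3g}, "
                         f"p={p:.3g}{flag} (Bonferroni threshold {thr:.3g})")
    return "\n".join(lines) if lines else "not enough replicates for statistics"


__all__ = [
    "nmse", "run_protocol", "EvaluationReport", "evaluate_cohort",
    "load_cohort", "standard_error", "stats_report",
]
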