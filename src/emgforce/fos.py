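"""Fast orthogonal search (FOS): greedy orthogonal least squares on a basis pool.

The force model is a sparse linear combination of candidate basis functions

    y(n) = sum_m a_m p_m(n) + e(n),

where the candidates p_m are built from the normalized EMG linear envelopes
and the (constant, isometric) elbow angle: the constant, the angle, each
envelope, sin/cos of the angle times each envelope and times cross-muscle
envelope products, and four nonlinear transforms (square, saturating
square, square root, logistic sigmoid) of each envelope.

Fitting is Gram–Schmidt-based greedy selection: at each step every
remaining candidate is implicitly orthogonalized against the functions
already chosen, the candidate giving the greatest reduction of the residual
mean squared error is added, and the loop stops after ``max_terms``
(default 9) terms or when no candidate retains numerically independent
energy.  The implementation keeps only inner-product recursions — the
orthogonalized energies and residual correlations of all candidates are
updated from a single matrix-vector product per step — so the cost per step
is O(n_samples * n_candidates) regardless of how many terms are already in
the model.  Coefficients in the original basis are recovered by
back-substitution through the triangular Gram–Schmidt factor.

The model/results split follows the usual statsmodels convention:
``FastOrthogonalSearch(y, pool).fit()`` returns an :class:`FOSResults`
carrying terms, coefficients, per-term MSE reductions and ``summary()``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.special

from .errors import IncompatiblePoolError, SchemaError
from .io import EnvelopeSet
from .selection import SelectionResult

#: provenance of one candidate: (family, muscles involved, channel indices)
Provenance = tuple[str, tuple[str, ...], tuple[int, ...]]


@dataclass
class BasisConfig:
    """Parameters of the candidate basis families.

    The saturating square is ``min(LE^2, saturation)`` and the sigmoid is a
    logistic ``1 / (1 + exp(-(LE - center)/slope))``.  Envelopes are
    normalized to 1 at 50 %MVC, so the defaults place the sigmoid operating
    point at the reference contraction level and let the saturating square
    clip at twice the reference amplitude.  The exact analytic forms used
    with the original hardware are not public; these are documented
    reconstructions.
    """

    sigmoid_center: float = 1.0
    sigmoid_slope: float = 0.25
    saturation: float = 4.0
    include_angle: bool = True


@dataclass
class CandidatePool:
    """Matrix of candidate basis functions with per-column provenance."""

    X: np.ndarray
    provenance: list[Provenance]
    names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise SchemaError("candidate matrix must be 2-D")
        if len(self.provenance) != self.X.shape[1] or len(self.names) != self.X.shape[1]:
            raise SchemaError("provenance/names must cover every candidate column")
        if not np.all(np.isfinite(self.X)):
            raise SchemaError("candidate matrix contains non-finite values")
        norms = np.einsum("ij,ij->j", self.X, self.X)
        if np.any(norms == 0):
            raise SchemaError("candidate pool contains an all-zero column")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_candidates(self) -> int:
        return self.X.shape[1]


def expected_pool_size(channels_per_muscle: Sequence[int],
                       angle_deg: float | None = None) -> int:
    """Closed-form candidate count for the basis enumeration.

    With C active channels in total and P cross-muscle channel pairs the
    pool holds 2 (constant, angle) + C (envelopes) + 2C (sin/cos x LE)
    + 2P (sin/cos x cross products) + 4C (nonlinear transforms)
    = 2 + 7C + 2P columns.  When ``angle_deg`` is given, families whose
    trigonometric factor vanishes exactly at that angle (e.g. cos at 90
    degrees) are excluded, matching :func:`build_candidates`.
    """
    counts = list(channels_per_muscle)
    c_total = sum(counts)
    pairs = sum(a * b for i, a in enumerate(counts) for b in counts[i + 1:])
    n = 2 + 7 * c_total + 2 * pairs
    if angle_deg is not None:
        if scipy.special.sindg(angle_deg) == 0.0:
            n -= c_total + pairs
        if scipy.special.cosdg(angle_deg) == 0.0:
            n -= c_total + pairs
        if float(angle_deg) == 0.0:
            n -= 1
    return n


def build_candidates(le: np.ndarray, channel_labels: Sequence[tuple[str, int]],
                     angle_deg: float, cfg: BasisConfig | None = None) -> CandidatePool:
    """Assemble the candidate matrix for a set of active envelope channels.

    ``le`` holds one column per active channel (already restricted to the
    analysis samples); ``channel_labels`` gives the (muscle, within-muscle
    index) identity of each column.  Channels whose envelope is identically
    zero are dropped with a warning (no all-zero candidate columns).
    """
    cfg = cfg or BasisConfig()
    le = np.asarray(le, dtype=float)
    if le.ndim != 2 or le.shape[1] == 0:
        raise SchemaError("need at least one envelope channel")
    if le.shape[1] != len(channel_labels):
        raise SchemaError("channel_labels must match the envelope columns")

    keep = [j for j in range(le.shape[1]) if np.any(le[:, j] != 0)]
    if len(keep) < le.shape[1]:
        dropped = [channel_labels[j] for j in range(le.shape[1]) if j not in keep]
        warnings.warn(f"dropping all-zero envelope channel(s): {dropped}")
    if not keep:
        raise SchemaError("every envelope channel is identically zero")
    le = le[:, keep]
    labels = [tuple(channel_labels[j]) for j in keep]

    n = le.shape[0]
    # exact-in-degrees trig: at 90 degrees the cosine factor is exactly 0,
    # so the cos-family columns vanish instead of becoming rounding noise
    sin_t = float(scipy.special.sindg(angle_deg))
    cos_t = float(scipy.special.cosdg(angle_deg))

    cols: list[np.ndarray] = []
    prov: list[Provenance] = []
    names: list[str] = []

    def add(col: np.ndarray, family: str, muscles: tuple[str, ...],
            channels: tuple[int, ...], name: str) -> None:
        if not np.any(col):
            return  # identically-zero function (degenerate trig factor)
        cols.append(col)
        prov.append((family, muscles, channels))
        names.append(name)

    add(np.ones(n), "constant", (), (), "1")
    if cfg.include_angle:
        add(np.full(n, float(angle_deg)), "angle", (), (), "theta")
    for j, (m, c) in enumerate(labels):
        add(le[:, j], "le", (m,), (c,), f"LE[{m}:{c}]")
    for j, (m, c) in enumerate(labels):
        add(sin_t * le[:, j], "sin_le", (m,), (c,), f"sin(theta)*LE[{m}:{c}]")
    for j, (m, c) in enumerate(labels):
        add(cos_t * le[:, j], "cos_le", (m,), (c,), f"cos(theta)*LE[{m}:{c}]")
    for j, jj in combinations(range(len(labels)), 2):
        (m1, c1), (m2, c2) = labels[j], labels[jj]
        if m1 == m2:
            continue
        prod = le[:, j] * le[:, jj]
        add(sin_t * prod, "sin_le_cross", (m1, m2), (c1, c2),
            f"sin(theta)*LE[{m1}:{c1}]*LE[{m2}:{c2}]")
        add(cos_t * prod, "cos_le_cross", (m1, m2), (c1, c2),
            f"cos(theta)*LE[{m1}:{c1}]*LE[{m2}:{c2}]")
    for j, (m, c) in enumerate(labels):
        add(le[:, j] ** 2, "quadratic", (m,), (c,), f"LE[{m}:{c}]^2")
    for j, (m, c) in enumerate(labels):
        add(np.minimum(le[:, j] ** 2, cfg.saturation), "limited_square", (m,), (c,),
            f"min(LE[{m}:{c}]^2,{cfg.saturation:g})")
    for j, (m, c) in enumerate(labels):
        add(np.sqrt(le[:, j]), "sqrt", (m,), (c,), f"sqrt(LE[{m}:{c}])")
    for j, (m, c) in enumerate(labels):
        z = (le[:, j] - cfg.sigmoid_center) / cfg.sigmoid_slope
        add(1.0 / (1.0 + np.exp(-z)), "sigmoid", (m,), (c,), f"sigmoid(LE[{m}:{c}])")

    return CandidatePool(np.column_stack(cols), prov, names)


def pool_from_envelopes(env: EnvelopeSet, selection: SelectionResult | None = None,
                        cfg: BasisConfig | None = None) -> tuple[CandidatePool, np.ndarray]:
    """Build the candidate pool and target force for one pre-processed trial.

    Uses the concatenated plateau samples; ``selection`` restricts the active
    channels (None means all channels of every muscle).
    """
    idx = env.segment_samples()
    if selection is None:
        labels = []
        for m in env.muscles:
            labels.extend((m, c) for c in range(env.channels_of(m).size))
        global_cols = np.concatenate([env.channels_of(m) for m in env.muscles])
    else:
        labels = selection.channel_labels()
        global_cols = selection.global_indices(env)
    pool = build_candidates(env.le[np.ix_(idx, global_cols)], labels,
                            env.angle_deg, cfg)
    return pool, env.force[idx]


class FastOrthogonalSearch:
    """Greedy orthogonal-least-squares model for force estimation.

    Parameters
    ----------
    y : ndarray, shape (n,)
        Target signal (measured force on the analysis samples).
    pool : CandidatePool
        Candidate basis functions, one column each.
    max_terms : int
        Stop after this many selected terms (protocol default 9).
    min_q_frac : float
        Stop early when the best achievable MSE reduction falls below this
        fraction of the target mean square.  0 keeps adding terms while any
        candidate reduces the error at all.
    energy_tol : float
        A candidate is skipped once its orthogonalized energy drops below
        ``energy_tol`` times its original energy (collinearity guard).
    """

    def __init__(self, y: np.ndarray, pool: CandidatePool, max_terms: int = 9,
                 min_q_frac: float = 0.0, energy_tol: float = 1e-10) -> None:
        self.y = np.asarray(y, dtype=float)
        self.pool = pool
        if self.y.ndim != 1 or self.y.size != pool.n_samples:
            raise SchemaError("y must be 1-D and match the pool's sample count")
        if pool.n_candidates == 0:
            raise SchemaError("candidate pool is empty")
        self.max_terms = int(max_terms)
        self.min_q_frac = float(min_q_frac)
        self.energy_tol = float(energy_tol)

    def fit(self) -> "FOSResults":
        X, y = self.pool.X, self.y
        n, n_cand = X.shape
        norms2 = np.einsum("ij,ij->j", X, X)
        mean_y2 = float(y @ y) / n

        g = X.T @ y                      # <p_c, y> residualized against Q
        e = norms2.copy()                # orthogonalized energy of each candidate
        available = np.ones(n_cand, dtype=bool)

        Q = np.empty((n, 0))
        terms: list[int] = []
        mse_reductions: list[float] = []
        r_cols: list[np.ndarray] = []    # columns of the triangular factor

        for _ in range(self.max_terms):
            valid = available & (e > self.energy_tol * norms2)
            if not valid.any():
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                score = np.where(valid, g * g / np.where(valid, e, 1.0), -np.inf)
            best = int(np.argmax(score))       # first max -> lowest-index tie-break
            q_red = score[best] / n            # MSE reduction of the best candidate
            if q_red <= self.min_q_frac * mean_y2:
                break

            x_best = X[:, best]
            c1 = Q.T @ x_best
            v = x_best - Q @ c1
            c2 = Q.T @ v                       # re-orthogonalization for stability
            v = v - Q @ c2
            nv = float(np.linalg.norm(v))
            if nv * nv <= self.energy_tol * norms2[best]:
                available[best] = False
                continue
            q_new = v / nv

            terms.append(best)
            mse_reductions.append(float((q_new @ y) ** 2) / n)
            r_cols.append((c1 + c2, nv))
            available[best] = False
            Q = np.column_stack([Q, q_new])

            r = X.T @ q_new
            g -= r * float(q_new @ y)
            e = np.maximum(e - r * r, 0.0)

        m = len(terms)
        if m == 0:
            raise SchemaError("no candidate could be selected (all collinear or zero)")
        R = np.zeros((m, m))
        for j, (col, nv) in enumerate(r_cols):
            R[: j, j] = col[: j]
            R[j, j] = nv
        coef = scipy.linalg.solve_triangular(R, Q.T @ y)
        resid = y - X[:, terms] @ coef
        training_mse = float(resid @ resid) / n

        return FOSResults(
            model=self,
            terms=np.array(terms, dtype=int),
            params=coef,
            mse_reduction=np.array(mse_reductions),
            training_mse=training_mse,
            provenance=[self.pool.provenance[t] for t in terms],
            names=[self.pool.names[t] for t in terms],
            nobs=n,
            n_candidates=n_cand,
            ortho_basis=Q,
        )


@dataclass
class FOSResults:
    """Fitted FOS force model: selected terms, coefficients, diagnostics."""

    terms: np.ndarray
    params: np.ndarray
    mse_reduction: np.ndarray
    training_mse: float
    provenance: list[Provenance]
    names: list[str]
    nobs: int
    n_candidates: int
    model: FastOrthogonalSearch | None = None
    #: orthonormalized selected functions (training only; not serialized)
    ortho_basis: np.ndarray | None = None

    @property
    def n_terms(self) -> int:
        return int(self.terms.size)

    def predict(self, pool: CandidatePool) -> np.ndarray:
        """Evaluate the fitted model on a (compatible) candidate pool."""
        for t, prov in zip(self.terms, self.provenance):
            if t >= pool.n_candidates or pool.provenance[int(t)] != tuple(prov):
                raise IncompatiblePoolError(
                    f"pool column {int(t)} does not match fitted term {prov}")
        return pool.X[:, self.terms] @ self.params

    def summary(self) -> str:
        head = (
            f"Fast orthogonal search results\n"
            f"  terms selected : {self.n_terms} (pool of {self.n_candidates})\n"
            f"  observations   : {self.nobs}\n"
            f"  training MSE   : {self.training_mse:.6g}\n"
        )
        tab = pd.DataFrame({
            "term": self.terms,
            "basis": self.names,
            "coef": self.params,
            "mse_reduction": self.mse_reduction,
        })
        return head + tab.to_string(index=False)

    # -- JSON serialization ------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "terms": self.terms.tolist(),
            "params": self.params.tolist(),
            "mse_reduction": self.mse_reduction.tolist(),
            "training_mse": self.training_mse,
            "provenance": [[f, list(ms), list(cs)] for f, ms, cs in self.provenance],
            "names": self.names,
            "nobs": self.nobs,
            "n_candidates": self.n_candidates,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "FOSResults":
        p = Path(text_or_path)
        text = p.read_text(encoding="utf-8") if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            terms=np.array(d["terms"], dtype=int),
            params=np.array(d["params"], dtype=float),
            mse_reduction=np.array(d["mse_reduction"], dtype=float),
            training_mse=float(d["training_mse"]),
            provenance=[(f, tuple(ms), tuple(int(c) for c in cs))
                        for f, ms, cs in d["provenance"]],
            names=list(d["names"]),
            nobs=int(d["nobs"]),
            n_candidates=int(d["n_candidates"]),
        )


def fos_fit(pool: CandidatePool, y: np.ndarray, max_terms: int = 9,
            min_q_frac: float = 0.0) -> FOSResults:
    """Functional wrapper around :class:`FastOrthogonalSearch`."""
    return FastOrthogonalSearch(y, pool, max_terms=max_terms,
                                min_q_frac=min_q_frac).fit()


def fos_predict(results: FOSResults, pool: CandidatePool) -> np.ndarray:
    """Functional wrapper around :meth:`FOSResults.predict`."""
    return results.predict(pool)


__all__ = [
    "Provenance", "BasisConfig", "CandidatePool", "expected_pool_size",
    "build_candidates", "pool_from_envelopes", "FastOrthogonalSearch",
    "FOSResults", "fos_fit", "fos_predict",
]
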