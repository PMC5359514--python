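"""Principal-factor extraction with varimax rotation and one-way-motion selection.

Each trajectory part is standardized, factored through the eigendecomposition
of its CV correlation matrix (principal-components method), rotated to simple
structure by Kaiser-normalized varimax, and scored by least squares.  Factors
whose coordinate moves essentially monotonically from one level to another —
"one-way motions" — are the ones carried forward to event ordering; factors
that wander (noise) or oscillate (reversible motions) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "StandardizedPart",
    "FactorModel",
    "OneWayFlag",
    "VarimaxConvergenceError",
    "standardize",
    "extract_factors",
    "varimax_rotate",
    "varimax_criterion",
    "compute_scores",
    "select_one_way_factors",
]

DEFAULT_MIN_RATIO = 0.6
#: Spearman-trend threshold for one-way motions.  A clean two-level step at
#: fraction p of the part has E[rho] ≈ 0.87·√(3p(1−p)) — 0.75 when centered
#: but only ~0.5 near p = 0.15 — so the threshold must admit transitions
#: sitting close to a part boundary while excluding oscillations (rho ≈ 0
#: over a full period) and noise (white-noise null sd ≈ 1/√T; autocorrelated
#: noise is screened jointly with the displacement ratio).
DEFAULT_MIN_RHO = 0.5


@dataclass
class StandardizedPart:
    """Column-standardized slice of a CVMatrix."""

    X: np.ndarray  # (T, M_retained), column mean 0 / SD 1
    cv_ids: list[str]
    dropped_cvs: list[str] = field(default_factory=list)


@dataclass
class FactorModel:
    loadings: np.ndarray  # (M, k), varimax-rotated
    rotation: np.ndarray  # (k, k) orthogonal
    eigenvalues: np.ndarray  # (k,)
    explained_variance_fraction: np.ndarray  # (k,)
    cv_ids: list[str]
    scores: np.ndarray | None = None  # (T, k)


@dataclass(frozen=True)
class OneWayFlag:
    factor_index: int
    net_displacement_ratio: float
    trend_rho: float
    selected: bool


class VarimaxConvergenceError(RuntimeError):
    def __init__(self, message: str, loadings: np.ndarray, rotation: np.ndarray):
        super().__init__(message)
        self.loadings = loadings
        self.rotation = rotation


def standardize(values: np.ndarray, cv_ids: list[str] | None = None) -> StandardizedPart:
    """Standardize columns to mean 0 / SD 1, dropping (near-)constant columns."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be 2-D")
    t, m = values.shape
    if t < 10:
        raise ValueError(f"need at least 10 samples to standardize, got {t}")
    if cv_ids is None:
        cv_ids = [f"cv{j}" for j in range(m)]
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    keep = sd > np.maximum(1e-12, 1e-8 * np.abs(mean))
    if not np.any(keep):
        raise ValueError("all columns are (near-)constant; nothing to standardize")
    x = (values[:, keep] - mean[keep]) / sd[keep]
    return StandardizedPart(
        X=x,
        cv_ids=[c for c, k in zip(cv_ids, keep) if k],
        dropped_cvs=[c for c, k in zip(cv_ids, keep) if not k],
    )


def extract_factors(X: np.ndarray, k: int | str = "kaiser") -> FactorModel:
    """Principal factors of the correlation matrix of standardized ``X``.

    Loading column j is eigenvector j scaled by √eigenvalue j, eigenvalues in
    descending order.  ``k="kaiser"`` retains eigenvalues > 1.
    """
    X = np.asarray(X, dtype=float)
    t, m = X.shape
    corr = X.T @ X / t
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    w = np.maximum(w, 0.0)
    if k == "kaiser":
        n_keep = max(1, int(np.sum(w > 1.0)))
    else:
        n_keep = int(k)
        if n_keep < 1 or n_keep > m:
            raise ValueError(f"k must be in [1, {m}], got {n_keep}")
    loadings = v[:, :n_keep] * np.sqrt(w[:n_keep])
    return FactorModel(
        loadings=loadings,
        rotation=np.eye(n_keep),
        eigenvalues=w[:n_keep],
        explained_variance_fraction=w[:n_keep] / m,
        cv_ids=[f"cv{j}" for j in range(m)],
    )


def varimax_criterion(loadings: np.ndarray, kaiser_normalize: bool = True) -> float:
    """Sum over factors of the variance of squared (Kaiser-normalized) loadings."""
    a = np.asarray(loadings, dtype=float)
    if kaiser_normalize:
        h = np.sqrt((a**2).sum(axis=1))
        h[h < 1e-12] = 1.0
        a = a / h[:, None]
    sq = a**2
    return float(np.sum(sq.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
    kaiser_normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Varimax rotation by iterated pairwise planar rotations.

    Rows are Kaiser-normalized (divided by their communality root) before
    rotation and denormalized after.  Sweeps over all factor pairs apply the
    closed-form optimal angle per pair; iteration stops when a full sweep
    improves the criterion by less than ``tol``.

    Returns ``(rotated_loadings, rotation, criterion_history)`` with
    ``rotated = loadings @ rotation`` and one history entry per sweep
    (starting value included); the history is non-decreasing.
    """
    a = np.array(loadings, dtype=float)
    m, k = a.shape
    rotation = np.eye(k)
    if k == 1:
        return a, rotation, [varimax_criterion(a, kaiser_normalize)]
    h = np.sqrt((a**2).sum(axis=1))
    h_safe = np.where(h < 1e-12, 1.0, h)
    if kaiser_normalize:
        a = a / h_safe[:, None]
    history = [varimax_criterion(a, kaiser_normalize=False)]
    for _ in range(max_iter):
        for p in range(k - 1):
            for q in range(p + 1, k):
                ap, aq = a[:, p], a[:, q]
                u = ap**2 - aq**2
                v = 2.0 * ap * aq
                su, sv = u.sum(), v.sum()
                num = 2.0 * (u @ v) - 2.0 * su * sv / m
                den = (u @ u) - (v @ v) - (su**2 - sv**2) / m
                phi = 0.25 * np.arctan2(num, den)
                c, s = np.cos(phi), np.sin(phi)
                g = np.array([[c, -s], [s, c]])
                a[:, [p, q]] = a[:, [p, q]] @ g
                rotation[:, [p, q]] = rotation[:, [p, q]] @ g
        history.append(varimax_criterion(a, kaiser_normalize=False))
        if history[-1] - history[-2] < tol:
            if kaiser_normalize:
                a = a * h_safe[:, None]
            return a, rotation, history
    if kaiser_normalize:
        a = a * h_safe[:, None]
    raise VarimaxConvergenceError(
        f"varimax did not converge in {max_iter} sweeps", loadings=a, rotation=rotation
    )


def compute_scores(X: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Least-squares (regression-method) factor scores, columns mean-centered.

    Solves ``X ≈ F @ loadingsᵀ`` for F.
    """
    X = np.asarray(X, dtype=float)
    loadings = np.asarray(loadings, dtype=float)
    if X.shape[1] != loadings.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} variables but loadings has {loadings.shape[0]} rows"
        )
    if np.linalg.matrix_rank(loadings) < loadings.shape[1]:
        raise np.linalg.LinAlgError("loadings matrix is rank-deficient; scores are not unique")
    gram = loadings.T @ loadings
    scores = X @ loadings @ np.linalg.inv(gram)
    return scores - scores.mean(axis=0)


def select_one_way_factors(
    scores: np.ndarray,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_rho: float = DEFAULT_MIN_RHO,
) -> list[OneWayFlag]:
    """Flag factors whose score is a one-way (monotone level-to-level) motion.

    net_displacement_ratio compares the endpoint levels of the decile-window
    moving average against its full range — a step between two levels scores
    near 1 wherever it sits in the part, a completed oscillation scores near
    0, and wandering noise rarely ends far from one of its extremes while
    also trending; trend_rho is the Spearman correlation with time.  A factor
    is selected when both statistics clear their thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    t = scores.shape[0]
    if t < 20:
        raise ValueError(f"need at least 20 samples, got {t}")
    d = max(2, t // 10)
    tt = np.arange(t)
    flags = []
    for j in range(scores.shape[1]):
        s = scores[:, j]
        smooth = np.convolve(s, np.ones(d) / d, mode="valid")
        span = float(smooth.max() - smooth.min())
        net = abs(float(smooth[-1] - smooth[0]))
        ratio = 0.0 if span <= 0 else min(net / span, 1.0)
        if np.ptp(s) <= 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(tt, s).statistic)
        flags.append(
            OneWayFlag(
                factor_index=j,
                net_displacement_ratio=ratio,
                trend_rho=rho,
                selected=bool(ratio >= min_ratio and abs(rho) >= min_rho),
            )
        )
    return flags
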