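"""Temporal ordering of factors by lagged cross-correlation of their scores.

For every pair of selected factors the normalized cross-correlation function
(CCF) over lags in [−max_lag, max_lag] locates the relative timing of the two
motions: the argmax lag says which factor moves first and by how many frames.
Pairs whose peak correlation clears a white-noise significance band and whose
lag is materially nonzero yield precedence constraints; the constraints are
assembled into a partial order of tie-groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "LagMatrix",
    "FactorSequence",
    "cross_correlate",
    "build_lag_matrix",
    "order_factors",
]

DEFAULT_SIG_K = 2.0  # ≈ 95% large-sample white-noise band, k/√T
DEFAULT_MIN_LAG = 5  # frames; smaller lags are treated as simultaneous


@dataclass
class LagMatrix:
    factor_ids: list[str]
    lag: np.ndarray  # (k, k) frames, lag[i, j] > 0 means i precedes j
    peak_ccf: np.ndarray  # (k, k) in [-1, 1]
    significant: np.ndarray  # (k, k) bool, symmetric

    @property
    def n(self) -> int:
        return len(self.factor_ids)


@dataclass
class FactorSequence:
    """Ordered list of tie-groups (sets of factor ids), earliest first."""

    groups: list[frozenset[str]]

    def __post_init__(self):
        all_ids = [f for g in self.groups for f in g]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("factor appears in more than one tie-group")

    def position(self, factor_id: str) -> int:
        for i, g in enumerate(self.groups):
            if factor_id in g:
                return i
        raise KeyError(factor_id)

    def __str__(self) -> str:
        return " < ".join("{" + ",".join(sorted(g)) + "}" for g in self.groups)


def cross_correlate(
    x: np.ndarray, y: np.ndarray, max_lag: int
) -> tuple[int, np.ndarray]:
    """Normalized cross-correlation of two series over lags in [−max_lag, max_lag].

    The value at lag ℓ is the Pearson correlation of ``x[t]`` with ``y[t + ℓ]``
    over the overlapping stretch, so a noiseless copy of ``x`` delayed by s
    attains exactly 1 at ℓ = s.  Returns ``(best_lag, ccf)`` where ``ccf[i]``
    corresponds to lag ``i − max_lag`` and ``best_lag`` is the argmax with
    ties broken toward 0.  Positive best_lag means x leads (precedes) y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be equal-length 1-D series")
    t = len(x)
    max_lag = int(max_lag)
    if max_lag < 0:
        raise ValueError("max_lag must be non-negative")
    if t <= 2 * max_lag:
        raise ValueError(f"series length {t} must exceed 2 × max_lag = {2 * max_lag}")
    if x.std() <= 0 or y.std() <= 0:
        raise ValueError("zero-variance series cannot be cross-correlated")
    lags = np.arange(-max_lag, max_lag + 1)
    ccf = np.empty(len(lags))
    for i, ell in enumerate(lags):
        if ell >= 0:
            xs, ys = x[: t - ell], y[ell:]
        else:
            xs, ys = x[-ell:], y[: t + ell]
        sx, sy = xs.std(), ys.std()
        if sx <= 1e-12 or sy <= 1e-12:
            ccf[i] = 0.0
            continue
        ccf[i] = float(((xs - xs.mean()) @ (ys - ys.mean())) / (len(xs) * sx * sy))
    best = np.flatnonzero(ccf == ccf.max())
    # ties toward zero lag, then toward the earlier (negative) lag for determinism
    best_lag = int(lags[best[np.lexsort((lags[best], np.abs(lags[best])))[0]]])
    return best_lag, ccf


def build_lag_matrix(
    scores: np.ndarray | dict[str, np.ndarray],
    factor_ids: list[str] | None = None,
    max_lag: int | None = None,
    sig_k: float = DEFAULT_SIG_K,
) -> LagMatrix:
    """Pairwise lag/peak-CCF matrix of the selected factors' score series.

    A pair is significant when its |peak CCF| reaches ``sig_k / √T`` (the
    large-sample white-noise band).  Whether a significant pair is *ordered*
    or tied is decided later, in :func:`order_factors`, by the lag size.
    """
    if isinstance(scores, dict):
        factor_ids = list(scores.keys())
        mat = np.column_stack([scores[f] for f in factor_ids])
    else:
        mat = np.asarray(scores, dtype=float)
        if factor_ids is None:
            factor_ids = [f"F{j + 1}" for j in range(mat.shape[1])]
    k = mat.shape[1]
    if k < 2:
        raise ValueError("need at least 2 factors to build a lag matrix")
    t = mat.shape[0]
    if max_lag is None:
        max_lag = max(1, (t - 1) // 3)
    lag = np.zeros((k, k), dtype=int)
    peak = np.eye(k)
    sig = np.zeros((k, k), dtype=bool)
    band = sig_k / np.sqrt(t)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                best, ccf = cross_correlate(mat[:, i], mat[:, j], max_lag)
            except ValueError as exc:
                raise ValueError(
                    f"pair ({factor_ids[i]}, {factor_ids[j]}): {exc}"
                ) from exc
            p = float(ccf[best + max_lag])
            lag[i, j] = best
            lag[j, i] = -best
            peak[i, j] = peak[j, i] = p
            sig[i, j] = sig[j, i] = abs(p) >= band
    return LagMatrix(factor_ids=factor_ids, lag=lag, peak_ccf=peak, significant=sig)


def order_factors(lm: LagMatrix, min_lag: int = DEFAULT_MIN_LAG) -> FactorSequence:
    """Partial order of factors from the pairwise lag matrix.

    Significant pairs with |lag| ≥ ``min_lag`` contribute a precedence edge;
    every other pair (insignificant, or lag too small to call) is treated as
    tied.  Mutually inconsistent precedences form cycles; cycles and ties are
    contracted into tie-groups, which are then totally ordered (every pair
    carries at least one arc, so the condensation is a chain).
    """
    g = nx.DiGraph()
    g.add_nodes_from(lm.factor_ids)
    for i in range(lm.n):
        for j in range(i + 1, lm.n):
            fi, fj = lm.factor_ids[i], lm.factor_ids[j]
            if lm.significant[i, j] and abs(lm.lag[i, j]) >= min_lag:
                if lm.lag[i, j] > 0:
                    g.add_edge(fi, fj)
                else:
                    g.add_edge(fj, fi)
            else:
                g.add_edge(fi, fj)
                g.add_edge(fj, fi)
    cond = nx.condensation(g)
    order = list(nx.topological_sort(cond))
    groups = [frozenset(cond.nodes[c]["members"]) for c in order]
    return FactorSequence(groups=groups)
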