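"""Plateau detection and trajectory cutting.

Replicate trajectories are cut into parts before factor analysis so that each
part contains roughly one burst of concerted motion.  Cut points are only
allowed inside intervals that are simultaneously flat ("plateaus") in every
collective variable, so the cutting itself cannot split a transition.

Two complementary detectors are provided.  :func:`detect_plateaus` judges a
single series by a sliding-window least-squares fit: a window is flat when
|fitted slope| ≤ ``flatness_k`` × residual SD / window — unitless and
rescaling-invariant.  :func:`cut_trajectory` works on the full CV matrix and
uses the dual view: it localizes transition *cores* per CV by a half-mean
difference test against a robust (MAD-calibrated) null, which stays reliable
under strongly autocorrelated noise where per-window slope tests do not, and
then cuts at midpoints of the runs that are quiet in every CV at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .cv import CVMatrix

__all__ = [
    "PlateauInterval",
    "TrajectoryPart",
    "Motif",
    "detect_plateaus",
    "transition_mask",
    "segment_trajectory",
    "cut_trajectory",
]

DEFAULT_WINDOW = 100
DEFAULT_FLATNESS_K = 2.0


@dataclass(frozen=True)
class PlateauInterval:
    start_frame: int
    end_frame: int  # closed interval

    def __post_init__(self):
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")

    def __len__(self) -> int:
        return self.end_frame - self.start_frame + 1


@dataclass(frozen=True)
class TrajectoryPart:
    trajectory_id: str
    start_frame: int
    end_frame: int  # closed interval

    def __len__(self) -> int:
        return self.end_frame - self.start_frame + 1


def _flat_window_mask(values: np.ndarray, window: int, flatness_k: float) -> np.ndarray:
    """Boolean mask over window start positions; True where every column is flat.

    ``values`` is (T,) or (T, M).  Slopes and residual SDs come from an
    ordinary least-squares line fit within each window, computed for all
    windows at once.
    """
    x2d = values[:, None] if values.ndim == 1 else values
    t, m = x2d.shape
    if window < 5:
        raise ValueError(f"window must be >= 5, got {window}")
    if window > t:
        raise ValueError(f"window ({window}) exceeds series length ({t})")
    xw = np.arange(window) - (window - 1) / 2.0
    sxx = float(xw @ xw)
    wins = sliding_window_view(x2d, window, axis=0)  # (T-window+1, M, window)
    slope = (wins @ xw) / sxx  # xw is centered, so no intercept term is needed
    # residual variance of the line fit: var(y) - slope^2 * var(x)
    var_resid = np.maximum(wins.var(axis=2) - slope**2 * (sxx / window), 0.0)
    thresh = flatness_k * np.sqrt(var_resid) / window
    return np.all(np.abs(slope) <= thresh, axis=1)


def _mask_to_intervals(flat: np.ndarray, window: int) -> list[PlateauInterval]:
    intervals = []
    t = len(flat)
    i = 0
    while i < t:
        if flat[i]:
            j = i
            while j + 1 < t and flat[j + 1]:
                j += 1
            intervals.append(PlateauInterval(i, j + window - 1))
            i = j + 1
        else:
            i += 1
    return intervals


def detect_plateaus(
    series: np.ndarray,
    window: int = DEFAULT_WINDOW,
    flatness_k: float = DEFAULT_FLATNESS_K,
) -> list[PlateauInterval]:
    """Maximal intervals in which every length-``window`` sub-window is flat."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    flat = _flat_window_mask(series, window, flatness_k)
    return _mask_to_intervals(flat, window)


DEFAULT_TRANSITION_Z = 3.0


def _half_window(window: int) -> int:
    return max(window // 2, int(round(1.5 * window)))


def _delta_stat(x: np.ndarray, half: int) -> tuple[np.ndarray, np.ndarray]:
    """Half-mean difference statistic and its robust null scale per column.

    ``delta[p, m]`` is the mean of ``x[p+half : p+2·half, m]`` minus the mean
    of ``x[p : p+half, m]`` — large in magnitude when a level shift sits near
    frame ``p + half``.  The scale is 1.4826 × MAD over all positions, which
    self-calibrates to the noise level and its autocorrelation.
    """
    t, m = x.shape
    csum = np.concatenate([np.zeros((1, m)), np.cumsum(x, axis=0)])
    n_pos = t - 2 * half + 1
    first = (csum[half : half + n_pos] - csum[:n_pos]) / half
    second = (csum[2 * half : 2 * half + n_pos] - csum[half : half + n_pos]) / half
    delta = second - first
    med = np.median(delta, axis=0)
    scale = 1.4826 * np.median(np.abs(delta - med), axis=0)
    return delta, np.maximum(scale, 1e-12)


def _per_cv_transition_mask(x: np.ndarray, window: int, transition_z: float) -> np.ndarray:
    """(T, M) mask of transition-core frames per (standardized) column.

    A frame is flagged for a column when the half-mean difference over the
    window centered there exceeds ``transition_z`` times the column's robust
    null scale; the flagged set localizes each transition tightly, so the
    quiet gaps between consecutive transitions stay wide.
    """
    t, m = x.shape
    half = _half_window(window)
    if 2 * half >= t:
        return np.zeros((t, m), dtype=bool)
    delta, scale = _delta_stat(x, half)
    hot = np.abs(delta) > transition_z * scale  # (n_pos, m)
    mask = np.zeros((t, m), dtype=bool)
    pos, col = np.nonzero(hot)
    mask[pos + half, col] = True
    return mask


def _standardize_live(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardized live columns and their boolean index into the originals."""
    sd = values.std(axis=0)
    mean = values.mean(axis=0)
    live = sd > np.maximum(1e-12, 1e-8 * np.abs(mean))
    x = (values[:, live] - mean[live]) / sd[live] if np.any(live) else values[:, live]
    return x, live


def transition_mask(
    cvm: CVMatrix,
    window: int = DEFAULT_WINDOW,
    transition_z: float = DEFAULT_TRANSITION_Z,
) -> np.ndarray:
    """(T, M) boolean mask: frame t lies in a transition core of CV m.

    Column order follows ``cvm.cv_ids``; near-constant CVs never flag.
    """
    x, live = _standardize_live(cvm.values)
    mask = np.zeros(cvm.values.shape, dtype=bool)
    if np.any(live):
        mask[:, live] = _per_cv_transition_mask(x, window, transition_z)
    return mask


@dataclass(frozen=True)
class Motif:
    """One burst of concerted motion: the CVs that shift and when they shift.

    ``onsets`` maps each participating CV id to its estimated transition time
    (frame of the peak half-mean difference); ``start``/``end`` bound the
    motif's transition-core frames.
    """

    start: int
    end: int
    onsets: dict[str, float]

    @property
    def cv_ids(self) -> frozenset[str]:
        return frozenset(self.onsets)

    @property
    def center(self) -> float:
        return float(np.mean(list(self.onsets.values())))


def _find_motifs(
    cvm: CVMatrix, window: int, transition_z: float, gap_floor: int, split_gap: int
) -> list[Motif]:
    """Locate transition motifs: cluster hot frames, then split each cluster
    wherever consecutive per-CV onset estimates gap by more than ``split_gap``.

    Onset estimates come from the argmax of each CV's half-mean difference
    statistic, which localizes a level shift to a few frames even when two
    shifts sit close enough that their flagged cores touch — so two motions
    carried by different CVs are separated far below the resolution of the
    flagged-core extents, while one motion's CVs (whose onset estimates agree
    to within their jitter) are never torn apart.
    """
    t = cvm.n_frames
    x, live = _standardize_live(cvm.values)
    live_ids = [c for c, keep in zip(cvm.cv_ids, live) if keep]
    half = _half_window(window)
    if not live_ids or 2 * half >= t:
        return []
    delta, scale = _delta_stat(x, half)
    hot_pos = np.abs(delta) > transition_z * scale  # (n_pos, m_live)
    any_hot = hot_pos.any(axis=1)
    # clusters of hot positions, merged across gaps shorter than gap_floor
    clusters: list[tuple[int, int]] = []
    for p in np.flatnonzero(any_hot):
        if clusters and p - clusters[-1][1] <= gap_floor:
            clusters[-1] = (clusters[-1][0], p)
        else:
            clusters.append((p, p))
    # smoothing |delta| before the argmax roughly halves the onset-estimate
    # jitter under autocorrelated noise, which is what bounds how close two
    # motions can be and still be told apart
    box = max(5, window // 3)
    kernel = np.ones(box) / box
    motifs: list[Motif] = []
    for ps, pe in clusters:
        lo = max(0, ps - box)
        hi = min(delta.shape[0], pe + 1 + box)
        onset: dict[str, float] = {}
        for m in np.flatnonzero(hot_pos[ps : pe + 1].any(axis=0)):
            seg = np.convolve(np.abs(delta[lo:hi, m]), kernel, mode="same")
            onset[live_ids[m]] = float(lo + int(seg.argmax()) + half)
        ordered = sorted(onset.items(), key=lambda kv: kv[1])
        for group in _split_onset_groups(ordered, split_gap):
            motifs.append(_motif_from(group, half))
    return motifs


def _split_onset_groups(
    ordered: list[tuple[str, float]], split_gap: int, min_size: int = 2
) -> list[list[tuple[str, float]]]:
    """Recursively split an onset-sorted CV group where two motions separate.

    A split requires the mean onsets of the two sides to differ by more than
    ``split_gap`` with at least ``min_size`` CVs on each side — pooling the
    members averages down the per-CV onset noise, so two closely spaced
    motions can be told apart without a single straggling estimate tearing a
    genuine group in two.
    """
    if len(ordered) < 2 * min_size:
        return [ordered]
    times = [tt for _, tt in ordered]
    best_i, best_sep = None, float(split_gap)
    for i in range(min_size, len(ordered) - min_size + 1):
        if times[i] - times[i - 1] < split_gap / 3:
            continue  # sides must not interleave
        sep = float(np.mean(times[i:]) - np.mean(times[:i]))
        if sep > best_sep:
            best_i, best_sep = i, sep
    if best_i is None:
        return [ordered]
    return _split_onset_groups(ordered[:best_i], split_gap, min_size) + _split_onset_groups(
        ordered[best_i:], split_gap, min_size
    )


def _motif_from(group: list[tuple[str, float]], half: int) -> Motif:
    times = [tt for _, tt in group]
    return Motif(
        start=int(min(times) - half // 2),
        end=int(max(times) + half // 2),
        onsets=dict(group),
    )


def segment_trajectory(
    cvm: CVMatrix,
    window: int = DEFAULT_WINDOW,
    transition_z: float = DEFAULT_TRANSITION_Z,
    min_part_length: int | None = None,
    gap_floor: int | None = None,
    split_gap: int | None = None,
) -> tuple[list[TrajectoryPart], list[list[str]], list[Motif]]:
    """Cut a trajectory into parts, one burst of concerted motion per part.

    Boundaries go at midpoints between consecutive motifs (see
    :func:`_find_motifs`), so a cut can never split one transition but does
    separate distinct motions even when they follow each other closely.
    Columns are standardized internally, making the result invariant under
    per-CV affine rescaling; near-constant columns never flag.  Parts shorter
    than ``min_part_length`` (default ``window``) are merged into a neighbor.

    Returns ``(parts, active_cvs_per_part, motifs)`` where the active CVs of
    a part are those of the motifs whose center falls inside it; with no
    transition activity a single part with no active CVs is returned.
    """
    if min_part_length is None:
        min_part_length = window
    if gap_floor is None:
        gap_floor = max(5, window // 4)
    if split_gap is None:
        split_gap = max(20, int(1.25 * window))
    t = cvm.n_frames
    motifs = _find_motifs(cvm, window, transition_z, gap_floor, split_gap)
    boundaries = [
        int((a.end + b.start) // 2) if a.end < b.start else int((a.center + b.center) // 2)
        for a, b in zip(motifs, motifs[1:])
    ]
    if motifs and t - 1 - motifs[-1].end >= window:
        # each transition's part ends in the plateau that follows it, so the
        # last burst of motion is also cut free of the trailing quiet stretch
        boundaries.append((motifs[-1].end + t - 1) // 2)
    boundaries = sorted({b for b in boundaries if 0 < b < t - 1})

    # assemble parts, merging any part shorter than min_part_length
    edges = [0] + [b + 1 for b in boundaries] + [t]
    merged = True
    while merged and len(edges) > 2:
        merged = False
        lengths = np.diff(edges)
        k = int(np.argmin(lengths))
        if lengths[k] < min_part_length:
            # drop the internal edge adjacent to the shorter neighbor
            if k == 0:
                del edges[1]
            elif k == len(lengths) - 1:
                del edges[-2]
            elif lengths[k - 1] <= lengths[k + 1]:
                del edges[k]
            else:
                del edges[k + 1]
            merged = True
    parts = [
        TrajectoryPart(cvm.trajectory_id, edges[i], edges[i + 1] - 1)
        for i in range(len(edges) - 1)
    ]
    actives: list[list[str]] = [[] for _ in parts]
    for motif in motifs:
        for i, part in enumerate(parts):
            if part.start_frame <= motif.center <= part.end_frame:
                actives[i] = sorted(set(actives[i]) | motif.cv_ids)
                break
    return parts, actives, motifs


def cut_trajectory(
    cvm: CVMatrix,
    window: int = DEFAULT_WINDOW,
    transition_z: float = DEFAULT_TRANSITION_Z,
    min_part_length: int | None = None,
) -> list[TrajectoryPart]:
    """Parts of :func:`segment_trajectory` (boundaries inside common plateaus)."""
    return segment_trajectory(
        cvm,
        window=window,
        transition_z=transition_z,
        min_part_length=min_part_length,
    )[0]
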