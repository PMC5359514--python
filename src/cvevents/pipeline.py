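"""End-to-end composition: CV matrices → parts → factors → order → consensus.

The per-replicate stage cuts each CV matrix into parts, factors each part
(standardize → principal factors → varimax → scores), keeps one-way factors,
and orders them in time (cross-correlation lags within a part, part order
across parts).  The cross-replicate stage matches factors by loading
congruence, extracts events, and aggregates the per-replicate orders into the
consensus staged sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import consensus as cns
from . import factors as fct
from . import ordering as ordg
from . import segmentation as seg
from .cv import CVMatrix

__all__ = [
    "PipelineParams",
    "PartAnalysis",
    "ReplicateAnalysis",
    "PipelineResult",
    "analyze_replicate",
    "analyze_dataset",
]


@dataclass
class PipelineParams:
    """All tunable thresholds of the analysis chain, with field defaults."""

    # segmentation
    window: int = seg.DEFAULT_WINDOW
    transition_z: float = seg.DEFAULT_TRANSITION_Z
    min_part_length: int | None = None  # defaults to 3 × window
    # factor model
    n_factors: int | str = "kaiser"
    varimax_tol: float = 1e-8
    varimax_max_iter: int = 1000
    min_ratio: float = fct.DEFAULT_MIN_RATIO
    min_rho: float = fct.DEFAULT_MIN_RHO
    # ordering
    max_lag: int | None = None  # None: (T_part - 1) // 3
    sig_k: float = ordg.DEFAULT_SIG_K
    min_lag: int = ordg.DEFAULT_MIN_LAG
    # consensus
    congruence_threshold: float = cns.DEFAULT_CONGRUENCE_THRESHOLD
    salient_loading: float = cns.DEFAULT_SALIENT_LOADING
    event_quorum: float = cns.DEFAULT_EVENT_QUORUM
    majority: float = cns.DEFAULT_MAJORITY
    minority_max: float = cns.DEFAULT_MINORITY_MAX
    event_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class PartAnalysis:
    part: seg.TrajectoryPart
    cv_ids: list[str]  # CVs retained after standardization
    dropped_cvs: list[str]
    model: fct.FactorModel | None  # None when the part is all-constant
    flags: list[fct.OneWayFlag] = field(default_factory=list)
    selected_factor_ids: list[str] = field(default_factory=list)
    lag_matrix: ordg.LagMatrix | None = None
    sequence_groups: list[frozenset[str]] = field(default_factory=list)


@dataclass
class ReplicateAnalysis:
    trajectory_id: str
    parts: list[PartAnalysis]
    factors: cns.TrajectoryFactors


@dataclass
class PipelineResult:
    replicates: list[ReplicateAnalysis]
    match: cns.FactorMatch
    events: cns.EventAssignment
    consensus: cns.ConsensusSequence
    #: per-trajectory event order (tie-groups of event labels)
    event_sequences: dict[str, list[frozenset[str]]]


def _extended_scores(
    cvm: CVMatrix,
    part: seg.TrajectoryPart,
    cols: list[int],
    part_values: np.ndarray,
    loadings: np.ndarray,
    window: int,
) -> np.ndarray:
    """Factor scores over the part plus one window of flanking frames.

    The flanking frames are standardized with the part's own mean/SD so the
    projection is consistent with the fitted loadings.
    """
    lo = max(0, part.start_frame - window)
    hi = min(cvm.n_frames, part.end_frame + 1 + window)
    ext = cvm.values[lo:hi][:, cols]
    mean = part_values.mean(axis=0)
    sd = part_values.std(axis=0)
    sd[sd <= 0] = 1.0
    x = (ext - mean) / sd
    gram = loadings.T @ loadings
    scores = x @ loadings @ np.linalg.inv(gram)
    return scores - scores.mean(axis=0)


def analyze_replicate(cvm: CVMatrix, params: PipelineParams | None = None) -> ReplicateAnalysis:
    """Segment one replicate and extract its ordered one-way factors.

    Each part is factored over its *active* CVs only — those whose own
    transition detector fires inside the part.  CVs sitting in a plateau
    throughout a part contribute no transition information there and would
    only inject noise dimensions into the correlation matrix.
    """
    params = params or PipelineParams()
    parts, actives, _motifs = seg.segment_trajectory(
        cvm,
        window=params.window,
        transition_z=params.transition_z,
        min_part_length=params.min_part_length,
    )
    analyses: list[PartAnalysis] = []
    all_groups: list[frozenset[str]] = []
    sel_ids: list[str] = []
    sel_loadings: list[np.ndarray] = []
    col_index = {c: i for i, c in enumerate(cvm.cv_ids)}
    for pi, (part, active_ids) in enumerate(zip(parts, actives)):
        if not active_ids:
            analyses.append(PartAnalysis(part, [], list(cvm.cv_ids), model=None))
            continue
        cols = [col_index[c] for c in active_ids]
        values = cvm.values[part.start_frame : part.end_frame + 1][:, cols]
        try:
            sp = fct.standardize(values, active_ids)
        except ValueError:
            # all-constant part (possible at vanishing noise): nothing to factor
            analyses.append(
                PartAnalysis(part, [], list(cvm.cv_ids), model=None)
            )
            continue
        model = fct.extract_factors(sp.X, k=params.n_factors)
        rotated, rotation, _ = fct.varimax_rotate(
            model.loadings, tol=params.varimax_tol, max_iter=params.varimax_max_iter
        )
        scores = fct.compute_scores(sp.X, rotated)
        # sign convention: every factor's score increases in time
        tgrid = np.arange(scores.shape[0])
        for j in range(scores.shape[1]):
            rho = stats.spearmanr(tgrid, scores[:, j]).statistic
            if np.isfinite(rho) and rho < 0:
                scores[:, j] *= -1.0
                rotated[:, j] *= -1.0
                rotation[:, j] *= -1.0
        model.loadings = rotated
        model.rotation = rotation
        model.scores = scores
        model.cv_ids = sp.cv_ids
        # one-way selection is judged on the part extended by one window on
        # each side: a transition sitting right at a part boundary (common
        # when two motions were separated by a narrow plateau) regains its
        # flanking levels, which the displacement and trend statistics need
        kept_cols = [col_index[c] for c in sp.cv_ids]
        kept_values = cvm.values[part.start_frame : part.end_frame + 1][:, kept_cols]
        ext_scores = _extended_scores(cvm, part, kept_cols, kept_values, rotated, params.window)
        flags = fct.select_one_way_factors(
            ext_scores, min_ratio=params.min_ratio, min_rho=params.min_rho
        )
        selected = [f.factor_index for f in flags if f.selected]
        fids = [f"p{pi}f{j}" for j in selected]
        pa = PartAnalysis(
            part,
            sp.cv_ids,
            sp.dropped_cvs,
            model=model,
            flags=flags,
            selected_factor_ids=fids,
        )
        if len(selected) >= 2:
            lm = ordg.build_lag_matrix(
                scores[:, selected],
                factor_ids=fids,
                max_lag=params.max_lag,
                sig_k=params.sig_k,
            )
            pa.lag_matrix = lm
            pa.sequence_groups = ordg.order_factors(lm, min_lag=params.min_lag).groups
        elif len(selected) == 1:
            pa.sequence_groups = [frozenset(fids)]
        analyses.append(pa)
        all_groups.extend(pa.sequence_groups)
        # full-CV-space loading vectors (zeros for dropped CVs)
        col_of = {c: i for i, c in enumerate(sp.cv_ids)}
        for j in selected:
            vec = np.zeros(len(cvm.cv_ids))
            for i_full, c in enumerate(cvm.cv_ids):
                if c in col_of:
                    vec[i_full] = rotated[col_of[c], j]
            sel_ids.append(f"p{pi}f{j}")
            sel_loadings.append(vec)
    factors = cns.TrajectoryFactors(
        trajectory_id=cvm.trajectory_id,
        cv_ids=list(cvm.cv_ids),
        factor_ids=sel_ids,
        loadings=np.column_stack(sel_loadings) if sel_loadings else np.zeros((len(cvm.cv_ids), 0)),
        sequence=ordg.FactorSequence(groups=all_groups),
    )
    return ReplicateAnalysis(trajectory_id=cvm.trajectory_id, parts=analyses, factors=factors)


def analyze_dataset(
    cvms: list[CVMatrix], params: PipelineParams | None = None
) -> PipelineResult:
    """Run the full chain on a replicate ensemble and build the consensus."""
    params = params or PipelineParams()
    if len(cvms) < 3:
        raise ValueError("need at least 3 replicates for a consensus analysis")
    replicates = [analyze_replicate(c, params) for c in cvms]
    models = [r.factors for r in replicates]
    match = cns.match_factors(
        models,
        threshold=params.congruence_threshold,
        salient_loading=params.salient_loading,
    )
    events = cns.assign_events(
        match,
        models,
        q=params.event_quorum,
        labels=params.event_labels or None,
        salient_loading=params.salient_loading,
    )
    peaks = cns.peak_factor_table(models, params.salient_loading)
    event_sequences: dict[str, list[frozenset[str]]] = {}
    for r in replicates:
        positions: dict[str, int] = {}
        for label, members in events.events.items():
            loc = cns.event_position(r.factors, members, peaks[r.trajectory_id])
            if loc is not None:
                positions[label] = loc[1]
        groups = [
            frozenset(lbl for lbl, p in positions.items() if p == gi)
            for gi in sorted(set(positions.values()))
        ]
        event_sequences[r.trajectory_id] = groups
    consensus = cns.build_consensus(
        event_sequences, majority=params.majority, minority_max=params.minority_max
    )
    return PipelineResult(
        replicates=replicates,
        match=match,
        events=events,
        consensus=consensus,
        event_sequences=event_sequences,
    )
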