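"""Cross-replicate factor matching, event extraction, and consensus ordering.

Replicate trajectories of the same transition produce similar but not
identical factor structures.  Factors are matched across replicates by the
Tucker congruence of their loading vectors; a *common factor* is a class of
mutually congruent factors, an *event* is the set of CVs that attain their
maximum |loading| on the same common factor in (nearly) every replicate, and
the consensus sequence is the majority partial order of events over the
per-replicate orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .ordering import FactorSequence

__all__ = [
    "TrajectoryFactors",
    "FactorMatch",
    "EventAssignment",
    "ConsensusSequence",
    "tucker_congruence",
    "match_factors",
    "peak_factor_table",
    "event_position",
    "assign_events",
    "build_consensus",
]

DEFAULT_CONGRUENCE_THRESHOLD = 0.85
DEFAULT_EVENT_QUORUM = 0.85
DEFAULT_MAJORITY = 0.75
#: loadings below this magnitude are treated as non-salient when comparing
#: factors across replicates: a factor's identity is carried by the variables
#: it loads strongly, and with few salient CVs the incidental near-zero
#: loadings of the remaining variables would otherwise dominate the
#: congruence denominator
DEFAULT_SALIENT_LOADING = 0.4


@dataclass
class TrajectoryFactors:
    """Selected factors of one trajectory, in a CV space shared across replicates.

    ``loadings`` columns follow ``factor_ids``; rows follow ``cv_ids``.  CVs
    dropped in some part carry zero loadings there, which keeps replicates
    comparable.  ``sequence`` is the within-trajectory temporal order.
    """

    trajectory_id: str
    cv_ids: list[str]
    factor_ids: list[str]
    loadings: np.ndarray  # (M, k)
    sequence: FactorSequence

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape != (len(self.cv_ids), len(self.factor_ids)):
            raise ValueError("loadings shape inconsistent with cv_ids × factor_ids")


@dataclass
class FactorMatch:
    common_ids: list[str]
    reference_trajectory: str
    #: trajectory -> {factor_id -> common_id}, injective per trajectory
    mapping: dict[str, dict[str, str]]
    #: trajectory -> {factor_id -> signed Tucker congruence of the accepted link}
    congruence: dict[str, dict[str, float]]


@dataclass
class EventAssignment:
    #: event label -> CV ids that peak on the event's common factor
    events: dict[str, frozenset[str]]
    residual_cvs: list[str]
    #: event label -> common factor id it was built from
    common_factor: dict[str, str] = field(default_factory=dict)


@dataclass
class ConsensusSequence:
    stages: list[frozenset[str]]
    #: (e, f) -> fraction of co-observing trajectories with e strictly before f
    support: dict[tuple[str, str], float]
    n_observed: dict[tuple[str, str], int]
    unobserved_pairs: list[tuple[str, str]]

    def __str__(self) -> str:
        return "; ".join(
            f"({i + 1}) " + " and ".join(sorted(stage)) for i, stage in enumerate(self.stages)
        )

    def to_dict(self) -> dict:
        return {
            "stages": [sorted(s) for s in self.stages],
            "support": {f"{e}<{f}": v for (e, f), v in sorted(self.support.items())},
            "n_observed": {f"{e},{f}": v for (e, f), v in sorted(self.n_observed.items())},
            "unobserved_pairs": [list(p) for p in self.unobserved_pairs],
        }


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence φ(a, b) = Σaᵢbᵢ / √(Σaᵢ² · Σbᵢ²) of two loading vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = float(a @ a)
    nb = float(b @ b)
    if na <= 0 or nb <= 0:
        raise ValueError("congruence undefined for a zero loading vector")
    return float(a @ b / np.sqrt(na * nb))


def _salient(vec: np.ndarray, cutoff: float) -> np.ndarray:
    masked = np.where(np.abs(vec) >= cutoff, vec, 0.0)
    return masked if np.any(masked) else vec


def match_factors(
    models: list[TrajectoryFactors],
    threshold: float = DEFAULT_CONGRUENCE_THRESHOLD,
    salient_loading: float = DEFAULT_SALIENT_LOADING,
) -> FactorMatch:
    """Match factors across trajectories by maximal total |Tucker congruence|.

    The trajectory with the most selected factors serves as the reference; its
    factors (in temporal order) define the common factors.  Every other
    trajectory's factors are linked one-to-one to common factors by optimal
    assignment on |φ| (sign-blind: a factor and its mirror image describe the
    same motion); links with |φ| below ``threshold`` are dropped.  Congruence
    is computed on salient loadings only (entries with magnitude ≥
    ``salient_loading``; pass 0 to disable the mask).
    """
    if len(models) < 2:
        raise ValueError("need at least 2 trajectories to match factors")
    cv_ids = models[0].cv_ids
    for m in models:
        if m.cv_ids != cv_ids:
            raise ValueError("all trajectories must share the same CV id list")
    ids = [m.trajectory_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trajectory ids")
    ref = max(models, key=lambda m: (len(m.factor_ids), m.trajectory_id))
    # common factors in the reference's own temporal order
    ref_order = sorted(
        ref.factor_ids, key=lambda f: (ref.sequence.position(f), ref.factor_ids.index(f))
    )
    common_ids = [f"CF{i + 1}" for i in range(len(ref_order))]
    ref_cols = {
        f: _salient(ref.loadings[:, ref.factor_ids.index(f)], salient_loading)
        for f in ref_order
    }

    mapping: dict[str, dict[str, str]] = {}
    congruence: dict[str, dict[str, float]] = {}
    any_link = False
    for m in models:
        mapping[m.trajectory_id] = {}
        congruence[m.trajectory_id] = {}
        if m is ref:
            for f, cf in zip(ref_order, common_ids):
                mapping[m.trajectory_id][f] = cf
                congruence[m.trajectory_id][f] = 1.0
            any_link = True
            continue
        if not m.factor_ids:
            continue
        phi = np.array(
            [
                [
                    tucker_congruence(_salient(m.loadings[:, a], salient_loading), ref_cols[f])
                    for f in ref_order
                ]
                for a in range(len(m.factor_ids))
            ]
        )
        rows, cols = linear_sum_assignment(-np.abs(phi))
        for r, c in zip(rows, cols):
            if abs(phi[r, c]) >= threshold:
                mapping[m.trajectory_id][m.factor_ids[r]] = common_ids[c]
                congruence[m.trajectory_id][m.factor_ids[r]] = float(phi[r, c])
                any_link = True
    if not any_link:
        warnings.warn("no factor pair reached the congruence threshold; empty match")
    return FactorMatch(
        common_ids=common_ids,
        reference_trajectory=ref.trajectory_id,
        mapping=mapping,
        congruence=congruence,
    )


def peak_factor_table(
    models: list[TrajectoryFactors],
    salient_loading: float = DEFAULT_SALIENT_LOADING,
) -> dict[str, dict[str, str]]:
    """Per trajectory, the factor on which each CV attains its maximum |loading|.

    Only salient peaks (|loading| ≥ ``salient_loading``) are recorded, and
    only factors carrying at least two salient loadings compete: a factor
    that moves a single CV is not a collective motion (its loading is ±1 by
    construction and would always win), and a CV with no eligible salient
    peak in a trajectory is simply not observed there.
    """
    table: dict[str, dict[str, str]] = {}
    for m in models:
        peaks: dict[str, str] = {}
        if m.factor_ids:
            absl = np.abs(m.loadings)
            eligible = (absl >= salient_loading).sum(axis=0) >= 2  # per factor
            masked = np.where(eligible[None, :], absl, -np.inf)
            cols = masked.argmax(axis=1)
            for i_cv, col in enumerate(cols):
                if np.isfinite(masked[i_cv, col]) and masked[i_cv, col] >= salient_loading:
                    peaks[m.cv_ids[i_cv]] = m.factor_ids[col]
        table[m.trajectory_id] = peaks
    return table


def event_position(
    model: TrajectoryFactors, members: frozenset[str] | set[str], peaks: dict[str, str]
) -> tuple[str, int] | None:
    """Locate an event inside one trajectory: its modal peak factor and the
    factor's tie-group index, or ``None`` when no member CV peaks saliently
    (the event is unobserved there) or the members disagree without majority.
    """
    counts: dict[str, int] = {}
    for cv in members:
        f = peaks.get(cv)
        if f is not None:
            counts[f] = counts.get(f, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    winners = sorted(f for f, c in counts.items() if c == best)
    if len(winners) > 1:
        return None  # split without majority: ambiguous in this trajectory
    return winners[0], model.sequence.position(winners[0])


def _copeak_clusters(
    cv_ids: list[str],
    copeak: dict[frozenset[str], tuple[int, int]],
    q: float,
) -> list[set[str]]:
    """Average-linkage agglomeration of CVs by co-peak fraction.

    Two clusters merge while the observation-weighted mean co-peak fraction
    across their CV pairs stays at or above ``q``; pairs never co-observed
    contribute no evidence either way.  Average linkage (rather than
    single-link components) keeps one noisy pair from chaining two groups
    whose members otherwise peak apart.
    """
    clusters: list[set[str]] = [{c} for c in cv_ids]

    def linkage(c1: set[str], c2: set[str]) -> float | None:
        same = both = 0
        for a in c1:
            for b in c2:
                stat = copeak.get(frozenset((a, b)))
                if stat is not None:
                    same += stat[0]
                    both += stat[1]
        return same / both if both else None

    while len(clusters) > 1:
        best, best_link = None, q
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = linkage(clusters[i], clusters[j])
                if link is not None and link >= best_link:
                    best, best_link = (i, j), link
        if best is None:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters


def assign_events(
    match: FactorMatch,
    models: list[TrajectoryFactors],
    q: float = DEFAULT_EVENT_QUORUM,
    labels: dict[str, str] | None = None,
    salient_loading: float = DEFAULT_SALIENT_LOADING,
    min_event_support: int = 2,
) -> EventAssignment:
    """Group CVs into events by consistent co-peaking across replicates.

    Two CVs belong to the same event when their maximum |loading| lands on
    the *same factor* in at least a fraction ``q`` of the trajectories where
    both are saliently observed.  Events are the connected components (of at
    least two CVs) of this relation; this needs no reference trajectory and
    tolerates replicates in which nearly simultaneous events merge into one
    factor — such replicates lower the cross-event co-peak fraction seen by
    the quorum, and the split replicates keep the events apart.  Single CVs
    and CVs never saliently observed go to the residual list.

    Events are labeled E1..Ek in order of their mean temporal position across
    trajectories (``labels`` renames them); ``common_factor`` records, where
    determined, the matched common factor the event peaks on in the
    reference trajectory.
    """
    cv_ids = models[0].cv_ids
    peaks = peak_factor_table(models, salient_loading)
    if not any(peaks.values()):
        raise ValueError("no salient factor peaks in any trajectory; no events to assign")
    copeak: dict[frozenset[str], tuple[int, int]] = {}
    for i, a in enumerate(cv_ids):
        for b in cv_ids[i + 1 :]:
            n_both = n_same = 0
            for t in peaks:
                fa, fb = peaks[t].get(a), peaks[t].get(b)
                if fa is not None and fb is not None:
                    n_both += 1
                    n_same += fa == fb
            if n_both >= min_event_support:
                copeak[frozenset((a, b))] = (n_same, n_both)
    components = [
        frozenset(c) for c in _copeak_clusters(cv_ids, copeak, q) if len(c) >= 2
    ]

    # temporal order of events: mean normalized tie-group position across replicates
    by_id = {m.trajectory_id: m for m in models}
    mean_pos = {}
    for comp in components:
        pos = []
        for t, m in by_id.items():
            loc = event_position(m, comp, peaks[t])
            if loc is not None:
                n_groups = max(len(m.sequence.groups), 1)
                pos.append(loc[1] / n_groups)
        mean_pos[comp] = float(np.mean(pos)) if pos else np.inf
    components.sort(key=lambda c: (mean_pos[c], sorted(c)))
    label_of = {comp: f"E{i + 1}" for i, comp in enumerate(components)}
    if labels:
        label_of = {comp: labels.get(lbl, lbl) for comp, lbl in label_of.items()}

    # where determinable, tie each event to the reference trajectory's common factor
    common: dict[str, str] = {}
    ref = by_id.get(match.reference_trajectory)
    if ref is not None:
        fmap = match.mapping.get(ref.trajectory_id, {})
        for comp in components:
            loc = event_position(ref, comp, peaks[ref.trajectory_id])
            if loc is not None and loc[0] in fmap:
                common[label_of[comp]] = fmap[loc[0]]

    assigned = set().union(*components) if components else set()
    return EventAssignment(
        events={label_of[c]: c for c in components},
        residual_cvs=[c for c in cv_ids if c not in assigned],
        common_factor=common,
    )


#: a precedence is vetoed when the opposite strict order shows up in more
#: than this fraction of the strictly ordered trajectories: events of the
#: same stage are exactly those whose order keeps flipping between runs
DEFAULT_MINORITY_MAX = 0.2


def build_consensus(
    sequences: dict[str, list[frozenset[str] | set[str]]],
    majority: float = DEFAULT_MAJORITY,
    minority_max: float = DEFAULT_MINORITY_MAX,
) -> ConsensusSequence:
    """Aggregate per-trajectory event orders into a staged consensus sequence.

    For each event pair the support of "e precedes f" is computed over the
    trajectories observing both: a trajectory whose tie-groups place e
    strictly before f contributes 1, one placing them in the same group
    contributes ½ to each direction (the Kendall treatment of ties).  A pair
    becomes a precedence arc when one direction reaches ``majority`` support
    *and* the opposite strict order occurs in at most ``minority_max`` of the
    strictly ordered trajectories — events that genuinely share a stage are
    recognizable precisely by their order flipping between replicates, however
    lopsided the flip count happens to be.  All other pairs are ties.  Cycles
    and ties are contracted into stages and the stages totally ordered.
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 trajectories for a consensus")
    positions: dict[str, dict[str, int]] = {}
    for t, groups in sequences.items():
        pos = {}
        for i, g in enumerate(groups):
            for e in g:
                if e in pos:
                    raise ValueError(f"trajectory {t}: event {e} appears twice")
                pos[e] = i
        positions[t] = pos
    events = sorted({e for pos in positions.values() for e in pos})
    if not events:
        raise ValueError("no events observed in any trajectory")
    support: dict[tuple[str, str], float] = {}
    n_observed: dict[tuple[str, str], int] = {}
    unobserved = []
    g = nx.DiGraph()
    g.add_nodes_from(events)
    for a_i, e in enumerate(events):
        for f in events[a_i + 1 :]:
            both = [t for t in positions if e in positions[t] and f in positions[t]]
            n_observed[(e, f)] = len(both)
            if not both:
                unobserved.append((e, f))
                g.add_edge(e, f)
                g.add_edge(f, e)
                continue
            n_ef = sum(1 for t in both if positions[t][e] < positions[t][f])
            n_fe = sum(1 for t in both if positions[t][f] < positions[t][e])
            n_tie = len(both) - n_ef - n_fe
            support[(e, f)] = (n_ef + 0.5 * n_tie) / len(both)
            support[(f, e)] = (n_fe + 0.5 * n_tie) / len(both)
            n_strict = n_ef + n_fe
            minority = min(n_ef, n_fe) / n_strict if n_strict else 0.0
            if support[(e, f)] >= majority and minority <= minority_max and n_ef > n_fe:
                g.add_edge(e, f)
            elif support[(f, e)] >= majority and minority <= minority_max and n_fe > n_ef:
                g.add_edge(f, e)
            else:
                g.add_edge(e, f)
                g.add_edge(f, e)
    cond = nx.condensation(g)
    order = list(nx.topological_sort(cond))
    stages = [frozenset(cond.nodes[c]["members"]) for c in order]
    return ConsensusSequence(
        stages=stages, support=support, n_observed=n_observed, unobserved_pairs=unobserved
    )
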