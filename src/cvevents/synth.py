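"""Synthetic data with planted ground truth.

Two families of fixtures:

* multivariate CV time series emulating replicate transition trajectories —
  sequential logistic transitions grouped into stages, replicate-to-replicate
  onset jitter, flat plateaus in between, and autocorrelated (AR(1))
  observation noise, with the planted onsets and staged order emitted as
  ground truth;
* toy structures and trajectories for the structural CV layer — ideal
  poly-alanine helices built from standard internal coordinates, and
  two-state logistic interpolations between a pair of conformations.

The default dataset mimics the bookkeeping of the PKA A-domain study:
26 CVs, seven planted transitions (the lettered events B, C1, D1, E, D2, F, G)
in five stages, 13 replicates of 3000 frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .cv import CVMatrix
from .pka import DEFAULT_CV_IDS
from .structures import AtomRecord, Structure, Trajectory

__all__ = [
    "EventSpec",
    "NoiseSpec",
    "SyntheticDataset",
    "generate_cv_dataset",
    "default_event_specs",
    "default_stage_centers",
    "default_dataset",
    "generate_ideal_helix",
    "generate_two_state_trajectory",
]

DEFAULT_T = 3000
DEFAULT_N_REPLICATES = 13
DEFAULT_WIDTH = 30.0  # frames
DEFAULT_JITTER_SD = 120.0  # frames
DEFAULT_NOISE_SD = 1.0
DEFAULT_AR_RHO = 0.9
DEFAULT_AMPLITUDE = 3.0  # = 3 × default noise SD

_AR_BURN_IN = 200


@dataclass(frozen=True)
class EventSpec:
    label: str
    stage: int
    amplitudes: dict[str, float]  # cv id -> signed amplitude, CV units
    width: float = DEFAULT_WIDTH  # logistic width, frames
    jitter_sd: float = DEFAULT_JITTER_SD  # onset SD across replicates, frames

    def __post_init__(self):
        if self.stage < 1:
            raise ValueError(f"event {self.label}: stage must be >= 1")
        if self.width <= 0:
            raise ValueError(f"event {self.label}: width must be positive")
        if not self.amplitudes:
            raise ValueError(f"event {self.label}: needs at least one member CV")

    @property
    def member_cv_ids(self) -> frozenset[str]:
        return frozenset(self.amplitudes)


@dataclass(frozen=True)
class NoiseSpec:
    sd: float = DEFAULT_NOISE_SD  # stationary observation SD per CV
    rho: float = DEFAULT_AR_RHO  # AR(1) coefficient
    seed: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class SyntheticDataset:
    replicates: list[CVMatrix]
    onsets: dict[str, dict[str, float]]  # replicate id -> {event label -> onset frame}
    stages: list[list[str]]  # planted staged order, stage 1 first
    event_cvs: dict[str, frozenset[str]]
    events: list[EventSpec] = field(default_factory=list)

    @property
    def cv_ids(self) -> list[str]:
        return self.replicates[0].cv_ids

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cvm in self.replicates:
            cvm.to_tsv(outdir / f"{cvm.trajectory_id}.tsv")
        truth = {
            "stages": self.stages,
            "onsets": self.onsets,
            "event_cvs": {k: sorted(v) for k, v in self.event_cvs.items()},
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))


def _logistic(u: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-u))


def _ar1(rng: np.random.Generator, t: int, sd: float, rho: float) -> np.ndarray:
    if sd == 0:
        return np.zeros(t)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=t + _AR_BURN_IN)
    x = lfilter([1.0], [1.0, -rho], eps)
    return x[_AR_BURN_IN:]


def generate_cv_dataset(
    events: list[EventSpec],
    n_replicates: int,
    T: int,
    noise: NoiseSpec,
    stage_centers: dict[int, float] | None = None,
    baselines: dict[str, float] | None = None,
    extra_cv_ids: list[str] | None = None,
    seed: int | None = None,
    max_redraws: int = 1000,
) -> SyntheticDataset:
    """Generate replicate CV matrices with planted staged transitions.

    CV m of replicate r is ``baseline + Σ_e amplitude_{e,m} · σ((t − τ(e,r)) / w_e)``
    plus AR(1) noise, with logistic σ.  Onsets are drawn per replicate as
    ``stage_center + N(0, jitter_sd)`` (jitter truncated at ±3 SD) and
    redrawn (up to ``max_redraws``)
    until every pair of events in different stages is in stage order.
    Identical seeds give bitwise-identical datasets.
    """
    labels = [e.label for e in events]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate event labels")
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if a.member_cv_ids & b.member_cv_ids:
                raise ValueError(
                    f"events {a.label} and {b.label} share CVs: "
                    f"{sorted(a.member_cv_ids & b.member_cv_ids)}"
                )
    stages_present = sorted({e.stage for e in events})
    if stage_centers is None:
        gap = T / (len(stages_present) + 1)
        stage_centers = {s: gap * (i + 1) for i, s in enumerate(stages_present)}
    max_w = max(e.width for e in events)
    if max(stage_centers.values()) + 5 * max_w >= T:
        raise ValueError("T too small: the last stage center + 5 widths must fit inside [0, T)")

    cv_ids = sorted({cv for e in events for cv in e.member_cv_ids})
    if extra_cv_ids:
        cv_ids = cv_ids + [c for c in extra_cv_ids if c not in cv_ids]
    baselines = baselines or {}
    rng = np.random.default_rng(noise.seed if seed is None else seed)

    stage_sorted = sorted(events, key=lambda e: e.stage)
    replicates = []
    onsets: dict[str, dict[str, float]] = {}
    tgrid = np.arange(T, dtype=float)
    for r in range(n_replicates):
        rep_id = f"rep{r + 1:02d}"
        for attempt in range(max_redraws):
            tau = {}
            for e in stage_sorted:
                jit = rng.normal(0.0, e.jitter_sd)
                while abs(jit) > 3.0 * e.jitter_sd:
                    jit = rng.normal(0.0, e.jitter_sd)
                tau[e.label] = stage_centers[e.stage] + jit
            ok = all(
                tau[a.label] < tau[b.label]
                for i, a in enumerate(stage_sorted)
                for b in stage_sorted[i + 1 :]
                if a.stage < b.stage
            )
            if ok:
                break
        else:
            raise RuntimeError(
                f"replicate {rep_id}: could not draw stage-ordered onsets in {max_redraws} tries"
            )
        values = np.empty((T, len(cv_ids)))
        for m, cv in enumerate(cv_ids):
            signal = np.full(T, baselines.get(cv, 0.0))
            for e in events:
                amp = e.amplitudes.get(cv)
                if amp is not None:
                    signal = signal + amp * _logistic((tgrid - tau[e.label]) / e.width)
            values[:, m] = signal + _ar1(rng, T, noise.sd, noise.rho)
        replicates.append(
            CVMatrix(trajectory_id=rep_id, times=tgrid.copy(), cv_ids=list(cv_ids), values=values)
        )
        onsets[rep_id] = {k: float(v) for k, v in tau.items()}

    stages = [
        [e.label for e in events if e.stage == s] for s in stages_present
    ]
    return SyntheticDataset(
        replicates=replicates,
        onsets=onsets,
        stages=stages,
        event_cvs={e.label: e.member_cv_ids for e in events},
        events=list(events),
    )


# --------------------------------------------------------------------------
# default dataset mimicking the A-domain study conditions
# --------------------------------------------------------------------------

# signed amplitude pattern per event over the default 26-CV set; signs follow
# the direction each observable moves during the H→B transition
_DEFAULT_EVENT_TABLE: list[tuple[str, int, dict[str, float]]] = [
    ("B", 1, {
        "d_A202N_cAMP_O6": -1, "d_G199O_A202N": +1, "d_L203_pocket": -1,
        "frac_alpha_pbc": +1, "rmsd_pbc": -1,
    }),
    ("C1", 2, {
        "d_sc_L135_L203": +1, "d_sc_L135_I204": +1,
        "d_sc_F136_L203": +1, "d_sc_F136_I204": +1,
    }),
    ("D1", 2, {
        "angle_bc_helix": +1, "d_Y229_L203": -1, "d_R226_D170": +1,
    }),
    ("E", 3, {
        "e_Y229_beta": -1, "d_R209_D170": -1,
    }),
    ("D2", 4, {
        "d_ca_L135_I204": +1, "d_N3A_PBC": +1, "rmsd_n3a": -1, "rmsd_bc_helix": -1,
    }),
    ("F", 4, {
        "frac_310_bc_turn": -1, "frac_alpha_bc_turn": -1, "frac_pi_bc_turn": +1,
        "d_L233_cluster": -1, "d_M234_I204": -1,
    }),
    ("G", 5, {
        "d_R241_E200": -1, "d_L238_I204": -1, "rmsd_domain": -1,
    }),
]

#: planted staged order of the default dataset
DEFAULT_STAGES: list[list[str]] = [["B"], ["C1", "D1"], ["E"], ["D2", "F"], ["G"]]


def default_event_specs(
    amplitude: float = DEFAULT_AMPLITUDE,
    width: float = DEFAULT_WIDTH,
    jitter_sd: float = DEFAULT_JITTER_SD,
) -> list[EventSpec]:
    specs = []
    for label, stage, signs in _DEFAULT_EVENT_TABLE:
        specs.append(
            EventSpec(
                label=label,
                stage=stage,
                amplitudes={cv: s * amplitude for cv, s in signs.items()},
                width=width,
                jitter_sd=jitter_sd,
            )
        )
    covered = set().union(*(s.member_cv_ids for s in specs))
    assert covered == set(DEFAULT_CV_IDS), "default events must cover the default CV set"
    return specs


def default_stage_centers(T: int = DEFAULT_T) -> dict[int, float]:
    """Stage centers 400, 900, ..., 2400 for the default T = 3000 (scaled with T)."""
    scale = T / DEFAULT_T
    return {s: (400.0 + (s - 1) * 500.0) * scale for s in range(1, 6)}


def default_dataset(
    seed: int,
    n_replicates: int = DEFAULT_N_REPLICATES,
    T: int = DEFAULT_T,
    noise_scale: float = 1.0,
) -> SyntheticDataset:
    """The default replicate ensemble: 26 CVs, 7 planted events in 5 stages.

    ``noise_scale`` multiplies the observation noise SD while leaving the
    planted amplitudes fixed (the degradation axis); at 1.0 the amplitudes
    are 3 × the noise SD.
    """
    return generate_cv_dataset(
        events=default_event_specs(),
        n_replicates=n_replicates,
        T=T,
        noise=NoiseSpec(sd=DEFAULT_NOISE_SD * noise_scale, rho=DEFAULT_AR_RHO),
        stage_centers=default_stage_centers(T),
        seed=seed,
    )


# --------------------------------------------------------------------------
# toy structures and trajectories
# --------------------------------------------------------------------------

# standard backbone internal coordinates (lengths Å, angles degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement: position D with |CD| = bond, ∠BCD = angle, dihedral(A,B,C,D) = torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(angle), np.sin(angle) * np.cos(torsion), np.sin(angle) * np.sin(torsion)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def generate_ideal_helix(
    n_res: int, phi: float, psi: float, chain: str = "A", start_resid: int = 1
) -> Structure:
    """Backbone-only poly-alanine chain with uniform (φ, ψ) and ω = 180°.

    (−57, −47) gives an ideal α-helix, (−49, −26) a 3₁₀-helix, (−57, −70) a
    π-helix, (180, 180) a fully extended chain.
    """
    if n_res < 6:
        raise ValueError(f"need at least 6 residues, got {n_res}")
    # seed residue placed explicitly in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [[n0, ca0, c0]]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_new = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_new = _place_atom(ca_prev, c_prev, n_new, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_new = _place_atom(c_prev, n_new, ca_new, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append([n_new, ca_new, c_new])
    atoms = []
    serial = 1
    for i, (n, ca, c) in enumerate(backbone):
        resid = start_resid + i
        o = _place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi - 180.0)
        for name, pos in (("N", n), ("CA", ca), ("C", c), ("O", o)):
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    residue_name="ALA",
                    residue_number=resid,
                    chain=chain,
                    element=name[0],
                    position=pos,
                )
            )
            serial += 1
    return Structure(atoms, title=f"ideal_helix_phi{phi:g}_psi{psi:g}")


def generate_two_state_trajectory(
    a: Structure,
    b: Structure,
    T: int,
    switch_center: float,
    switch_width: float,
    noise_sd: float = 0.0,
    seed: int | None = None,
    frame_interval: float = 1.0,
) -> Trajectory:
    """Logistic interpolation between two atom-matched conformations.

    Frame t is ``a + σ((t − center)/width) · (b − a)`` plus isotropic Gaussian
    jitter of SD ``noise_sd`` per coordinate.
    """
    if len(a) != len(b):
        raise ValueError(f"structures have {len(a)} vs {len(b)} atoms")
    for x, y in zip(a.atoms, b.atoms):
        if (x.name, x.residue_number, x.chain) != (y.name, y.residue_number, y.chain):
            raise ValueError(
                f"atom mismatch: {x.chain}/{x.residue_number}/{x.name} vs "
                f"{y.chain}/{y.residue_number}/{y.name}"
            )
    if switch_width <= 0:
        raise ValueError("switch_width must be positive")
    rng = np.random.default_rng(seed)
    frac = _logistic((np.arange(T) - switch_center) / switch_width)
    delta = b.coords - a.coords
    frames = a.coords[None, :, :] + frac[:, None, None] * delta[None, :, :]
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, size=frames.shape)
    return Trajectory(topology=a, frames=frames, frame_interval=frame_interval)
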