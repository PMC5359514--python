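"""Collective variables (CVs) over structures and trajectories.

Each CV maps one coordinate frame to a scalar: inter-atom and inter-centroid
distances, backbone-segment RMSD to a reference conformation, helix rotation
angles, helix-form fractions (3₁₀/α/π content of a residue stretch), and a
pairwise contact-energy proxy.  Evaluating a list of CV definitions over a
trajectory yields a :class:`CVMatrix` — the T×M table that the downstream
segmentation/factor/ordering stages consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .structures import (
    DegenerateGeometryError,
    Selection,
    SelectionError,
    Structure,
    Trajectory,
    superpose,
)

__all__ = [
    "CVDefinition",
    "CVMatrix",
    "HelixForm",
    "CVEvaluationError",
    "eval_distance",
    "eval_centroid_distance",
    "classify_helix_form",
    "helix_form_fraction",
    "eval_segment_rmsd",
    "eval_helix_rotation",
    "eval_contact_energy",
    "evaluate_cvs",
]

CV_KINDS = (
    "atom_distance",
    "ca_distance",
    "hbond_distance",
    "centroid_distance",
    "segment_rmsd",
    "helix_rotation",
    "helix_form_fraction",
    "contact_energy",
)

# kinds that measure a single-atom-to-single-atom distance
_ATOM_DISTANCE_KINDS = ("atom_distance", "ca_distance", "hbond_distance")


class HelixForm(str, Enum):
    THREE_TEN = "three_ten"
    ALPHA = "alpha"
    PI = "pi"
    OTHER = "other"


class CVEvaluationError(RuntimeError):
    """Hard failure while evaluating a CV on a frame."""


@dataclass(frozen=True)
class HelixFormLabel:
    residue_number: int
    form: HelixForm


@dataclass
class CVDefinition:
    """Declarative definition of one collective variable.

    ``selections`` carries one or two selection expressions depending on
    ``kind``; ``reference`` is required for ``segment_rmsd`` and
    ``helix_rotation``; ``params`` holds kind-specific constants
    (``residue_range``, ``form``, ``cutoff`` ...).
    """

    id: str
    kind: str
    selections: tuple[str, ...] = ()
    reference: Structure | None = None
    params: dict = field(default_factory=dict)
    unit: str = ""

    def __post_init__(self):
        if self.kind not in CV_KINDS:
            raise ValueError(f"CV {self.id}: unknown kind {self.kind!r}")
        self.selections = tuple(self.selections)
        needs_ref = self.kind in ("segment_rmsd", "helix_rotation")
        if needs_ref and self.reference is None:
            raise ValueError(f"CV {self.id}: kind {self.kind} requires a reference structure")
        if not needs_ref and self.reference is not None:
            raise ValueError(f"CV {self.id}: kind {self.kind} takes no reference structure")


@dataclass
class CVMatrix:
    """T×M collective-variable time series of one trajectory (mixed units)."""

    trajectory_id: str
    times: np.ndarray  # (T,), ps
    cv_ids: list[str]
    values: np.ndarray  # (T, M)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.times), len(self.cv_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.times)} times × {len(self.cv_ids)} cv_ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("CVMatrix contains non-finite values")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.cv_ids)
        df.insert(0, "time_ps", self.times)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path, trajectory_id: str | None = None) -> "CVMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        if "time_ps" not in df.columns:
            raise ValueError(f"{path}: missing 'time_ps' column")
        cv_ids = [c for c in df.columns if c != "time_ps"]
        return cls(
            trajectory_id=trajectory_id or path.stem,
            times=df["time_ps"].to_numpy(),
            cv_ids=cv_ids,
            values=df[cv_ids].to_numpy(),
        )


# --------------------------------------------------------------------------
# elementary CVs
# --------------------------------------------------------------------------


def eval_distance(frame: Structure, sel1: Selection | str, sel2: Selection | str) -> float:
    """Euclidean distance (Å) between two single-atom selections."""
    i = _as_selection(sel1).resolve_one(frame)
    j = _as_selection(sel2).resolve_one(frame)
    return float(np.linalg.norm(frame.coords[i] - frame.coords[j]))


def eval_centroid_distance(frame: Structure, sel1: Selection | str, sel2: Selection | str) -> float:
    """Distance (Å) between the geometric centroids of two atom groups."""
    g1 = _resolve_group(frame, sel1)
    g2 = _resolve_group(frame, sel2)
    return float(np.linalg.norm(frame.coords[g1].mean(axis=0) - frame.coords[g2].mean(axis=0)))


def _as_selection(sel: Selection | str) -> Selection:
    return sel if isinstance(sel, Selection) else Selection(sel)


def _resolve_group(frame: Structure, sel: Selection | str) -> np.ndarray:
    idx = _as_selection(sel).resolve(frame)
    if len(idx) == 0:
        raise SelectionError(f"selection {_as_selection(sel).expression!r} matched no atoms")
    return idx


# --------------------------------------------------------------------------
# helix-form classification
# --------------------------------------------------------------------------

#: donor-N to acceptor-O distance below which a backbone H-bond is assumed.
#: No angular term: crystallographic entries carry no hydrogens, so the
#: backbone N stands proxy for its amide H.
HBOND_CUTOFF = 3.5  # Å

# i -> i+n H-bond patterns; longer-range pattern wins when several match
_FORM_OFFSETS = ((HelixForm.PI, 5), (HelixForm.ALPHA, 4), (HelixForm.THREE_TEN, 3))


def classify_helix_form(
    frame: Structure,
    residue_range: tuple[int, int],
    chain: str | None = None,
    cutoff: float = HBOND_CUTOFF,
) -> list[HelixFormLabel]:
    """Label residues of ``residue_range`` as 3₁₀/α/π/other.

    Residue i is labeled by the shortest O(i)···N(i+n) contact pattern that
    satisfies the H-bond distance criterion, with precedence π > α > 3₁₀ when
    several patterns match.  Only residues whose i+3 partner exists in the
    structure are evaluated (interior residues); a residue with a missing
    backbone atom is labeled ``other`` with a warning.
    """
    lo, hi = residue_range
    if hi - lo + 1 < 6:
        raise ValueError(f"residue range {residue_range} too short (need ≥ 6 residues)")
    atom_pos: dict[tuple[int, str], np.ndarray] = {}
    for a in frame.atoms:
        if chain is not None and a.chain != chain:
            continue
        if a.name in ("N", "O"):
            atom_pos[(a.residue_number, a.name)] = a.position
    labels = []
    for i in range(lo, hi + 1):
        if any((i + off, "N") not in atom_pos for off in (3, 4, 5)):
            continue  # not interior: some acceptor pattern cannot be decided
        if (i, "O") not in atom_pos:
            warnings.warn(f"residue {i}: missing backbone O, labeling 'other'", stacklevel=2)
            labels.append(HelixFormLabel(i, HelixForm.OTHER))
            continue
        o = atom_pos[(i, "O")]
        form = HelixForm.OTHER
        for candidate, off in _FORM_OFFSETS:
            n = atom_pos.get((i + off, "N"))
            if n is not None and np.linalg.norm(o - n) < cutoff:
                form = candidate
                break
        labels.append(HelixFormLabel(i, form))
    return labels


def helix_form_fraction(
    frame: Structure,
    residue_range: tuple[int, int],
    form: HelixForm | str,
    chain: str | None = None,
    cutoff: float = HBOND_CUTOFF,
) -> float:
    """Fraction of evaluated residues in ``residue_range`` carrying ``form``."""
    form = HelixForm(form)
    labels = classify_helix_form(frame, residue_range, chain=chain, cutoff=cutoff)
    if not labels:
        return 0.0
    return sum(1 for l in labels if l.form == form) / len(labels)


# --------------------------------------------------------------------------
# segment RMSD and helix rotation
# --------------------------------------------------------------------------


def _matched_backbone(
    frame: Structure, reference: Structure, residue_range: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Backbone coordinates of ``residue_range`` matched atom-by-atom."""
    lo, hi = residue_range

    def index(s: Structure) -> dict[tuple[int, str], int]:
        return {
            (a.residue_number, a.name): i
            for i, a in enumerate(s.atoms)
            if lo <= a.residue_number <= hi and a.name in ("N", "CA", "C", "O")
        }

    fi, ri = index(frame), index(reference)
    common = sorted(fi.keys() & ri.keys())
    missing = sorted({r for r, _ in fi.keys() ^ ri.keys()})
    if not common:
        raise CVEvaluationError(
            f"no common backbone atoms in residue range {residue_range}; missing residues: {missing}"
        )
    if missing:
        # tolerate ragged termini but report residues absent from the reference
        absent_in_ref = sorted({r for r, _ in fi.keys() - ri.keys()})
        if absent_in_ref:
            raise CVEvaluationError(
                f"residues missing in reference for range {residue_range}: {absent_in_ref}"
            )
    x = frame.coords[[fi[k] for k in common]]
    y = reference.coords[[ri[k] for k in common]]
    return x, y


def eval_segment_rmsd(
    frame: Structure, residue_range: tuple[int, int], reference: Structure
) -> float:
    """Backbone RMSD (Å) of a residue range after least-squares superposition."""
    x, y = _matched_backbone(frame, reference, residue_range)
    _, _, rmsd = superpose(x, y)
    return rmsd


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    w, v = np.linalg.eigh(cov)
    if w[-1] < 2.0 * max(w[-2], 1e-12):
        raise DegenerateGeometryError(
            "segment has no well-defined long axis (near-spherical point set)"
        )
    return v[:, -1]


def eval_helix_rotation(
    frame: Structure,
    helix_range: tuple[int, int],
    reference: Structure,
    anchor_range: tuple[int, int],
) -> float:
    """Rotation angle (degrees, in [0, 90]) of a helix relative to a reference.

    The frame is first superposed on the reference over the backbone of
    ``anchor_range`` (the stationary scaffold); the returned angle is between
    the principal inertia axes of the helix backbone in the two structures.
    """
    if helix_range[1] - helix_range[0] + 1 < 6:
        raise ValueError(f"helix range {helix_range} too short (need ≥ 6 residues)")
    ax, ay = _matched_backbone(frame, reference, anchor_range)
    rot, trans, _ = superpose(ax, ay)
    hx, hy = _matched_backbone(frame, reference, helix_range)
    hx_aligned = hx @ rot.T + trans
    u = _principal_axis(hx_aligned)
    v = _principal_axis(hy)
    cosang = np.clip(abs(float(u @ v)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# --------------------------------------------------------------------------
# contact-energy proxy
# --------------------------------------------------------------------------

# per-element Lennard-Jones parameters: (epsilon kcal/mol, sigma Å)
LJ_PARAMS = {
    "C": (0.086, 3.40),
    "N": (0.170, 3.25),
    "O": (0.210, 2.96),
    "S": (0.250, 3.50),
    "H": (0.015, 2.00),
}
_LJ_DEFAULT = (0.100, 3.30)

COULOMB_CONST = 332.06  # kcal·Å/(mol·e²)
SCREENING_LENGTH = 10.0  # Å

# unit formal charges spread over the charged-group atoms
_FORMAL_CHARGES = {
    ("ARG", "NH1"): 0.5,
    ("ARG", "NH2"): 0.5,
    ("LYS", "NZ"): 1.0,
    ("ASP", "OD1"): -0.5,
    ("ASP", "OD2"): -0.5,
    ("GLU", "OE1"): -0.5,
    ("GLU", "OE2"): -0.5,
}


def _atom_charge(residue_name: str, atom_name: str) -> float:
    return _FORMAL_CHARGES.get((residue_name.upper(), atom_name.upper()), 0.0)


def eval_contact_energy(
    frame: Structure,
    group1: Selection | str,
    group2: Selection | str,
    screening_length: float = SCREENING_LENGTH,
) -> float:
    """Pairwise interaction-energy proxy (kcal/mol) between two atom groups.

    Sum over cross-pairs of a 12-6 dispersion–repulsion term with per-element
    parameters (Lorentz–Berthelot combination) plus a distance-screened
    electrostatic term with unit formal charges on charged side-chain groups.
    More negative means more favorable.  This is a consistent proxy, not a
    force-field energy: only relative changes along a trajectory are meaningful.
    """
    g1 = _resolve_group(frame, group1)
    g2 = _resolve_group(frame, group2)
    if set(g1) & set(g2):
        raise SelectionError("contact-energy groups overlap")
    coords = frame.coords
    eps1, sig1, q1 = _lj_arrays(frame, g1)
    eps2, sig2, q2 = _lj_arrays(frame, g2)
    d = np.linalg.norm(coords[g1][:, None, :] - coords[g2][None, :, :], axis=2)
    d = np.maximum(d, 1e-6)
    eps = np.sqrt(eps1[:, None] * eps2[None, :])
    sig = 0.5 * (sig1[:, None] + sig2[None, :])
    sr6 = (sig / d) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    e_el = COULOMB_CONST * q1[:, None] * q2[None, :] / d * np.exp(-d / screening_length)
    return float(np.sum(e_lj + e_el))


def _lj_arrays(frame: Structure, idx: np.ndarray):
    eps = np.empty(len(idx))
    sig = np.empty(len(idx))
    q = np.empty(len(idx))
    for k, i in enumerate(idx):
        a = frame.atoms[i]
        eps[k], sig[k] = LJ_PARAMS.get(a.element.upper(), _LJ_DEFAULT)
        q[k] = _atom_charge(a.residue_name, a.name)
    return eps, sig, q


# --------------------------------------------------------------------------
# trajectory evaluation
# --------------------------------------------------------------------------


def _eval_cv(frame: Structure, cv: CVDefinition) -> float:
    if cv.kind in _ATOM_DISTANCE_KINDS:
        return eval_distance(frame, cv.selections[0], cv.selections[1])
    if cv.kind == "centroid_distance":
        return eval_centroid_distance(frame, cv.selections[0], cv.selections[1])
    if cv.kind == "segment_rmsd":
        return eval_segment_rmsd(frame, tuple(cv.params["residue_range"]), cv.reference)
    if cv.kind == "helix_rotation":
        return eval_helix_rotation(
            frame,
            tuple(cv.params["helix_range"]),
            cv.reference,
            tuple(cv.params["anchor_range"]),
        )
    if cv.kind == "helix_form_fraction":
        return helix_form_fraction(
            frame,
            tuple(cv.params["residue_range"]),
            cv.params["form"],
            cutoff=cv.params.get("cutoff", HBOND_CUTOFF),
        )
    if cv.kind == "contact_energy":
        return eval_contact_energy(
            frame,
            cv.selections[0],
            cv.selections[1],
            screening_length=cv.params.get("screening_length", SCREENING_LENGTH),
        )
    raise ValueError(f"unhandled CV kind {cv.kind!r}")  # pragma: no cover


def evaluate_cvs(trajectory: Trajectory, defs: list[CVDefinition]) -> CVMatrix:
    """Evaluate every CV definition on every frame; column order = ``defs`` order."""
    ids = [d.id for d in defs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate CV ids")
    values = np.empty((trajectory.n_frames, len(defs)))
    for t in range(trajectory.n_frames):
        frame = trajectory.frame(t)
        for m, cv in enumerate(defs):
            try:
                values[t, m] = _eval_cv(frame, cv)
            except Exception as exc:
                raise CVEvaluationError(f"frame {t}, CV {cv.id!r}: {exc}") from exc
    return CVMatrix(
        trajectory_id=trajectory.topology.title or "trajectory",
        times=trajectory.times,
        cv_ids=ids,
        values=values,
    )
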