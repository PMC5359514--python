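"""Structures, trajectories, atom selections, and rigid-body superposition.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`AtomRecord` (the order defines the coordinate layout of every
trajectory frame), and a :class:`Trajectory` is a ``(T, N, 3)`` coordinate
array tied to its topology.  File I/O goes through biotite (PDB, including
multi-model files used as a plain-text trajectory fallback) and MDAnalysis
(DCD as the binary trajectory dialect).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "Selection",
    "PDBFormatError",
    "SelectionError",
    "DegenerateGeometryError",
    "TrajectoryMismatchError",
    "read_structure",
    "write_structure",
    "fetch_pdb",
    "read_trajectory",
    "write_trajectory",
    "superpose",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBFormatError(ValueError):
    """Raised when a structure file cannot be parsed."""


class SelectionError(ValueError):
    """Raised when a selection expression is invalid or resolves unexpectedly."""


class DegenerateGeometryError(ValueError):
    """Raised when point sets are too degenerate for a unique superposition."""


class TrajectoryMismatchError(ValueError):
    """Raised when trajectory frames do not match the topology atom count."""


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    element: str
    position: np.ndarray
    insertion_code: str = ""

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial} {self.name}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def residue_key(self) -> tuple[str, str]:
        return (self.chain, f"{self.residue_number}{self.insertion_code}")


@dataclass
class Structure:
    """Ordered collection of atoms; the order defines the frame layout."""

    atoms: list[AtomRecord]
    title: str = ""
    _coords: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("Structure must contain at least one atom")
        keys = [(a.chain, a.residue_number, a.insertion_code, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom key {dup} in structure")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} does not match {len(self.atoms)} atoms")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, title=title if title is not None else self.title)

    def subset(self, indices: np.ndarray, title: str = "") -> "Structure":
        return Structure([self.atoms[i] for i in indices], title=title or self.title)

    def select(self, selection: "Selection | str") -> np.ndarray:
        if isinstance(selection, str):
            selection = Selection(selection)
        return selection.resolve(self)

    def residues(self) -> list[tuple[str, int, str, str]]:
        """(chain, residue_number, insertion_code, residue_name) in first-seen order."""
        out, seen = [], set()
        for a in self.atoms:
            k = (a.chain, a.residue_number, a.insertion_code, a.residue_name)
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out


@dataclass
class Trajectory:
    topology: Structure
    frames: np.ndarray  # (T, N, 3), Å
    frame_interval: float = 1.0  # ps

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (T, N, 3), got {self.frames.shape}")
        if self.frames.shape[1] != len(self.topology):
            raise TrajectoryMismatchError(
                f"frames have {self.frames.shape[1]} atoms but topology has {len(self.topology)}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must have at least one frame")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def frame(self, t: int) -> Structure:
        return self.topology.with_coords(self.frames[t])


# --------------------------------------------------------------------------
# selections
# --------------------------------------------------------------------------

_RESID_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def _parse_resid_spec(spec: str) -> list[tuple[int, int]]:
    """``"135"``, ``"135-140"`` or ``"135,139-141,172"`` → inclusive ranges."""
    ranges = []
    for piece in spec.split(","):
        m = _RESID_RE.match(piece)
        if not m:
            raise SelectionError(f"bad resid spec {spec!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionError(f"bad resid range {piece!r}")
        ranges.append((lo, hi))
    return ranges


@dataclass(frozen=True)
class Selection:
    """Deterministic, order-preserving atom subset of a structure.

    The expression is a conjunction of clauses joined by ``and``:

    - ``chain A``
    - ``resid 135`` or ``resid 135-140`` (inclusive range)
    - ``resname LEU`` (comma-separated alternatives allowed)
    - ``name CA,CB``
    - ``backbone`` (N, CA, C, O)
    - ``sidechain`` (heavy atoms not in the backbone)
    - ``all``
    """

    expression: str

    def resolve(self, structure: Structure) -> np.ndarray:
        preds = self._parse()
        idx = [i for i, a in enumerate(structure.atoms) if all(p(a) for p in preds)]
        return np.asarray(idx, dtype=int)

    def resolve_one(self, structure: Structure) -> int:
        idx = self.resolve(structure)
        if len(idx) != 1:
            raise SelectionError(
                f"selection {self.expression!r} resolved to {len(idx)} atoms, expected exactly 1"
            )
        return int(idx[0])

    def _parse(self):
        preds = []
        expr = self.expression.strip()
        if not expr:
            raise SelectionError("empty selection expression")
        for clause in re.split(r"\s+and\s+", expr):
            tokens = clause.split()
            kw = tokens[0].lower()
            if kw == "all" and len(tokens) == 1:
                preds.append(lambda a: True)
            elif kw == "backbone" and len(tokens) == 1:
                preds.append(lambda a: a.name in BACKBONE_NAMES)
            elif kw == "sidechain" and len(tokens) == 1:
                preds.append(lambda a: a.name not in BACKBONE_NAMES and a.element != "H")
            elif kw == "chain" and len(tokens) == 2:
                chains = set(tokens[1].split(","))
                preds.append(lambda a, c=chains: a.chain in c)
            elif kw == "resid" and len(tokens) == 2:
                ranges = _parse_resid_spec(tokens[1])
                preds.append(
                    lambda a, r=ranges: any(lo <= a.residue_number <= hi for lo, hi in r)
                )
            elif kw == "resname" and len(tokens) == 2:
                names = set(tokens[1].upper().split(","))
                preds.append(lambda a, n=names: a.residue_name.upper() in n)
            elif kw == "name" and len(tokens) == 2:
                names = set(tokens[1].upper().split(","))
                preds.append(lambda a, n=names: a.name.upper() in n)
            else:
                raise SelectionError(f"unrecognized selection clause {clause!r}")
        return preds


# --------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# --------------------------------------------------------------------------


def _atom_array_to_structure(arr, title: str = "") -> Structure:
    import biotite.structure as struc  # noqa: F401

    n = arr.array_length()
    ins = arr.ins_code if "ins_code" in arr.get_annotation_categories() else [""] * n
    atoms = []
    for i in range(n):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]),
                residue_number=int(arr.res_id[i]),
                chain=str(arr.chain_id[i]),
                element=str(arr.element[i]),
                position=np.asarray(arr.coord[i], dtype=float),
                insertion_code=str(ins[i]).strip(),
            )
        )
    return Structure(atoms, title=title)


def _structure_to_atom_array(structure: Structure, coords: np.ndarray | None = None):
    import biotite.structure as struc

    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords if coords is not None else structure.coords, dtype=np.float32)
    arr.chain_id = np.array([a.chain or "A" for a in structure.atoms])
    arr.res_id = np.array([a.residue_number for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element for a in structure.atoms])
    arr.set_annotation("ins_code", np.array([a.insertion_code for a in structure.atoms]))
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def _locate_bad_pdb_line(path: Path) -> str:
    """Best-effort scan for the first malformed ATOM/HETATM line, for error messages."""
    try:
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                if line.startswith(("ATOM  ", "HETATM")):
                    try:
                        float(line[30:38])
                        float(line[38:46])
                        float(line[46:54])
                    except (ValueError, IndexError):
                        return f" (line {ln}: {line.rstrip()!r})"
    except OSError:
        pass
    return ""


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    One :class:`AtomRecord` per ATOM/HETATM record of the requested model;
    alternate locations resolved by keeping the first listed conformer
    (altloc "A" or blank).
    """
    import biotite.structure.io.pdb as pdbio

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise PDBFormatError(f"{path}: empty file")
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=model, altloc="first", extra_fields=[])
    except Exception as exc:  # biotite raises various subclasses
        raise PDBFormatError(f"{path}: cannot parse PDB{_locate_bad_pdb_line(path)}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBFormatError(f"{path}: no ATOM/HETATM records")
    return _atom_array_to_structure(arr, title=path.stem)


def fetch_pdb(pdb_id: str, cache_dir: str | Path = "data/pdb", timeout: float = 20.0) -> Path:
    """Return a local path to a PDB entry, downloading from RCSB if needed.

    Looks for ``<cache_dir>/<ID>.pdb`` first; without network access the
    cached copy is the only way to obtain the entry.
    """
    import urllib.request

    pdb_id = pdb_id.upper()
    cache_dir = Path(cache_dir)
    cached = cache_dir / f"{pdb_id}.pdb"
    if cached.exists():
        return cached
    cache_dir.mkdir(parents=True, exist_ok=True)
    url = f"https://files.rcsb.org/download/{pdb_id}.pdb"
    with urllib.request.urlopen(url, timeout=timeout) as resp:
        data = resp.read()
    cached.write_bytes(data)
    return cached


def write_structure(structure: Structure, path: str | Path) -> None:
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_structure_to_atom_array(structure))
    pdb_file.write(str(path))


def read_trajectory(topology: Structure, path: str | Path, frame_interval: float = 1.0) -> Trajectory:
    """Read a trajectory (DCD, or multi-model PDB as the plain-text fallback)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".dcd":
        frames = _read_dcd_frames(path)
    else:
        frames = _read_multimodel_pdb_frames(path)
    if frames.shape[1] != len(topology):
        raise TrajectoryMismatchError(
            f"{path}: file frames have {frames.shape[1]} atoms, topology has {len(topology)}"
        )
    return Trajectory(topology, frames, frame_interval=frame_interval)


def _read_dcd_frames(path: Path) -> np.ndarray:
    from MDAnalysis.coordinates.DCD import DCDReader

    with DCDReader(str(path)) as reader:
        return np.array([ts.positions.copy() for ts in reader], dtype=float)


def _read_multimodel_pdb_frames(path: Path) -> np.ndarray:
    import biotite.structure.io.pdb as pdbio

    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdb_file.get_structure(altloc="first")
    except Exception as exc:
        raise PDBFormatError(f"{path}: cannot parse PDB{_locate_bad_pdb_line(path)}: {exc}") from exc
    coord = np.asarray(stack.coord, dtype=float)
    if coord.ndim == 2:  # single model
        coord = coord[None]
    return coord


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDWriter

        universe = mda.Universe.empty(len(trajectory.topology), trajectory=True)
        universe.load_new(trajectory.frames.astype(np.float32), order="fac")
        with DCDWriter(str(path), n_atoms=len(trajectory.topology)) as writer:
            for _ in universe.trajectory:
                writer.write(universe.atoms)
    else:
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio

        arrays = [
            _structure_to_atom_array(trajectory.topology, coords=f) for f in trajectory.frames
        ]
        stack = struc.stack(arrays)
        pdb_file = pdbio.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))


# --------------------------------------------------------------------------
# superposition
# --------------------------------------------------------------------------


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ x + translation`` maps mobile points onto the reference in the
    least-squares sense.  The rotation is proper orthogonal (Kabsch with the
    reflection case sign-corrected, as done by scipy's ``align_vectors``).
    """
    from scipy.spatial.transform import Rotation

    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"point sets must both be (K, 3); got {mobile.shape} and {reference.shape}")
    k = mobile.shape[0]
    if k < 3:
        raise DegenerateGeometryError(f"need at least 3 points, got {k}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    am = mobile - cm
    ar = reference - cr
    # collinear (or coincident) point sets leave a rotation axis undetermined
    if np.linalg.matrix_rank(np.vstack([am, ar]), tol=1e-8 * max(1.0, np.abs(am).max(initial=1.0))) < 2:
        raise DegenerateGeometryError("point sets are collinear; superposition is not unique")
    rot, rssd = Rotation.align_vectors(ar, am)
    rmsd = float(rssd) / np.sqrt(k)
    rotation = rot.as_matrix()
    translation = cr - rotation @ cm
    return rotation, translation, rmsd
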