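import numpy as np
import pytest

from cvevents.structures import AtomRecord, Structure
from cvevents.synth import generate_ideal_helix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def alpha_helix():
    return generate_ideal_helix(12, -57.0, -47.0)


@pytest.fixture
def two_atom_structure():
    return Structure(
        [
            AtomRecord(1, "CA", "GLY", 1, "A", "C", np.array([0.0, 0.0, 0.0])),
            AtomRecord(2, "CA", "ALA", 2, "A", "C", np.array([3.0, 4.0, 0.0])),
        ],
        title="pair",
    )


def make_structure(coords, names=None, resnames=None, resids=None, chain="A"):
    """Ad-hoc structure builder used across test modules."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or [f"C{i}" for i in range(n)]
    resnames = resnames or ["GLY"] * n
    resids = resids or list(range(1, n + 1))
    atoms = [
        AtomRecord(i + 1, names[i], resnames[i], resids[i], chain, names[i][0], coords[i])
        for i in range(n)
    ]
    return Structure(atoms)


# ----- independent oracles ------------------------------------------------


def quaternion_rmsd(mobile, reference):
    """Horn's closed-form quaternion superposition RMSD (independent oracle)."""
    m = np.asarray(mobile, float)
    r = np.asarray(reference, float)
    mc = m - m.mean(axis=0)
    rc = r - r.mean(axis=0)
    s = mc.T @ rc
    k = np.array(
        [
            [s[0, 0] + s[1, 1] + s[2, 2], s[1, 2] - s[2, 1], s[2, 0] - s[0, 2], s[0, 1] - s[1, 0]],
            [s[1, 2] - s[2, 1], s[0, 0] - s[1, 1] - s[2, 2], s[0, 1] + s[1, 0], s[0, 2] + s[2, 0]],
            [s[2, 0] - s[0, 2], s[0, 1] + s[1, 0], -s[0, 0] + s[1, 1] - s[2, 2], s[1, 2] + s[2, 1]],
            [s[0, 1] - s[1, 0], s[0, 2] + s[2, 0], s[1, 2] + s[2, 1], -s[0, 0] - s[1, 1] + s[2, 2]],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    ssd = (mc**2).sum() + (rc**2).sum() - 2.0 * lam
    return float(np.sqrt(max(ssd, 0.0) / len(m)))


def dihedral(p0, p1, p2, p3):
    """Torsion angle in degrees (praxeolitic formula; independent oracle)."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def varimax_grid_criterion_max(loadings, step_deg=0.01):
    """Exhaustive single-angle varimax maximization for 2-factor loadings."""
    a = np.asarray(loadings, float)
    h = np.sqrt((a**2).sum(axis=1))
    h[h < 1e-12] = 1.0
    a = a / h[:, None]
    thetas = np.radians(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(thetas), np.sin(thetas)
    # columns rotated by each angle
    b1 = a[:, 0][:, None] * c[None, :] + a[:, 1][:, None] * s[None, :]
    b2 = -a[:, 0][:, None] * s[None, :] + a[:, 1][:, None] * c[None, :]
    crit = (b1**2).var(axis=0) + (b2**2).var(axis=0)
    return float(crit.max())
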