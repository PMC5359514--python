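import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from cvevents.structures import (
    DegenerateGeometryError,
    PDBFormatError,
    Selection,
    SelectionError,
    Trajectory,
    TrajectoryMismatchError,
    read_structure,
    read_trajectory,
    superpose,
    write_structure,
    write_trajectory,
)

from conftest import make_structure, quaternion_rmsd

TWO_ATOM_PDB = """\
ATOM      1  CA  GLY A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       4.500  -1.250   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_reads_two_atom_pdb_verbatim(self, tmp_path):
        path = tmp_path / "two.pdb"
        path.write_text(TWO_ATOM_PDB)
        s = read_structure(path)
        assert len(s) == 2
        assert s.atoms[0].name == "CA"
        assert s.atoms[0].residue_name == "GLY"
        assert s.atoms[1].residue_number == 2
        np.testing.assert_allclose(s.coords[0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(s.coords[1], [4.5, -1.25, 0.0])

    def test_non_numeric_coordinates_raise_named_error(self, tmp_path):
        bad = TWO_ATOM_PDB.replace("   4.500", "   x.500")
        path = tmp_path / "bad.pdb"
        path.write_text(bad)
        with pytest.raises(PDBFormatError):
            read_structure(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(PDBFormatError):
            read_structure(path)

    def test_roundtrip_preserves_coordinates(self, tmp_path, alpha_helix):
        path = tmp_path / "helix.pdb"
        write_structure(alpha_helix, path)
        back = read_structure(path)
        assert len(back) == len(alpha_helix)
        # PDB prints 3 decimals
        np.testing.assert_allclose(back.coords, alpha_helix.coords, atol=2e-3)


class TestTrajectoryIO:
    def _trajectory(self, topology, rng, t=5):
        frames = topology.coords[None] + rng.normal(0, 0.5, size=(t, len(topology), 3))
        return Trajectory(topology, frames)

    def test_multimodel_pdb_roundtrip(self, tmp_path, alpha_helix, rng):
        traj = self._trajectory(alpha_helix, rng)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(alpha_helix, path)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.frames, traj.frames, atol=2e-3)

    def test_dcd_roundtrip(self, tmp_path, alpha_helix, rng):
        traj = self._trajectory(alpha_helix, rng)
        path = tmp_path / "traj.dcd"
        write_trajectory(traj, path)
        back = read_trajectory(alpha_helix, path)
        assert back.n_frames == 5
        np.testing.assert_allclose(back.frames, traj.frames, atol=1e-4)

    def test_single_frame_file(self, tmp_path, alpha_helix, rng):
        traj = Trajectory(alpha_helix, alpha_helix.coords[None])
        path = tmp_path / "one.pdb"
        write_trajectory(traj, path)
        assert read_trajectory(alpha_helix, path).n_frames == 1

    def test_atom_count_mismatch_reports_both_counts(self, tmp_path, alpha_helix, rng):
        traj = self._trajectory(alpha_helix, rng)
        path = tmp_path / "traj.pdb"
        write_trajectory(traj, path)
        small = make_structure(np.zeros((3, 3)) + np.arange(3)[:, None])
        with pytest.raises(TrajectoryMismatchError, match="48"):
            read_trajectory(small, path)


class TestSelection:
    def test_resolves_in_structure_order(self, alpha_helix):
        idx = alpha_helix.select("name CA")
        assert list(idx) == sorted(idx)
        assert len(idx) == 12

    def test_resid_lists_and_ranges(self, alpha_helix):
        assert len(alpha_helix.select("resid 2-4 and name CA")) == 3
        assert len(alpha_helix.select("resid 1,3,7 and backbone")) == 12

    def test_unknown_clause_rejected(self, alpha_helix):
        with pytest.raises(SelectionError):
            Selection("within 5 of resid 3").resolve(alpha_helix)

    def test_resolve_one_requires_unique(self, alpha_helix):
        with pytest.raises(SelectionError):
            Selection("name CA").resolve_one(alpha_helix)


class TestSuperpose:
    def test_self_superposition_is_identity(self, rng):
        x = rng.normal(size=(10, 3))
        rot, trans, rmsd = superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-8)

    def test_translation_invariance(self, rng):
        x = rng.normal(size=(8, 3))
        _, _, rmsd = superpose(x, x + np.array([5.0, 0.0, 0.0]))
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle_with_noise(self, rng):
        for _ in range(20):
            x = rng.normal(size=(10, 3))
            r = Rotation.random(rng=rng).as_matrix()
            y = x @ r.T + rng.normal(size=3) * 3 + rng.normal(size=(10, 3)) * 0.1
            _, _, rmsd = superpose(x, y)
            assert rmsd == pytest.approx(quaternion_rmsd(x, y), abs=1e-8)

    def test_symmetric_in_value(self, rng):
        x = rng.normal(size=(12, 3))
        y = rng.normal(size=(12, 3))
        assert superpose(x, y)[2] == pytest.approx(superpose(y, x)[2], abs=1e-10)

    def test_returns_proper_rotation(self, rng):
        x = rng.normal(size=(6, 3))
        y = rng.normal(size=(6, 3))
        rot, _, _ = superpose(x, y)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(rot.T @ rot, np.eye(3), atol=1e-10)

    def test_degenerate_inputs_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)
        with pytest.raises(DegenerateGeometryError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_rmsd_invariant_under_common_rigid_transform(self, seed):
        g = np.random.default_rng(seed)
        x = g.normal(size=(7, 3))
        y = g.normal(size=(7, 3))
        r = Rotation.random(rng=g).as_matrix()
        t = g.normal(size=3) * 10
        base = superpose(x, y)[2]
        moved = superpose(x @ r.T + t, y @ r.T + t)[2]
        assert moved == pytest.approx(base, abs=1e-8)
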