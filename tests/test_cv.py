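import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cvevents.cv import (
    CVDefinition,
    CVMatrix,
    HelixForm,
    LJ_PARAMS,
    classify_helix_form,
    eval_contact_energy,
    eval_distance,
    eval_helix_rotation,
    eval_segment_rmsd,
    evaluate_cvs,
    helix_form_fraction,
)
from cvevents.pka import DEFAULT_CV_IDS, default_cv_definitions
from cvevents.structures import SelectionError, Structure, superpose
from cvevents.synth import generate_ideal_helix, generate_two_state_trajectory

from conftest import make_structure


class TestDistances:
    def test_three_four_five_triangle(self, two_atom_structure):
        d = eval_distance(two_atom_structure, "resid 1", "resid 2")
        assert d == pytest.approx(5.0)

    def test_ambiguous_selection_rejected(self, alpha_helix):
        with pytest.raises(SelectionError):
            eval_distance(alpha_helix, "name CA", "name N")

    def test_distance_rigid_invariance(self, alpha_helix, rng):
        d0 = eval_distance(alpha_helix, "resid 1 and name CA", "resid 9 and name CA")
        r = Rotation.random(rng=rng).as_matrix()
        moved = alpha_helix.with_coords(alpha_helix.coords @ r.T + rng.normal(size=3) * 8)
        d1 = eval_distance(moved, "resid 1 and name CA", "resid 9 and name CA")
        assert d1 == pytest.approx(d0, abs=1e-8)


class TestHelixForms:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [
            (-57.0, -47.0, HelixForm.ALPHA),
            (-49.0, -26.0, HelixForm.THREE_TEN),
            (-57.0, -70.0, HelixForm.PI),
            (180.0, 180.0, HelixForm.OTHER),
        ],
    )
    def test_ideal_geometries(self, phi, psi, expected):
        helix = generate_ideal_helix(12, phi, psi)
        labels = classify_helix_form(helix, (1, 12))
        assert labels, "interior residues must be evaluated"
        assert {l.form for l in labels} == {expected}

    def test_labels_stable_under_coordinate_jitter(self):
        helix = generate_ideal_helix(10, -57.0, -47.0)
        for seed in range(100):
            g = np.random.default_rng(seed)
            jittered = helix.with_coords(helix.coords + g.normal(0, 0.05, helix.coords.shape))
            labels = classify_helix_form(jittered, (1, 10))
            assert {l.form for l in labels} == {HelixForm.ALPHA}

    def test_missing_backbone_oxygen_warns_and_labels_other(self, alpha_helix):
        atoms = [a for a in alpha_helix.atoms if not (a.residue_number == 3 and a.name == "O")]
        broken = Structure(atoms)
        with pytest.warns(UserWarning, match="residue 3"):
            labels = classify_helix_form(broken, (1, 12))
        by_res = {l.residue_number: l.form for l in labels}
        assert by_res[3] == HelixForm.OTHER

    def test_form_fraction_counts_interior_residues(self, alpha_helix):
        assert helix_form_fraction(alpha_helix, (1, 12), "alpha") == pytest.approx(1.0)
        assert helix_form_fraction(alpha_helix, (1, 12), "pi") == pytest.approx(0.0)


class TestSegmentRmsd:
    def test_identity_is_zero(self, alpha_helix):
        assert eval_segment_rmsd(alpha_helix, (1, 12), alpha_helix) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_removed(self, alpha_helix, rng):
        r = Rotation.random(rng=rng).as_matrix()
        moved = alpha_helix.with_coords(alpha_helix.coords @ r.T + 5.0)
        assert eval_segment_rmsd(moved, (1, 12), alpha_helix) == pytest.approx(0.0, abs=1e-6)

    def test_blend_matches_direct_oracle(self, rng):
        a = generate_ideal_helix(10, -57.0, -47.0)
        b = generate_ideal_helix(10, -49.0, -26.0)
        blend = a.with_coords(0.5 * a.coords + 0.5 * b.coords)
        got = eval_segment_rmsd(blend, (1, 10), a)
        # independent route: superpose backbone directly, then root mean square
        rot, trans, _ = superpose(blend.coords, a.coords)
        aligned = blend.coords @ rot.T + trans
        oracle = float(np.sqrt(((aligned - a.coords) ** 2).sum(axis=1).mean()))
        assert got == pytest.approx(oracle, abs=1e-8)


class TestHelixRotation:
    def test_reference_against_itself(self, alpha_helix):
        angle = eval_helix_rotation(alpha_helix, (6, 12), alpha_helix, (1, 5))
        assert angle == pytest.approx(0.0, abs=1e-6)

    def test_constructed_thirty_degree_rotation(self, alpha_helix):
        helix_idx = alpha_helix.select("resid 6-12")
        # helix long axis, to build a perpendicular rotation axis
        seg = alpha_helix.coords[helix_idx]
        centered = seg - seg.mean(axis=0)
        w, v = np.linalg.eigh(centered.T @ centered)
        axis_long = v[:, -1]
        perp = np.cross(axis_long, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis_long, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        rot = Rotation.from_rotvec(np.radians(30.0) * perp).as_matrix()
        coords = alpha_helix.coords.copy()
        center = seg.mean(axis=0)
        coords[helix_idx] = (coords[helix_idx] - center) @ rot.T + center
        moved = alpha_helix.with_coords(coords)
        angle = eval_helix_rotation(moved, (6, 12), alpha_helix, (1, 5))
        assert angle == pytest.approx(30.0, abs=0.5)


class TestContactEnergy:
    def test_long_range_decay(self):
        s = make_structure([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]], names=["C1", "C2"])
        e = eval_contact_energy(s, "resid 1", "resid 2")
        assert abs(e) < 1e-3

    def test_pair_minimum_equals_minus_epsilon(self):
        eps, sigma = LJ_PARAMS["C"]
        rmin = 2.0 ** (1.0 / 6.0) * sigma
        s = make_structure([[0.0, 0.0, 0.0], [rmin, 0.0, 0.0]], names=["C1", "C2"])
        e = eval_contact_energy(s, "resid 1", "resid 2")
        assert e == pytest.approx(-eps, rel=1e-10)

    def test_matches_brute_force_double_loop(self, rng):
        coords = np.vstack([rng.normal(0, 2, (5, 3)), rng.normal(6, 2, (5, 3))])
        names = ["C1", "N1", "O1", "S1", "C2"] + ["O2", "C3", "N2", "C4", "S2"]
        resids = [1] * 5 + [2] * 5
        s = make_structure(coords, names=names, resids=resids)
        got = eval_contact_energy(s, "resid 1", "resid 2")
        total = 0.0
        for i in range(5):
            for j in range(5, 10):
                e1, s1 = LJ_PARAMS[names[i][0]]
                e2, s2 = LJ_PARAMS[names[j][0]]
                eps = np.sqrt(e1 * e2)
                sig = 0.5 * (s1 + s2)
                r = np.linalg.norm(coords[i] - coords[j])
                total += 4.0 * eps * ((sig / r) ** 12 - (sig / r) ** 6)
        assert got == pytest.approx(total, abs=1e-10)

    def test_symmetric_in_groups(self, rng):
        coords = rng.normal(0, 3, (6, 3))
        s = make_structure(coords, resids=[1, 1, 1, 2, 2, 2])
        assert eval_contact_energy(s, "resid 1", "resid 2") == pytest.approx(
            eval_contact_energy(s, "resid 2", "resid 1")
        )

    def test_overlapping_groups_rejected(self, alpha_helix):
        with pytest.raises(SelectionError):
            eval_contact_energy(alpha_helix, "resid 1-3", "resid 3-5")


class TestEvaluateCvs:
    def _defs(self):
        return [
            CVDefinition("d12", "atom_distance", ("resid 1 and name CA", "resid 12 and name CA")),
            CVDefinition("d29", "ca_distance", ("resid 2 and name CA", "resid 9 and name CA")),
            CVDefinition(
                "frac_a", "helix_form_fraction", params={"residue_range": (1, 12), "form": "alpha"}
            ),
        ]

    def test_constant_trajectory_gives_constant_columns(self, alpha_helix):
        from cvevents.structures import Trajectory

        traj = Trajectory(alpha_helix, np.repeat(alpha_helix.coords[None], 4, axis=0))
        cvm = evaluate_cvs(traj, self._defs())
        assert cvm.values.shape == (4, 3)
        assert np.allclose(cvm.values, cvm.values[0])

    def test_two_state_interpolation_distances_are_unimodal(self):
        # linearly interpolated atom positions give convex pairwise distances:
        # each distance column may dip once but never oscillates
        a = generate_ideal_helix(12, -57.0, -47.0)
        b = generate_ideal_helix(12, -57.0, -70.0)
        traj = generate_two_state_trajectory(a, b, T=60, switch_center=30, switch_width=6)
        cvm = evaluate_cvs(traj, self._defs()[:2])
        for col in cvm.values.T:
            signs = np.sign(np.diff(col))
            signs = signs[signs != 0]
            assert np.count_nonzero(np.diff(signs)) <= 1
            assert col.max() <= max(col[0], col[-1]) + 1e-9

    def test_tsv_roundtrip(self, tmp_path, rng):
        cvm = CVMatrix("t", np.arange(5.0), ["a", "b"], rng.normal(size=(5, 2)))
        path = tmp_path / "cv.tsv"
        cvm.to_tsv(path)
        back = CVMatrix.from_tsv(path, "t")
        assert back.cv_ids == ["a", "b"]
        np.testing.assert_allclose(back.values, cvm.values, rtol=1e-6)


class TestDefaultCvSet:
    def test_has_twenty_six_definitions_with_reference(self, alpha_helix):
        defs = default_cv_definitions(reference=alpha_helix)
        assert len(defs) == 26
        assert [d.id for d in defs] == DEFAULT_CV_IDS
        assert len({d.id for d in defs}) == 26

    def test_reference_free_subset_omits_reference_kinds(self):
        defs = default_cv_definitions(None)
        assert len(defs) == 21
        assert all(d.kind not in ("segment_rmsd", "helix_rotation") for d in defs)
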