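"""Ensemble geometry: superposition, dihedrals, restraints, H-bonds, SASA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igdyn.structure import (
    DistanceRestraint,
    PDBParseError,
    StructureEnsemble,
    buried_surface,
    circular_difference,
    classify_distances,
    dihedral,
    detect_hbonds,
    evaluate_restraint,
    per_residue_rmsd,
    phi_psi,
    read_pdb_ensemble,
    sasa,
    superpose,
    _SASA_RADII,
    PROBE_RADIUS,
)


def make_ensemble(names, elements, resnums, xyz, resnames=None):
    n = len(names)
    atoms = dict(
        chain=["A"] * n,
        resnum=np.asarray(resnums, int),
        resname=resnames if resnames is not None else ["ALA"] * n,
        name=list(names),
        element=list(elements),
    )
    xyz = np.asarray(xyz, float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    return StructureEnsemble(atoms, xyz)


class TestPDBIO:
    def _toy(self, n_models):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(12, 3)) * 3.0
        xyz = np.stack([base + 0.01 * k for k in range(n_models)])
        return make_ensemble(
            ["N", "CA", "C", "O"] * 3, ["N", "C", "C", "O"] * 3,
            [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3], xyz)

    @pytest.mark.parametrize("n_models", [1, 20])
    def test_round_trip(self, tmp_path, n_models):
        ens = self._toy(n_models)
        path = tmp_path / "toy.pdb"
        ens.to_pdb(path)
        back = read_pdb_ensemble(path)
        assert back.n_models == n_models
        assert back.n_atoms == ens.n_atoms
        assert np.abs(back.xyz - ens.xyz).max() < 1e-3   # PDB prints 3 decimals

    def test_missing_endmdl_is_parse_error_naming_line(self, tmp_path):
        path = tmp_path / "broken.pdb"
        ens = self._toy(2)
        ens.to_pdb(path)
        lines = [l for l in path.read_text().splitlines()]
        drop = next(i for i, l in enumerate(lines) if l.startswith("ENDMDL"))
        del lines[drop]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(PDBParseError, match=r"line \d+"):
            read_pdb_ensemble(path)

    def test_inconsistent_models_rejected(self, tmp_path):
        path = tmp_path / "mismatch.pdb"
        text = (
            "MODEL        1\n"
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "ATOM      3  C   ALA A   1       2.200   1.300   0.000  1.00  0.00           C\n"
            "ENDMDL\n"
            "MODEL        2\n"
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C\n"
            "ENDMDL\nEND\n"
        )
        path.write_text(text)
        with pytest.raises(PDBParseError):
            read_pdb_ensemble(path)


def brute_force_min_rmsd(P, Q, n_grid=14, refine_iters=3000):
    """Quaternion-search oracle for the optimal superposition RMSD."""
    from scipy.optimize import minimize

    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_of_quat(q):
        q = q / np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ])
        return np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))

    rng = np.random.default_rng(0)
    quats = rng.normal(size=(n_grid ** 3, 4))
    best = min(quats, key=rmsd_of_quat)
    res = minimize(rmsd_of_quat, best, method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": refine_iters})
    return float(res.fun)


class TestSuperpose:
    def test_identity(self):
        P = np.random.default_rng(1).normal(size=(8, 3))
        sup = superpose(P, P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(10, 3))
        theta = math.pi / 2
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        sup = superpose(P @ R.T + [3.0, -1.0, 7.0], P)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_matches_brute_force_quaternion_oracle(self):
        rng = np.random.default_rng(5)
        P = rng.normal(size=(4, 3)) * 2.0
        Q = rng.normal(size=(4, 3)) * 2.0
        assert superpose(P, Q).rmsd == pytest.approx(
            brute_force_min_rmsd(P, Q), abs=1e-6)

    def test_rotation_always_proper(self):
        # a reflected point set must still yield det(R) = +1
        rng = np.random.default_rng(8)
        P = rng.normal(size=(6, 3))
        Q = P.copy()
        Q[:, 0] *= -1.0
        sup = superpose(P, Q)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0)

    def test_collinear_rejected(self):
        P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(P, P)


class TestPerResidueRMSD:
    def _chain(self, n_res=6, jitter=None, seed=0):
        names, elements, resnums, xyz = [], [], [], []
        rng = np.random.default_rng(seed)
        for r in range(1, n_res + 1):
            base = np.array([3.8 * r, 0.0, 0.0])
            for name, off in (("N", [-1.2, 0.5, 0.3]), ("CA", [0, 0, 0]),
                              ("C", [1.2, 0.5, -0.3])):
                names.append(name)
                elements.append(name[0])
                resnums.append(r)
                xyz.append(base + off + (rng.normal(0, 0.4, 3) if seed else 0))
        return names, elements, resnums, np.array(xyz)

    def test_identical_models_zero_spread(self):
        names, el, rn, xyz = self._chain()
        ens = make_ensemble(names, el, rn, np.stack([xyz] * 5))
        df = per_residue_rmsd(ens)
        assert (df.rmsd < 1e-12).all()

    def test_localized_perturbation(self):
        names, el, rn, xyz = self._chain(seed=3)
        moved = xyz.copy()
        sel = np.asarray(rn) == 4
        moved[sel] += [0.0, 1.0, 0.0]
        ensA = make_ensemble(names, el, rn, xyz)
        ensB = make_ensemble(names, el, rn, moved)
        df = per_residue_rmsd(ensA, ensB, fit_residues=[1, 2, 3, 5, 6])
        k = df.set_index("residue_id").rmsd
        assert k[4] == pytest.approx(1.0, abs=1e-9)
        assert all(k[r] < 1e-9 for r in (1, 2, 3, 5, 6))


class TestDihedrals:
    def _points(self, angle_deg):
        # four points constructed so the torsion about the central bond is known
        a = math.radians(angle_deg)
        return (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 0.0]),
                np.array([0.0, 1.5, 0.0]),
                np.array([math.cos(a), 1.5, -math.sin(a)]))

    def test_cis_is_zero(self):
        assert dihedral(*self._points(0.0)) == pytest.approx(0.0, abs=1e-10)

    def test_trans_is_180(self):
        assert abs(dihedral(*self._points(180.0))) == pytest.approx(180.0)

    @pytest.mark.parametrize("angle", [-150.0, -60.0, 30.0, 90.0, 179.0])
    def test_constructed_angles(self, angle):
        assert dihedral(*self._points(angle)) == pytest.approx(angle, abs=1e-9)

    def test_matches_vector_algebra_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.normal(size=(4, 3)) * 3.0
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            cosang = n1 @ n2 / (np.linalg.norm(n1) * np.linalg.norm(n2))
            sign = math.copysign(1.0, np.cross(n1, n2) @ b2)
            expected = sign * math.degrees(math.acos(np.clip(cosang, -1, 1)))
            assert dihedral(*p) == pytest.approx(expected, abs=1e-6)

    def test_phi_psi_undefined_at_termini(self):
        names, el, rn, xyz = [], [], [], []
        for r in range(1, 4):
            for name, off in (("N", [0.0, 0.0, 0.0]), ("CA", [1.0, 0.8, 0.0]),
                              ("C", [2.2, 0.2, 0.4])):
                names.append(name)
                el.append(name[0])
                rn.append(r)
                xyz.append(np.array(off) + [3.5 * r, 0.0, 0.0])
        ens = make_ensemble(names, el, rn, np.array(xyz))
        df = phi_psi(ens).set_index("residue_id")
        assert math.isnan(df.loc[1, "phi"]) and math.isnan(df.loc[3, "psi"])
        assert not math.isnan(df.loc[2, "phi"]) and not math.isnan(df.loc[2, "psi"])


class TestCircularDifference:
    def test_wraparound(self):
        assert circular_difference(179.0, -179.0) == pytest.approx(2.0)

    def test_ef_loop_psi_flip(self):
        assert circular_difference(84.0, -70.0) == pytest.approx(154.0)

    @settings(max_examples=50, deadline=None)
    @given(x=st.floats(-180.0, 180.0), k=st.integers(-3, 3))
    def test_identity_and_periodicity(self, x, k):
        assert circular_difference(x, x) == pytest.approx(0.0, abs=1e-9)
        assert circular_difference(x + 360.0 * k, 10.0) == pytest.approx(
            circular_difference(x, 10.0), abs=1e-6)


class TestRestraints:
    def _pair_ensemble(self):
        # residue 1: lone HA; residue 2: HA plus a methyl 4 A away from res-1 HA
        names = ["HA", "HA", "HB1", "HB2", "HB3"]
        elements = ["H"] * 5
        resnums = [1, 2, 2, 2, 2]
        xyz = np.array([
            [0.0, 0.0, 0.0],
            [3.0, 0.0, 0.0],
            [4.0, 0.0, 0.0],
            [0.0, 4.0, 0.0],
            [0.0, 0.0, 4.0],
        ])
        return make_ensemble(names, elements, resnums, xyz)

    def test_single_pair_distance(self):
        ens = self._pair_ensemble()
        rst = DistanceRestraint(1, "HA", 2, "HA", upper=3.5)
        assert evaluate_restraint(rst, ens) == pytest.approx(3.0)

    def test_methyl_r6_sum(self):
        ens = self._pair_ensemble()
        rst = DistanceRestraint(1, "HA", 2, "HB#", upper=4.0)
        expected = (3.0 * 4.0 ** -6) ** (-1.0 / 6.0)
        assert evaluate_restraint(rst, ens) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(3.33, abs=0.01)

    def test_selection_order_symmetric(self):
        ens = self._pair_ensemble()
        a = evaluate_restraint(DistanceRestraint(1, "HA", 2, "HB#", upper=4.0), ens)
        b = evaluate_restraint(DistanceRestraint(2, "HB#", 1, "HA", upper=4.0), ens)
        assert a == pytest.approx(b)

    def test_unresolvable_selection_names_it(self):
        with pytest.raises(KeyError, match="HZ9"):
            evaluate_restraint(DistanceRestraint(1, "HZ9", 2, "HA", upper=3.0),
                               self._pair_ensemble())

    def test_classification_rule(self):
        # printed EF-loop example: upper 3.5, distances 3.6 (IN) / 7.6 (OUT)
        v_in, v_out, cls = classify_distances(3.6, 7.6, 3.5, tolerance=0.3)
        assert (v_in, v_out) == (pytest.approx(0.1), pytest.approx(4.1))
        assert cls == "IN-specific"
        assert classify_distances(3.0, 3.0, 10.0)[2] == "both"
        assert classify_distances(5.0, 4.0, 3.0)[2] == "neither"

    @settings(max_examples=40, deadline=None)
    @given(d_in=st.floats(1.0, 10.0), d_out=st.floats(1.0, 10.0),
           upper=st.floats(1.5, 6.0),
           tol_lo=st.floats(0.0, 0.5), extra=st.floats(0.0, 2.0))
    def test_classification_monotone_in_tolerance(self, d_in, d_out, upper,
                                                  tol_lo, extra):
        order = {"neither": 0, "IN-specific": 1, "OUT-specific": 1, "both": 2}
        lo = classify_distances(d_in, d_out, upper, tol_lo)[2]
        hi = classify_distances(d_in, d_out, upper, tol_lo + extra)[2]
        assert order[hi] >= order[lo]


def beta_ladder(n_models=20, skip_model=None):
    """Idealised antiparallel two-strand ladder with N-H...O=C hydrogen bonds.

    Donor H of strand-2 residues point straight at carbonyl O of strand-1
    residues.  If *skip_model* is given, that model (1-based) has the H bonds
    broken by displacing the second strand.
    """
    names, elements, resnums, base = [], [], [], []
    for r in range(1, 4):                # strand 1: N, CA, C, O
        x = 3.5 * r
        for name, el, off in (("N", "N", [-1.2, 0, 0]), ("CA", "C", [0, 0, 0]),
                              ("C", "C", [1.2, 0, 0]), ("O", "O", [1.2, 1.1, 0])):
            names.append(name)
            elements.append(el)
            resnums.append(r)
            base.append(np.array([x, 0.0, 0.0]) + off)
    for i, r in enumerate(range(4, 7)):  # strand 2 above, amide H pointing down
        x = 3.5 * (3 - i) + 1.2          # H sits right above an O of strand 1
        for name, el, off in (("N", "N", [0, 1.0, 0]), ("H", "H", [0, 0, 0]),
                              ("CA", "C", [1.3, 1.3, 0]), ("C", "C", [-1.3, 1.4, 0]),
                              ("O", "O", [-1.3, 2.5, 0])):
            names.append(name)
            elements.append(el)
            resnums.append(r)
            base.append(np.array([x, 2.9, 0.0]) + off)
    base = np.array(base)
    models = []
    for k in range(n_models):
        m = base.copy()
        if skip_model is not None and k == skip_model - 1:
            m[np.asarray(resnums) >= 4] += [0.0, 6.0, 0.0]
        models.append(m)
    return make_ensemble(names, elements, resnums, np.stack(models))


class TestHBonds:
    def test_ladder_bonds_found(self):
        pairs = detect_hbonds(beta_ladder())
        assert set(pairs) == {(4, 3), (5, 2), (6, 1)}

    def test_presence_threshold_excludes_19_of_20(self):
        ens = beta_ladder(n_models=20, skip_model=7)
        assert detect_hbonds(ens, presence_fraction=1.0) == []
        assert set(detect_hbonds(ens, presence_fraction=15 / 20)) == \
            {(4, 3), (5, 2), (6, 1)}

    def test_identical_models_fraction_independent(self):
        ens = beta_ladder(n_models=20)
        assert detect_hbonds(ens, 0.75) == detect_hbonds(ens, 1.0)


class TestBuriedSurface:
    def _two_atoms(self, d):
        return make_ensemble(["CA", "CA"], ["C", "C"], [1, 2],
                             np.array([[0.0, 0, 0], [d, 0, 0]]))

    def test_far_groups_bury_nothing(self):
        ens = self._two_atoms(30.0)
        a = ens.mask(residues=[1])
        b = ens.mask(residues=[2])
        assert buried_surface(ens, a, b) == 0.0

    def test_two_spheres_against_cap_formula(self):
        d = 4.0
        ens = self._two_atoms(d)
        area = buried_surface(ens, ens.mask(residues=[1]), ens.mask(residues=[2]))
        R = _SASA_RADII["C"] + PROBE_RADIUS
        analytic = 2.0 * math.pi * R * (R - d / 2.0)   # one spherical cap
        assert area == pytest.approx(analytic, rel=0.02)

    def test_symmetric_in_groups(self):
        ens = self._two_atoms(4.5)
        a, b = ens.mask(residues=[1]), ens.mask(residues=[2])
        assert buried_surface(ens, a, b) == pytest.approx(buried_surface(ens, b, a))

    def test_overlapping_groups_rejected(self):
        ens = self._two_atoms(4.0)
        a = ens.mask(residues=(1, 2))
        with pytest.raises(ValueError):
            buried_surface(ens, a, a)

    def test_isolated_atom_area_is_full_sphere(self):
        areas = sasa(np.zeros((1, 3)), ["C"])
        R = _SASA_RADII["C"] + PROBE_RADIUS
        assert areas[0] == pytest.approx(4 * math.pi * R * R, rel=1e-6)
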