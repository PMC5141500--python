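"""Torsion, distance and superposition arithmetic."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gpcrfp as g
from gpcrfp.errors import (
    DegenerateGeometryError,
    InsufficientPairsError,
    NoSideChainError,
    UnsupportedChiError,
)
from gpcrfp.structures import Atom, Residue, Structure
from gpcrfp.synthetic import helix_seq


def dihedral_oracle(p1, p2, p3, p4):
    """Independent sign convention: angle between plane normals with the
    sign taken from a triple product (no atan2)."""
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), b2) < 0:
        ang = -ang
    if ang <= -180.0:
        ang += 360.0
    return ang


coord = st.floats(-50, 50)
point = st.tuples(coord, coord, coord).map(np.array)


def _good_quadruple(pts):
    p1, p2, p3, p4 = pts
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    return (
        min(np.linalg.norm(v) for v in (b1, b2, b3)) > 1e-3
        and np.linalg.norm(np.cross(b1, b2)) > 1e-2
        and np.linalg.norm(np.cross(b2, b3)) > 1e-2
    )


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert g.dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (1, 1, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert g.dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), (-1, 1, 0)) == pytest.approx(180.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            g.dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            g.dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    @given(st.tuples(point, point, point, point).filter(_good_quadruple))
    def test_matches_independent_oracle(self, pts):
        from hypothesis import assume

        expected = dihedral_oracle(*pts)
        # the acos in the oracle is ill-conditioned at the cis/trans poles
        assume(0.01 < abs(expected) < 179.99)
        got = g.dihedral(*pts)
        assert got == pytest.approx(expected, abs=1e-9)
        assert -180.0 < got <= 180.0

    @given(st.tuples(point, point, point, point).filter(_good_quadruple))
    def test_mirror_negates_sign(self, pts):
        mirrored = [p * np.array([1.0, 1.0, -1.0]) for p in pts]
        a = g.dihedral(*pts)
        b = g.dihedral(*mirrored)
        if abs(a) == pytest.approx(180.0, abs=1e-9):
            assert abs(b) == pytest.approx(180.0, abs=1e-9)
        else:
            assert b == pytest.approx(-a, abs=1e-9)

    @given(st.tuples(point, point, point, point).filter(_good_quadruple))
    def test_reversed_atom_order_preserves_value(self, pts):
        a = g.dihedral(*pts)
        b = g.dihedral(*reversed(pts))
        assert b == pytest.approx(a, abs=1e-9)


class TestChiAngle:
    def test_constructed_trp_chi2_exact(self):
        trp = helix_seq(6, 8)
        spec = g.SyntheticSpec(
            seed=9, n_frames=1, noise_sigma=0.0,
            residue_types={trp: "TRP"},
            rotamer_programs=(g.RotamerProgram(trp, 2, (55.0, 55.0), 1.0),),
        )
        res = g.generate_ensemble(spec).frame_structure(0).residue(trp)
        assert g.chi_angle(res, 2) == pytest.approx(55.0, abs=1e-6)

    @pytest.mark.parametrize("target", [-163.0, 103.0, -60.0, 179.5])
    def test_constructed_phe_chi1_exact(self, target):
        phe = helix_seq(2, 5)
        spec = g.SyntheticSpec(
            seed=9, n_frames=1, noise_sigma=0.0,
            residue_types={phe: "PHE"},
            rotamer_programs=(g.RotamerProgram(phe, 1, (target, target), 1.0),),
        )
        res = g.generate_ensemble(spec).frame_structure(0).residue(phe)
        assert g.chi_angle(res, 1) == pytest.approx(target, abs=1e-6)

    def test_unsupported_chi(self, small_bundle):
        structure, _, _ = small_bundle
        ala = structure.residue(helix_seq(1, 1))
        with pytest.raises(UnsupportedChiError):
            g.chi_angle(ala, 1)

    def test_missing_atom_gives_nan(self, small_bundle):
        structure, _, _ = small_bundle
        trp = structure.residue(helix_seq(6, 8))
        crippled = Residue(
            trp.chain_id, trp.seq_number, trp.res_name,
            [a for a in trp.atoms if a.name != "CD1"],
        )
        assert np.isnan(g.chi_angle(crippled, 2))


def _point_residue(seq, name, xyz_list, res_name="XXX"):
    atoms = [
        Atom(i + 1, nm, "C", "", 1.0, np.array(xyz))
        for i, (nm, xyz) in enumerate(xyz_list)
    ]
    return Residue("A", seq, res_name, atoms)


class TestDistances:
    def test_single_atom_sidechains(self):
        ra = _point_residue(1, "r", [("CB", (0, 0, 0))])
        rb = _point_residue(2, "r", [("CB", (3, 0, 0))])
        assert g.min_sidechain_distance(ra, rb) == pytest.approx(3.0)

    def test_matches_exhaustive_minimum(self, small_bundle):
        structure, _, _ = small_bundle
        trp = structure.residue(helix_seq(6, 8))
        phe = structure.residue(helix_seq(6, 6))
        brute = min(
            np.linalg.norm(a.coord - b.coord)
            for a in trp.sidechain_heavy_atoms()
            for b in phe.sidechain_heavy_atoms()
        )
        assert g.min_sidechain_distance(trp, phe) == pytest.approx(brute)
        assert g.min_sidechain_distance(phe, trp) == pytest.approx(brute)

    def test_glycine_rejected(self):
        gly = _point_residue(1, "GLY", [("N", (0, 0, 0)), ("CA", (1.5, 0, 0))], "GLY")
        other = _point_residue(2, "r", [("CB", (3, 0, 0))])
        with pytest.raises(NoSideChainError):
            g.min_sidechain_distance(gly, other)

    def test_ca_distance(self):
        ra = _point_residue(1, "r", [("CA", (0, 0, 0))])
        rb = _point_residue(2, "r", [("CA", (0, 4, 0))])
        assert g.ca_distance(ra, rb) == pytest.approx(4.0)
        rc = _point_residue(3, "r", [("CB", (0, 0, 0))])
        assert np.isnan(g.ca_distance(ra, rc))

    def test_min_sidechain_bounded_by_ca_distance(self, small_bundle):
        # sanity: side chains cannot be farther apart than the CA-CA
        # distance plus the two side-chain radii (10 A is generous)
        structure, _, _ = small_bundle
        trp = structure.residue(helix_seq(6, 8))
        pro = structure.residue(helix_seq(5, 8))
        assert g.min_sidechain_distance(trp, pro) <= g.ca_distance(trp, pro) + 10.0


def _random_rigid(rng):
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, 3)
    return R, t


class TestSuperpose:
    def test_self_is_identity(self, small_bundle):
        structure, _, _ = small_bundle
        res = g.superpose(structure, structure)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_copy_recovers_zero_rmsd(self, small_bundle):
        structure, _, _ = small_bundle
        rng = np.random.default_rng(5)
        R, t = _random_rigid(rng)
        moved = structure.with_coords(structure.coords @ R.T + t)
        res = g.superpose(moved, structure)
        assert res.rmsd < 1e-6
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_rmsd_symmetric(self, small_bundle):
        structure, _, _ = small_bundle
        rng = np.random.default_rng(6)
        noisy = structure.with_coords(
            structure.coords + rng.normal(0, 0.5, (structure.n_atoms, 3))
        )
        f = g.superpose(structure, noisy).rmsd
        b = g.superpose(noisy, structure).rmsd
        assert f == pytest.approx(b, abs=1e-9)

    def test_fit_never_increases_rmsd(self, small_bundle):
        structure, _, _ = small_bundle
        rng = np.random.default_rng(7)
        sel = g.Selection(atom_names=("CA",))
        idx = g.select(structure, sel)
        for _ in range(5):
            R, t = _random_rigid(rng)
            noisy = structure.with_coords(
                (structure.coords + rng.normal(0, 0.3, (structure.n_atoms, 3)))
                @ R.T + t
            )
            before = float(
                np.sqrt(np.mean(np.sum(
                    (noisy.coords[idx] - structure.coords[idx]) ** 2, axis=1)))
            )
            after = g.superpose(noisy, structure, sel).rmsd
            assert after <= before + 1e-9

    def test_insufficient_pairs(self, small_bundle):
        structure, _, _ = small_bundle
        sel = g.Selection(atom_names=("CA",), residues=(helix_seq(1, 1),))
        with pytest.raises(InsufficientPairsError):
            g.superpose(structure, structure, sel)

    def test_pair_displacement_zero_for_identical(self, small_bundle):
        structure, _, _ = small_bundle
        d = g.pair_displacement(structure, structure, helix_seq(5, 8))
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_pair_displacement_sees_local_shift(self, small_bundle):
        # move one residue's CA; the displacement should be ~ the shift
        structure, _, _ = small_bundle
        seq = helix_seq(5, 8)
        res = structure.residue(seq)
        coords = structure.coords
        i = structure.atom_index(res.chain_id, seq, "CA")
        coords[i] += np.array([0.0, 0.0, 3.0])
        moved = structure.with_coords(coords)
        d = g.pair_displacement(moved, structure, seq)
        assert d == pytest.approx(3.0, abs=0.1)


class TestSeries:
    def test_distance_series_matches_per_frame_calls(self, study_ensemble):
        ens, _, spec = study_ensemble
        a, b = spec.contact_programs[0].seq_a, spec.contact_programs[0].seq_b
        series = g.distance_series(ens, a, b, "min_sidechain_heavy")
        for fi in (0, 17, 123):
            frame = ens.frame_structure(fi)
            expected = g.min_sidechain_distance(frame.residue(a), frame.residue(b))
            assert series.values[fi] == pytest.approx(expected, abs=1e-9)

    def test_chi_series_matches_per_frame_calls(self, study_ensemble):
        ens, _, spec = study_ensemble
        seq = spec.rotamer_programs[0].seq
        series = g.chi_series(ens, seq, 2)
        for fi in (0, 42):
            frame = ens.frame_structure(fi)
            assert series.values[fi] == pytest.approx(
                g.chi_angle(frame.residue(seq), 2), abs=1e-9
            )

    def test_series_tsv_export(self, tmp_path, study_ensemble):
        ens, _, spec = study_ensemble
        series = g.chi_series(ens, spec.rotamer_programs[0].seq, 2)
        p = tmp_path / "chi.tsv"
        series.to_tsv(p)
        lines = p.read_text().splitlines()
        assert lines[0] == "frame_index\tvalue\tmissing"
        assert len(lines) == ens.n_frames + 1
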