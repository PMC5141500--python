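"""Hydrogen-bond / vdW detection, persistence filtering, water counts."""

import numpy as np
import pytest

import gpcrfp as g
from gpcrfp.contacts import acceptor_atoms, donor_atoms, vdw_atoms
from gpcrfp.structures import Atom, BWEntry, BWMap, Residue, Structure
from gpcrfp.synthetic import helix_seq


def _res(seq, res_name, atoms, chain="A", solvent=False):
    return Residue(
        chain, seq, res_name,
        [Atom(i + 1, nm, el, "", 1.0, np.array(xyz, dtype=float))
         for i, (nm, el, xyz) in enumerate(atoms)],
        solvent,
    )


def hbond_oracle(structure, criteria):
    """Exhaustive all-pairs application of the same geometric rules."""
    out = set()
    residues = [r for r in structure.residues if not r.is_solvent]
    for i, ra in enumerate(residues):
        for rb in residues[i + 1:]:
            hit = False
            for dres, ares in ((ra, rb), (rb, ra)):
                for dn in donor_atoms(dres):
                    d = dres.atom(dn).coord
                    hyds = [
                        a.coord for a in dres.atoms
                        if a.is_hydrogen
                        and np.linalg.norm(a.coord - d) < 1.3
                    ]
                    for an in acceptor_atoms(ares):
                        acc = ares.atom(an).coord
                        if np.linalg.norm(d - acc) > criteria.hbond_da_cutoff:
                            continue
                        if not hyds:
                            hit = True
                            continue
                        for h in hyds:
                            v1, v2 = h - d, acc - d
                            cosang = v1 @ v2 / (
                                np.linalg.norm(v1) * np.linalg.norm(v2)
                            )
                            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                            if ang <= criteria.hbond_angle_cutoff:
                                hit = True
            if hit:
                ka, kb = ra.key, rb.key
                out.add((min(ka, kb), max(ka, kb)))
    return out


def vdw_oracle(structure, criteria):
    out = set()
    residues = [r for r in structure.residues if not r.is_solvent]
    for i, ra in enumerate(residues):
        pa = [ra.atom(n).coord for n in vdw_atoms(ra)]
        for rb in residues[i + 1:]:
            pb = [rb.atom(n).coord for n in vdw_atoms(rb)]
            if not pa or not pb:
                continue
            dmin = min(np.linalg.norm(x - y) for x in pa for y in pb)
            if dmin <= criteria.vdw_cutoff:
                ka, kb = ra.key, rb.key
                out.add((min(ka, kb), max(ka, kb)))
    return out


class TestHbondDetection:
    def test_linear_hbond_detected(self):
        don = _res(1, "GLN", [("NE2", "N", (0, 0, 0)), ("HE21", "H", (1, 0, 0)),
                              ("CA", "C", (-3, 0, 0))])
        acc = _res(2, "ASP", [("OD1", "O", (2.9, 0, 0)), ("CA", "C", (6, 0, 0))])
        s = Structure([don, acc])
        assert g.detect_hbonds(s) == {(("A", 1), ("A", 2))}

    def test_long_distance_rejected(self):
        don = _res(1, "GLN", [("NE2", "N", (0, 0, 0)), ("HE21", "H", (1, 0, 0))])
        acc = _res(2, "ASP", [("OD1", "O", (4.0, 0, 0))])
        assert g.detect_hbonds(Structure([don, acc])) == set()

    def test_angle_criterion_with_hydrogens(self):
        # H points perpendicular to the D->A axis: deviation 90 deg > 30
        don = _res(1, "GLN", [("NE2", "N", (0, 0, 0)), ("HE21", "H", (0, 1, 0))])
        acc = _res(2, "ASP", [("OD1", "O", (2.9, 0, 0))])
        assert g.detect_hbonds(Structure([don, acc])) == set()

    def test_distance_only_without_hydrogens(self):
        don = _res(1, "GLN", [("NE2", "N", (0, 0, 0))])
        acc = _res(2, "ASP", [("OD1", "O", (2.9, 0, 0))])
        assert g.detect_hbonds(Structure([don, acc])) == {(("A", 1), ("A", 2))}


class TestVdwDetection:
    @pytest.mark.parametrize("d,expected", [(4.4, True), (4.6, False)])
    def test_default_cutoff_boundary(self, d, expected):
        ra = _res(1, "PHE", [("CB", "C", (0, 0, 0)), ("CG", "C", (-1.5, 0, 0))])
        rb = _res(2, "LEU", [("CB", "C", (d, 0, 0))])
        got = g.detect_vdw_contacts(Structure([ra, rb]))
        assert (len(got) == 1) is expected

    def test_ala_uses_ca_and_cb(self):
        ala = _res(1, "ALA", [("N", "N", (0, 3, 0)), ("CA", "C", (0, 0, 0)),
                              ("CB", "C", (0, -1.5, 0))])
        phe = _res(2, "PHE", [("CB", "C", (4.2, 0, 0))])
        got = g.detect_vdw_contacts(Structure([ala, phe]))
        assert got == {(("A", 1), ("A", 2))}  # via Ala CA, not backbone N

    def test_kinds_are_independent_channels(self):
        # a pair within both criteria appears in both detectors
        don = _res(1, "SER", [("OG", "O", (0, 0, 0)), ("CB", "C", (-1.4, 0, 0))])
        acc = _res(2, "THR", [("OG1", "O", (2.9, 0, 0)), ("CB", "C", (4.3, 0, 0))])
        s = Structure([don, acc])
        assert g.detect_hbonds(s) and g.detect_vdw_contacts(s)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_random_frames_match_exhaustive_search(self, seed):
        from gpcrfp.contacts import ContactCriteria

        spec = g.SyntheticSpec(
            seed=seed, n_frames=1, noise_sigma=1.0,
            residue_types={helix_seq(6, 8): "TRP", helix_seq(5, 8): "PHE",
                           helix_seq(4, 4): "PRO"},
        )
        frame = g.generate_ensemble(spec).frame_structure(0)
        crit = ContactCriteria()
        assert g.detect_hbonds(frame, crit) == hbond_oracle(frame, crit)
        assert g.detect_vdw_contacts(frame, crit) == vdw_oracle(frame, crit)

    def test_cutoff_monotonicity(self):
        from gpcrfp.contacts import ContactCriteria

        spec = g.SyntheticSpec(seed=3, n_frames=1, noise_sigma=0.5)
        frame = g.generate_ensemble(spec).frame_structure(0)
        small = g.detect_vdw_contacts(frame, ContactCriteria(vdw_cutoff=4.0))
        large = g.detect_vdw_contacts(frame, ContactCriteria(vdw_cutoff=5.5))
        assert small <= large
        hb_small = g.detect_hbonds(frame, ContactCriteria(hbond_da_cutoff=3.0))
        hb_large = g.detect_hbonds(frame, ContactCriteria(hbond_da_cutoff=4.0))
        assert hb_small <= hb_large


def _toggling_ensemble(pattern):
    """Two single-CB residues on different 'helices'; CB distance 3 A when
    the pattern says contact, 8 A otherwise."""
    ra = _res(101, "LEU", [("CB", "C", (0, 0, 0))])
    rb = _res(201, "LEU", [("CB", "C", (3, 0, 0))])
    top = Structure([ra, rb])
    frames = np.zeros((len(pattern), 2, 3))
    for i, on in enumerate(pattern):
        frames[i, 1, 0] = 3.0 if on else 8.0
    bw = BWMap(
        {101: BWEntry("1.50", "1", "intracellular"),
         201: BWEntry("2.50", "2", "intracellular")},
        {"1": (101, 101), "2": (201, 201)},
    )
    return g.Ensemble(top, frames), bw


class TestPersistence:
    def test_six_of_ten_retained(self):
        ens, bw = _toggling_ensemble([1, 1, 1, 1, 1, 1, 0, 0, 0, 0])
        series = g.interhelical_persistence(ens, bw)
        vdw = [s for s in series if s.kind == "vdw"]
        assert len(vdw) == 1
        assert vdw[0].persistence == pytest.approx(0.6)

    def test_exactly_half_not_retained(self):
        ens, bw = _toggling_ensemble([1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
        series = g.interhelical_persistence(ens, bw)
        assert [s for s in series if s.kind == "vdw"] == []

    def test_persistence_invariant_under_frame_reorder(self):
        pattern = [1, 0, 1, 1, 0, 1, 1, 0, 1, 1]
        a, bw = _toggling_ensemble(pattern)
        b, _ = _toggling_ensemble(pattern[::-1])
        pa = g.interhelical_persistence(a, bw)[0].persistence
        pb = g.interhelical_persistence(b, bw)[0].persistence
        assert pa == pytest.approx(pb)

    def test_same_helix_pairs_excluded(self):
        ra = _res(101, "LEU", [("CB", "C", (0, 0, 0))])
        rb = _res(102, "LEU", [("CB", "C", (3, 0, 0))])
        bw = BWMap(
            {101: BWEntry("1.50", "1", "intracellular"),
             102: BWEntry("1.51", "1", "intracellular")},
            {"1": (101, 102)},
        )
        ens = g.Ensemble(Structure([ra, rb]),
                         Structure([ra, rb]).coords[None])
        assert g.interhelical_persistence(ens, bw) == []

    def test_filtered_is_subset_of_detector_output(self, study_ensemble):
        ens, bw, _ = study_ensemble
        series = g.interhelical_persistence(ens, bw)
        frame0 = ens.frame_structure(0)
        all_vdw = g.detect_vdw_contacts(frame0)
        for s in series:
            if s.kind == "vdw" and s.present[0]:
                assert s.pair in all_vdw


class TestWaterContacts:
    def test_water_within_cutoff_counts_once(self):
        res = _res(1, "ALA", [("CA", "C", (0, 0, 0)), ("CB", "C", (1.5, 0, 0))])
        wat = _res(900, "HOH", [("O", "O", (4.0, 0, 0))], chain="W", solvent=True)
        top = Structure([res, wat])
        ens = g.Ensemble(top, np.repeat(top.coords[None], 4, axis=0))
        # water is 2.5 A from CB
        assert g.water_contacts(ens, 1, cutoff=3.0) == pytest.approx(1.0)

    def test_water_beyond_cutoff_ignored(self):
        res = _res(1, "ALA", [("CB", "C", (0, 0, 0))])
        wat = _res(900, "HOH", [("O", "O", (3.5, 0, 0))], chain="W", solvent=True)
        top = Structure([res, wat])
        ens = g.Ensemble(top, top.coords[None])
        assert g.water_contacts(ens, 1, cutoff=3.0) == 0.0

    def test_matches_exhaustive_count(self, study_ensemble):
        ens, _, spec = study_ensemble
        seq = spec.waters[0].seq
        got = g.water_contacts(ens, seq, cutoff=3.0)
        res = ens.topology.residue(seq)
        heavy_idx = ens.topology.atom_indices_of(
            res, [a.name for a in res.heavy_atoms()]
        )
        waters = [r for r in ens.topology.residues if r.is_solvent]
        total = 0
        for fi in range(ens.n_frames):
            pts = ens.frames[fi][heavy_idx]
            for w in waters:
                widx = ens.topology.atom_indices_of(w)
                dmin = min(
                    np.linalg.norm(pts - ens.frames[fi][i], axis=1).min()
                    for i in widx
                )
                if dmin <= 3.0:
                    total += 1
        assert got == pytest.approx(total / ens.n_frames)

    def test_no_waters_returns_zero(self, small_bundle):
        structure, _, _ = small_bundle
        ens = g.Ensemble.from_structure(structure)
        assert g.water_contacts(ens, helix_seq(6, 8)) == 0.0
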