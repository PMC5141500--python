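"""Hydrogen-bond / van-der-Waals contact detection and persistence.

Contacts are geometric: a residue pair is hydrogen bonded in a frame
when any donor-acceptor heavy-atom distance is within the D-A cutoff
(and, when hydrogens are present, some donor hydrogen lies within the
angular tolerance of the D->A axis); it is in van-der-Waals contact when
the minimum heavy-atom cross distance is within the vdW cutoff.  The two
kinds are independent channels -- a pair may be both in one frame.

The interhelical pipeline restricts pairs to residues on different TM
helices of an attached BW map, computes per-frame booleans over an
ensemble, and keeps only pairs present in strictly more than the
persistence threshold of frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structures import BWMap, Ensemble, Residue, Structure

logger = logging.getLogger(__name__)

_TM_HELICES = {"1", "2", "3", "4", "5", "6", "7"}

#: Side-chain donor heavy atoms per residue type (N/O chemistry only).
SIDECHAIN_DONORS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"),
    "LYS": ("NZ",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TRP": ("NE1",),
    "TYR": ("OH",),
}

#: Side-chain acceptor heavy atoms per residue type.
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "ASN": ("OD1",),
    "ASP": ("OD1", "OD2"),
    "GLN": ("OE1",),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
}

_WATER_ATOMS = ("O", "OW", "OH2")


@dataclass
class ContactCriteria:
    """Geometric cutoffs for contact detection.

    The persistence threshold is strict: a pair present in exactly half
    of the frames is not retained.
    """

    hbond_da_cutoff: float = 3.5  # Angstrom, donor-acceptor heavy atoms
    hbond_angle_cutoff: float = 30.0  # degrees H-D-A deviation from linear
    vdw_cutoff: float = 4.5  # Angstrom, minimum heavy-atom distance
    persistence_threshold: float = 0.5  # strict > fraction of frames

    def __post_init__(self) -> None:
        if min(self.hbond_da_cutoff, self.hbond_angle_cutoff, self.vdw_cutoff) <= 0:
            raise ValidationError("all contact cutoffs must be positive")
        if not (0.0 < self.persistence_threshold < 1.0):
            raise ValidationError("persistence threshold must be in (0, 1)")

    def as_dict(self) -> dict:
        return {
            "hbond_da_cutoff": self.hbond_da_cutoff,
            "hbond_angle_cutoff": self.hbond_angle_cutoff,
            "vdw_cutoff": self.vdw_cutoff,
            "persistence_threshold": self.persistence_threshold,
        }


@dataclass
class ContactSeries:
    """Per-frame presence of one residue-pair contact."""

    pair: tuple[tuple[str, int], tuple[str, int]]  # ((chain, seq) A, B)
    kind: str  # "hbond" | "vdw"
    present: np.ndarray  # (n_frames,) bool
    halves: tuple[str | None, str | None] = (None, None)

    @property
    def persistence(self) -> float:
        return float(np.mean(self.present))

    @property
    def half_bucket(self) -> str:
        ha, hb = self.halves
        if ha == hb and ha is not None:
            return ha
        return "spanning"


def donor_atoms(res: Residue) -> list[str]:
    """Heavy-atom donor names present in a residue (backbone N included)."""
    if res.is_solvent:
        return [a.name for a in res.atoms if a.name in _WATER_ATOMS]
    names = []
    if res.atom("N") is not None and res.res_name != "PRO":
        names.append("N")
    for nm in SIDECHAIN_DONORS.get(res.res_name, ()):
        if res.atom(nm) is not None:
            names.append(nm)
    return names


def acceptor_atoms(res: Residue) -> list[str]:
    """Heavy-atom acceptor names present in a residue (backbone O included)."""
    if res.is_solvent:
        return [a.name for a in res.atoms if a.name in _WATER_ATOMS]
    names = []
    for bb in ("O", "OXT"):
        if res.atom(bb) is not None:
            names.append(bb)
    for nm in SIDECHAIN_ACCEPTORS.get(res.res_name, ()):
        if res.atom(nm) is not None:
            names.append(nm)
    return names


def vdw_atoms(res: Residue) -> list[str]:
    """Atom names participating in vdW contacts under side-chain scope.

    Side-chain heavy atoms, except that glycine contributes CA and
    alanine contributes both CA and CB (their tiny side chains pack
    through those atoms).
    """
    if res.res_name == "GLY":
        return ["CA"] if res.atom("CA") else []
    names = [a.name for a in res.sidechain_heavy_atoms()]
    if res.res_name == "ALA" and res.atom("CA") is not None:
        names = ["CA"] + names
    return names


def _attached_hydrogens(res: Residue, donor_name: str) -> list[str]:
    """Hydrogens covalently attached to a donor (by <1.3 A proximity)."""
    d = res.atom(donor_name)
    if d is None:
        return []
    out = []
    for a in res.atoms:
        if a.is_hydrogen and np.linalg.norm(a.coord - d.coord) < 1.3:
            out.append(a.name)
    return out


def _hbond_geometry_ok(
    d: np.ndarray, a: np.ndarray, hydrogens: list[np.ndarray], criteria: ContactCriteria
) -> bool:
    if np.linalg.norm(d - a) > criteria.hbond_da_cutoff:
        return False
    if not hydrogens:
        # distance-only criterion for structures without hydrogens
        return True
    da = a - d
    for h in hydrogens:
        dh = h - d
        cosang = np.dot(dh, da) / (np.linalg.norm(dh) * np.linalg.norm(da))
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang <= criteria.hbond_angle_cutoff:
            return True
    return False


def detect_hbonds(
    structure: Structure,
    criteria: ContactCriteria | None = None,
    include_solvent: bool = False,
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs hydrogen-bonded in one frame (deduplicated, A<B order)."""
    criteria = criteria or ContactCriteria()
    residues = [
        r for r in structure.residues if include_solvent or not r.is_solvent
    ]
    found = set()
    for i, ra in enumerate(residues):
        for rb in residues[i + 1:]:
            if _pair_hbonded(ra, rb, criteria):
                found.add(_ordered_pair(ra, rb))
    return found


def _pair_hbonded(ra: Residue, rb: Residue, criteria: ContactCriteria) -> bool:
    for donor_res, acceptor_res in ((ra, rb), (rb, ra)):
        for dn in donor_atoms(donor_res):
            datom = donor_res.atom(dn)
            hyds = [
                donor_res.atom(h).coord
                for h in _attached_hydrogens(donor_res, dn)
            ]
            for an in acceptor_atoms(acceptor_res):
                aatom = acceptor_res.atom(an)
                if _hbond_geometry_ok(datom.coord, aatom.coord, hyds, criteria):
                    return True
    return False


def detect_vdw_contacts(
    structure: Structure,
    criteria: ContactCriteria | None = None,
    atom_scope: str = "side_chain_heavy",
) -> set[tuple[tuple[str, int], tuple[str, int]]]:
    """Residue pairs in van-der-Waals contact in one frame.

    ``atom_scope`` is ``"side_chain_heavy"`` (default; Gly/Ala include
    CA/CB) or ``"all_heavy"``.
    """
    criteria = criteria or ContactCriteria()
    residues = [r for r in structure.residues if not r.is_solvent]
    coords = []
    for r in residues:
        if atom_scope == "side_chain_heavy":
            names = vdw_atoms(r)
        elif atom_scope == "all_heavy":
            names = [a.name for a in r.heavy_atoms()]
        else:
            raise ValueError(f"unknown atom_scope {atom_scope!r}")
        coords.append(np.array([r.atom(n).coord for n in names]) if names else None)
    found = set()
    for i, ra in enumerate(residues):
        if coords[i] is None:
            continue
        for j in range(i + 1, len(residues)):
            if coords[j] is None:
                continue
            d = np.linalg.norm(
                coords[i][:, None, :] - coords[j][None, :, :], axis=-1
            ).min()
            if d <= criteria.vdw_cutoff:
                found.add(_ordered_pair(ra, residues[j]))
    return found


def _ordered_pair(ra: Residue, rb: Residue):
    ka, kb = ra.key, rb.key
    return (ka, kb) if ka <= kb else (kb, ka)


# ---------------------------------------------------------------------------
# ensemble pipeline
# ---------------------------------------------------------------------------

class _ContactEngine:
    """Precomputed topology indexing for fast per-frame detection."""

    def __init__(self, topology: Structure, bwmap: BWMap, include_non_tm: bool):
        self.top = topology
        self.residues = []
        for r in topology.residues:
            if r.is_solvent:
                continue
            hid = bwmap.helix_of(r.seq_number)
            if hid is None:
                continue
            if not include_non_tm and hid not in _TM_HELICES:
                continue
            self.residues.append((r, hid))
        # per-residue index lists into the flat coordinate array
        self.vdw_idx = [
            topology.atom_indices_of(r, vdw_atoms(r)) for r, _ in self.residues
        ]
        self.donors = []  # list of (res_pos, donor_idx, [h_idx...])
        self.acceptors = []  # list of (res_pos, acc_idx)
        for pos, (r, _) in enumerate(self.residues):
            for dn in donor_atoms(r):
                di = topology.atom_index(r.chain_id, r.seq_number, dn)
                h_idx = [
                    topology.atom_index(r.chain_id, r.seq_number, h)
                    for h in _attached_hydrogens(r, dn)
                ]
                self.donors.append((pos, di, [i for i in h_idx if i is not None]))
            for an in acceptor_atoms(r):
                self.acceptors.append(
                    (pos, topology.atom_index(r.chain_id, r.seq_number, an))
                )

    def frame_pairs(self, frame: np.ndarray, criteria: ContactCriteria):
        """(hbond pairs, vdw pairs) as sets of residue-position pairs."""
        hb = set()
        if self.donors and self.acceptors:
            d_pos = np.array([p for p, _, _ in self.donors])
            d_idx = np.array([i for _, i, _ in self.donors])
            a_pos = np.array([p for p, _ in self.acceptors])
            a_idx = np.array([i for _, i in self.acceptors])
            tree_a = cKDTree(frame[a_idx])
            near = tree_a.query_ball_point(frame[d_idx], criteria.hbond_da_cutoff)
            for k, hits in enumerate(near):
                pd = d_pos[k]
                hyd = self.donors[k][2]
                for m in hits:
                    pa = a_pos[m]
                    if pa == pd:
                        continue
                    if hyd:
                        ok = _hbond_geometry_ok(
                            frame[d_idx[k]],
                            frame[a_idx[m]],
                            [frame[i] for i in hyd],
                            criteria,
                        )
                        if not ok:
                            continue
                    hb.add((min(pd, pa), max(pd, pa)))
        vdw = set()
        flat_idx = []
        flat_pos = []
        for pos, idx in enumerate(self.vdw_idx):
            flat_idx.extend(idx)
            flat_pos.extend([pos] * len(idx))
        if flat_idx:
            pts = frame[np.array(flat_idx)]
            pos_arr = np.array(flat_pos)
            tree = cKDTree(pts)
            for ii, jj in tree.query_pairs(criteria.vdw_cutoff):
                pi, pj = pos_arr[ii], pos_arr[jj]
                if pi != pj:
                    vdw.add((min(pi, pj), max(pi, pj)))
        return hb, vdw


def interhelical_persistence(
    ensemble: Ensemble,
    bwmap: BWMap,
    criteria: ContactCriteria | None = None,
    include_non_tm: bool = False,
) -> list[ContactSeries]:
    """Persistent interhelical contacts over an ensemble.

    Only pairs whose residues lie on *different* helices are considered
    (loop/H8 residues excluded unless ``include_non_tm``); only series
    with persistence strictly above the threshold are returned, each
    labelled with the membrane half of both residues.
    """
    criteria = criteria or ContactCriteria()
    engine = _ContactEngine(ensemble.topology, bwmap, include_non_tm)
    n_excluded = sum(
        1 for r in ensemble.topology.residues
        if not r.is_solvent and bwmap.helix_of(r.seq_number) is None
    )
    if n_excluded:
        logger.info("%d residues outside the BW map excluded", n_excluded)
    n = ensemble.n_frames
    counts: dict[tuple[int, int, str], np.ndarray] = {}
    for fi in range(n):
        hb, vdw = engine.frame_pairs(ensemble.frames[fi], criteria)
        for kind, pairs in (("hbond", hb), ("vdw", vdw)):
            for pi, pj in pairs:
                key = (pi, pj, kind)
                if key not in counts:
                    counts[key] = np.zeros(n, dtype=bool)
                counts[key][fi] = True
    out = []
    for (pi, pj, kind), present in sorted(
        counts.items(), key=lambda kv: (kv[0][2], kv[0][0], kv[0][1])
    ):
        ra, ha = engine.residues[pi]
        rb, hbx = engine.residues[pj]
        if ha == hbx:
            continue  # intrahelical
        if np.mean(present) > criteria.persistence_threshold:
            out.append(
                ContactSeries(
                    pair=(ra.key, rb.key),
                    kind=kind,
                    present=present,
                    halves=(bwmap.half_of(ra.seq_number), bwmap.half_of(rb.seq_number)),
                )
            )
    return out


def contacts_to_tsv(
    series: list[ContactSeries], bwmap: BWMap, path, criteria: ContactCriteria
) -> None:
    """Write the persistent-contact report as tidy TSV."""
    lines = [f"# criteria: {criteria.as_dict()}"]
    lines.append("resA\tbwA\tresB\tbwB\tkind\tpersistence\thalf")
    for s in series:
        (ca, sa), (cb, sb) = s.pair
        lines.append(
            f"{sa}\t{bwmap.label_of(sa) or '-'}\t{sb}\t{bwmap.label_of(sb) or '-'}\t"
            f"{s.kind}\t{s.persistence:.6f}\t{s.half_bucket}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def water_contacts(
    ensemble: Ensemble, seq: int, cutoff: float = 3.0, chain: str | None = None
) -> float:
    """Average number of distinct waters within ``cutoff`` of a residue.

    Per frame a water counts when any of its atoms is within the cutoff
    of any heavy atom of the residue; the return value is the arithmetic
    mean over frames.  Returns 0.0 (with a warning) when the topology
    holds no waters.
    """
    top = ensemble.topology
    res = top.residue(seq, chain)
    res_idx = top.atom_indices_of(res, [a.name for a in res.heavy_atoms()])
    waters = [r for r in top.residues if r.is_solvent]
    if not waters:
        logger.warning("water_contacts: no solvent residues in topology")
        return 0.0
    water_idx = [top.atom_indices_of(w) for w in waters]
    total = 0
    for fi in range(ensemble.n_frames):
        frame = ensemble.frames[fi]
        pts = frame[res_idx]
        tree = cKDTree(pts)
        for widx in water_idx:
            d, _ = tree.query(frame[widx], k=1)
            if np.min(d) <= cutoff:
                total += 1
    return total / ensemble.n_frames
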