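"""Distances, side-chain torsions, superposition and RMSD.

Angles are reported in degrees on (-180, +180] with the standard IUPAC
sign convention.  Missing observations (disordered side chains, absent
atoms) are carried as NaN, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    InsufficientPairsError,
    NoSideChainError,
    UnsupportedChiError,
)
from .structures import Ensemble, Residue, Selection, Structure, select

logger = logging.getLogger(__name__)

MISSING = float("nan")

#: Atom quadruples defining side-chain torsions chi1 and chi2 per residue
#: type (standard definitions; chi1 about CA-CB, chi2 about CB-CG).
CHI_ATOMS: dict[str, dict[int, tuple[str, str, str, str]]] = {
    "ARG": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "ASN": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "OD1")},
    "ASP": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "OD1")},
    "CYS": {1: ("N", "CA", "CB", "SG")},
    "GLN": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "GLU": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "HIS": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "ND1")},
    "ILE": {1: ("N", "CA", "CB", "CG1"), 2: ("CA", "CB", "CG1", "CD1")},
    "LEU": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "LYS": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "MET": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "SD")},
    "PHE": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "PRO": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD")},
    "SER": {1: ("N", "CA", "CB", "OG")},
    "THR": {1: ("N", "CA", "CB", "OG1")},
    "TRP": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "TYR": {1: ("N", "CA", "CB", "CG"), 2: ("CA", "CB", "CG", "CD1")},
    "VAL": {1: ("N", "CA", "CB", "CG1")},
}


# ---------------------------------------------------------------------------
# torsions
# ---------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees on (-180, +180].

    Positive values correspond to a clockwise rotation of p4 when viewed
    from p2 toward p3 (the usual biochemical convention).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for a, b, name in ((p1, p2, "p1/p2"), (p2, p3, "p2/p3"), (p3, p4, "p3/p4")):
        if np.linalg.norm(b - a) < 1e-9:
            raise DegenerateGeometryError(f"coincident consecutive points {name}")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise DegenerateGeometryError("collinear consecutive points")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -np.degrees(np.arctan2(y, x))
    # canonical range (-180, 180]
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def wrap_angle(a: float | np.ndarray) -> float | np.ndarray:
    """Wrap degrees onto (-180, 180]."""
    out = np.mod(np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return float(out) if np.isscalar(a) or np.asarray(a).ndim == 0 else out


def chi_angle(residue: Residue, chi_index: int) -> float:
    """Side-chain torsion chi1 or chi2 of a residue, degrees.

    Returns NaN (with a logged warning) when a defining atom is absent;
    raises :class:`UnsupportedChiError` when the residue type has no such
    torsion.
    """
    defs = CHI_ATOMS.get(residue.res_name)
    if defs is None or chi_index not in defs:
        raise UnsupportedChiError(
            f"chi{chi_index} undefined for residue type {residue.res_name}"
        )
    pts = []
    for name in defs[chi_index]:
        a = residue.atom(name)
        if a is None:
            logger.warning(
                "chi%d(%s %s/%d): missing atom %s",
                chi_index, residue.res_name, residue.chain_id, residue.seq_number, name,
            )
            return MISSING
        pts.append(a.coord)
    return dihedral(*pts)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def min_sidechain_distance(resA: Residue, resB: Residue) -> float:
    """Minimum distance over all cross pairs of side-chain heavy atoms (A).

    Symmetric in its arguments.  Glycine (or a fully disordered side
    chain) has no side-chain heavy atoms and raises
    :class:`NoSideChainError`.
    """
    a = resA.sidechain_heavy_atoms()
    b = resB.sidechain_heavy_atoms()
    if not a or not b:
        empty = resA if not a else resB
        raise NoSideChainError(
            f"residue {empty.res_name} {empty.seq_number} has no side-chain heavy atoms"
        )
    pa = np.array([x.coord for x in a])
    pb = np.array([x.coord for x in b])
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
    return float(d.min())


def ca_distance(resA: Residue, resB: Residue) -> float:
    """Distance between the two CA atoms; NaN if either CA is missing."""
    a = resA.atom("CA")
    b = resB.atom("CA")
    if a is None or b is None:
        logger.warning(
            "ca_distance(%d, %d): missing CA", resA.seq_number, resB.seq_number
        )
        return MISSING
    return float(np.linalg.norm(a.coord - b.coord))


# ---------------------------------------------------------------------------
# per-frame series over an ensemble
# ---------------------------------------------------------------------------

@dataclass
class DistanceSeries:
    """Per-frame distance between a residue pair."""

    pair_spec: tuple[int, int, str]  # (seq A, seq B, mode)
    values: np.ndarray  # (n_frames,), Angstrom; NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_tsv(self, path) -> None:
        _series_tsv(self.values, path)


@dataclass
class DihedralSeries:
    """Per-frame chi torsion of one residue."""

    residue_seq: int
    chi_index: int
    values: np.ndarray  # degrees on (-180, 180]; NaN = missing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_tsv(self, path) -> None:
        _series_tsv(self.values, path)


def _series_tsv(values: np.ndarray, path) -> None:
    lines = ["frame_index\tvalue\tmissing"]
    for i, v in enumerate(values):
        if np.isnan(v):
            lines.append(f"{i}\tnan\t1")
        else:
            lines.append(f"{i}\t{v:.6f}\t0")
    Path(path).write_text("\n".join(lines) + "\n")


def distance_series(
    ensemble: Ensemble,
    seq_a: int,
    seq_b: int,
    mode: str = "min_sidechain_heavy",
    chain: str | None = None,
) -> DistanceSeries:
    """Per-frame inter-residue distance (CA-CA or minimum side-chain heavy)."""
    top = ensemble.topology
    ra = top.residue(seq_a, chain)
    rb = top.residue(seq_b, chain)
    if mode == "ca_ca":
        ia = top.atom_index(ra.chain_id, ra.seq_number, "CA")
        ib = top.atom_index(rb.chain_id, rb.seq_number, "CA")
        if ia is None or ib is None:
            vals = np.full(ensemble.n_frames, MISSING)
        else:
            vals = np.linalg.norm(ensemble.frames[:, ia] - ensemble.frames[:, ib], axis=1)
    elif mode == "min_sidechain_heavy":
        names_a = [a.name for a in ra.sidechain_heavy_atoms()]
        names_b = [a.name for a in rb.sidechain_heavy_atoms()]
        if not names_a or not names_b:
            bad = seq_a if not names_a else seq_b
            raise NoSideChainError(f"residue {bad} has no side-chain heavy atoms")
        ia = top.atom_indices_of(ra, names_a)
        ib = top.atom_indices_of(rb, names_b)
        pa = ensemble.frames[:, ia]  # (F, na, 3)
        pb = ensemble.frames[:, ib]  # (F, nb, 3)
        d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=-1)
        vals = d.reshape(ensemble.n_frames, -1).min(axis=1)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    return DistanceSeries((seq_a, seq_b, mode), vals)


def chi_series(
    ensemble: Ensemble, seq: int, chi_index: int, chain: str | None = None
) -> DihedralSeries:
    """Per-frame chi torsion for one residue across all frames."""
    top = ensemble.topology
    res = top.residue(seq, chain)
    defs = CHI_ATOMS.get(res.res_name)
    if defs is None or chi_index not in defs:
        raise UnsupportedChiError(
            f"chi{chi_index} undefined for residue type {res.res_name}"
        )
    idx = [top.atom_index(res.chain_id, res.seq_number, nm) for nm in defs[chi_index]]
    if any(i is None for i in idx):
        logger.warning("chi%d(%d): missing atoms in topology", chi_index, seq)
        vals = np.full(ensemble.n_frames, MISSING)
        return DihedralSeries(seq, chi_index, vals)
    p = ensemble.frames[:, idx]  # (F, 4, 3)
    vals = _dihedral_vectorized(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    return DihedralSeries(seq, chi_index, vals)


def _dihedral_vectorized(p1, p2, p3, p4) -> np.ndarray:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    ang = -np.degrees(np.arctan2(y, x))
    ang[ang <= -180.0] += 360.0
    return ang


# ---------------------------------------------------------------------------
# superposition (Kabsch)
# ---------------------------------------------------------------------------

@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper rotation
    translation: np.ndarray  # (3,)
    rmsd: float  # Angstrom, on the paired set after transform
    atom_count: int
    unpaired_mobile: int = 0
    unpaired_reference: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform (n, 3) mobile-frame coordinates into the reference frame."""
        return coords @ self.rotation.T + self.translation


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired coordinate sets.

    Finds the proper rotation R and translation t minimising
    ``|R x + t - y|`` over the pairs; reflections are excluded by the
    determinant correction inside scipy's ``align_vectors``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise InsufficientPairsError("paired coordinate sets must share shape (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise InsufficientPairsError(f"need >= 3 paired atoms, got {n}")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(R, t, rmsd, n)


def _paired_coords(
    mobile: Structure,
    reference: Structure,
    atom_spec: Selection,
    bwmap=None,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Pair atoms by (chain, seq_number, atom name) intersection."""
    mob_idx = select(mobile, atom_spec, bwmap)
    ref_idx = select(reference, atom_spec, bwmap)
    mob_keys = {}
    for res, atom, i in mobile.iter_atoms():
        mob_keys[i] = (res.chain_id, res.seq_number, atom.name)
    ref_map = {}
    for res, atom, i in reference.iter_atoms():
        ref_map[(res.chain_id, res.seq_number, atom.name)] = i
    pairs = []
    ref_sel = set(ref_idx.tolist())
    for i in mob_idx:
        key = mob_keys[int(i)]
        j = ref_map.get(key)
        if j is not None and j in ref_sel:
            pairs.append((int(i), j))
    n_unpaired_mob = len(mob_idx) - len(pairs)
    n_unpaired_ref = len(ref_idx) - len(pairs)
    if n_unpaired_mob or n_unpaired_ref:
        logger.info(
            "superpose pairing dropped %d mobile / %d reference atoms",
            n_unpaired_mob, n_unpaired_ref,
        )
    mc = mobile.coords
    rc = reference.coords
    mob = np.array([mc[i] for i, _ in pairs])
    ref = np.array([rc[j] for _, j in pairs])
    return mob, ref, n_unpaired_mob, n_unpaired_ref


def superpose(
    mobile: Structure,
    reference: Structure,
    atom_spec: Selection | None = None,
    bwmap=None,
) -> SuperpositionResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired strictly by (chain, seq_number, atom name); atoms
    present in only one structure are dropped with a logged count.  The
    default selection is all CA atoms.
    """
    if atom_spec is None:
        atom_spec = Selection(atom_names=("CA",))
    mob, ref, um, ur = _paired_coords(mobile, reference, atom_spec, bwmap)
    if mob.shape[0] < 3:
        raise InsufficientPairsError(
            f"only {mob.shape[0]} paired atoms under the selection"
        )
    res = kabsch(mob, ref)
    res.unpaired_mobile = um
    res.unpaired_reference = ur
    return res


def pair_displacement(
    mobile: Structure,
    reference: Structure,
    seq_number: int,
    superpose_spec: Selection | None = None,
    chain: str | None = None,
    bwmap=None,
) -> float:
    """CA displacement of one residue after whole-selection superposition.

    The mobile structure is fitted onto the reference with
    ``superpose_spec``; the result is the distance between the residue's
    CA in the reference and its superposed mobile position.
    """
    sup = superpose(mobile, reference, superpose_spec, bwmap)
    ra = mobile.residue(seq_number, chain)
    rb = reference.residue(seq_number, chain)
    a = ra.atom("CA")
    b = rb.atom("CA")
    if a is None or b is None:
        return MISSING
    moved = sup.apply(a.coord[np.newaxis, :])[0]
    return float(np.linalg.norm(moved - b.coord))
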