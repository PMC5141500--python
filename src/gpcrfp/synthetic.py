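"""Synthetic 7-TM bundles and conformational ensembles.

The generator emulates, at desk scale, the statistical structure the
analysis pipeline assumes of an MD ensemble of a 7-helix receptor:

* ideal alpha-helices (1.5 A rise, 100 deg twist per residue) standing
  on a circle, poly-Ala backbone, with designated residues built as
  full Trp/Phe/Pro side chains from ideal internal coordinates;
* two-state side-chain rotamer switching with a programmed occupancy;
* residue-pair contacts toggling between a bound and an unbound
  distance with a programmed on-fraction;
* mixtures of K distinct backbone conformers (rigid tilts of helix
  subsets -- internal deformations, so they survive superposition)
  with programmed proportions;
* single-atom water pseudo-residues placed at a set distance from
  chosen residues;
* isotropic Gaussian coordinate noise applied after all programmed
  placements.

Everything is driven by one mandatory integer seed; the same seed
yields a bit-identical ensemble.  There is no physical realism here --
no force field, no membrane -- the emulation is purely statistical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleSpecError, ValidationError
from .structures import Atom, BWEntry, BWMap, Ensemble, Residue, Structure

RISE_PER_RESIDUE = 1.5  # Angstrom
TWIST_PER_RESIDUE = 100.0  # degrees
CA_HELIX_RADIUS = 2.3  # Angstrom


# ---------------------------------------------------------------------------
# programs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RotamerProgram:
    """Two-state chi switching: well_angles[0] with probability occupancy."""

    seq: int
    chi_index: int
    well_angles: tuple[float, float]
    occupancy: float


@dataclass(frozen=True)
class ContactProgram:
    """Pair toggling between bound/unbound minimum side-chain distance."""

    seq_a: int
    seq_b: int
    bound_distance: float
    unbound_distance: float
    on_fraction: float


@dataclass(frozen=True)
class ConformerProgram:
    """A backbone conformer: a rigid tilt applied to a subset of helices."""

    proportion: float
    tilt_helices: tuple[int, ...]
    tilt_degrees: float


@dataclass(frozen=True)
class WaterProgram:
    seq: int
    count: int
    distance: float


@dataclass
class SyntheticSpec:
    seed: int
    n_helices: int = 7
    residues_per_helix: int = 16
    bundle_radius: float = 11.0
    n_frames: int = 100
    noise_sigma: float = 0.2
    residue_types: Mapping[int, str] = field(default_factory=dict)
    rotamer_programs: tuple[RotamerProgram, ...] = ()
    contact_programs: tuple[ContactProgram, ...] = ()
    conformers: tuple[ConformerProgram, ...] = ()
    waters: tuple[WaterProgram, ...] = ()
    frame_spacing: float | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory (no implicit randomness)")
        for p in self.rotamer_programs:
            if not 0.0 <= p.occupancy <= 1.0:
                raise ValidationError("rotamer occupancy must be in [0, 1]")
        for c in self.contact_programs:
            if not 0.0 <= c.on_fraction <= 1.0:
                raise ValidationError("contact on-fraction must be in [0, 1]")
        if self.conformers:
            total = sum(c.proportion for c in self.conformers)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError("conformer proportions must sum to 1")
        rot_seqs = {p.seq for p in self.rotamer_programs}
        for c in self.contact_programs:
            if c.seq_b in rot_seqs:
                raise ValidationError(
                    f"residue {c.seq_b} cannot carry both a rotamer and a "
                    "contact program (the contact translation would undo it)"
                )


def helix_seq(helix: int, position: int) -> int:
    """Author numbering of a bundle residue: helix h, 1-based position."""
    return 100 * helix + position


# ---------------------------------------------------------------------------
# internal-coordinate side-chain templates
# ---------------------------------------------------------------------------

def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d with |cd|=bond, angle(b,c,d), torsion(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


# Each entry: (atom_name, (ref1, ref2, ref3), bond A, angle deg, torsion)
# where torsion is a number or ("chi1"|"chi2", offset).  CB is placed
# separately (tetrahedral construction off N/CA/C).
_SIDECHAIN_TEMPLATES: dict[str, list] = {
    "ALA": [],
    "PRO": [
        ("CG", ("N", "CA", "CB"), 1.50, 104.0, ("chi1", 0.0)),
        ("CD", ("CA", "CB", "CG"), 1.51, 105.0, ("chi2", 0.0)),
    ],
    "PHE": [
        ("CG", ("N", "CA", "CB"), 1.50, 114.0, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.39, 120.7, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.39, 120.7, ("chi2", 180.0)),
        ("CE1", ("CB", "CG", "CD1"), 1.39, 120.7, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.39, 120.7, 180.0),
        ("CZ", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
    ],
    "TRP": [
        ("CG", ("N", "CA", "CB"), 1.50, 114.0, ("chi1", 0.0)),
        ("CD1", ("CA", "CB", "CG"), 1.37, 127.0, ("chi2", 0.0)),
        ("CD2", ("CA", "CB", "CG"), 1.43, 126.6, ("chi2", 180.0)),
        ("NE1", ("CB", "CG", "CD1"), 1.38, 110.2, 180.0),
        ("CE2", ("CB", "CG", "CD2"), 1.41, 107.0, 180.0),
        ("CE3", ("CB", "CG", "CD2"), 1.40, 133.9, 0.0),
        ("CZ2", ("CG", "CD2", "CE2"), 1.40, 122.4, 180.0),
        ("CZ3", ("CG", "CD2", "CE3"), 1.39, 118.7, 180.0),
        ("CH2", ("CD2", "CE2", "CZ2"), 1.37, 117.5, 0.0),
    ],
}

_DEFAULT_CHI = {
    "PRO": {1: -28.0, 2: 32.0},
    "PHE": {1: -60.0, 2: 90.0},
    "TRP": {1: -60.0, 2: 90.0},
    "ALA": {},
}

_ELEMENTS = {"N": "N", "O": "O"}


def _element_of(name: str) -> str:
    return _ELEMENTS.get(name[0], "C") if name[0] in "NOC" else "C"


def _place_cb(n, ca, c, bond=1.53):
    """Tetrahedral CB off the backbone (L-chirality)."""
    u = n - ca
    u /= np.linalg.norm(u)
    v = c - ca
    v /= np.linalg.norm(v)
    bis = -(u + v)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u, v)
    perp /= np.linalg.norm(perp)
    half = math.radians(54.75)
    return ca + bond * (math.cos(half) * bis + math.sin(half) * perp)


def sidechain_coords(
    backbone: Mapping[str, np.ndarray],
    res_name: str,
    chi: Mapping[int, float] | None = None,
) -> dict[str, np.ndarray]:
    """Side-chain atom coordinates from backbone N/CA/C and chi angles."""
    if res_name not in _SIDECHAIN_TEMPLATES:
        raise ValidationError(f"no side-chain template for {res_name}")
    angles = dict(_DEFAULT_CHI[res_name])
    if chi:
        angles.update(chi)
    pos = {k: np.asarray(v, dtype=float) for k, v in backbone.items()}
    pos["CB"] = _place_cb(pos["N"], pos["CA"], pos["C"])
    out = {"CB": pos["CB"]}
    for name, refs, bond, angle, torsion in _SIDECHAIN_TEMPLATES[res_name]:
        if isinstance(torsion, tuple):
            key, offset = torsion
            t = angles[int(key[-1])] + offset
        else:
            t = torsion
        p = _nerf(pos[refs[0]], pos[refs[1]], pos[refs[2]], bond, angle, t)
        pos[name] = p
        out[name] = p
    return out


# ---------------------------------------------------------------------------
# bundle construction
# ---------------------------------------------------------------------------

def _helix_backbone(n_res: int, direction: int) -> np.ndarray:
    """(n_res, 4, 3) N/CA/C/O coordinates of one ideal helix at origin.

    The helix axis is z; ``direction=+1`` runs the chain N->C along +z,
    ``-1`` flips the helix (180 deg about x) so the chain runs down.
    """
    i = np.arange(n_res)
    phi = np.radians(TWIST_PER_RESIDUE * i)
    z = RISE_PER_RESIDUE * (i - (n_res - 1) / 2.0)
    ca = np.stack(
        [CA_HELIX_RADIUS * np.cos(phi), CA_HELIX_RADIUS * np.sin(phi), z], axis=1
    )
    # extrapolated neighbours for chain-end offsets
    prev = np.vstack([2 * ca[0] - ca[1], ca[:-1]])
    nxt = np.vstack([ca[1:], 2 * ca[-1] - ca[-2]])
    n_at = ca + 0.385 * (prev - ca)
    c_at = ca + 0.40 * (nxt - ca)
    radial = c_at.copy()
    radial[:, 2] = 0.0
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    o_at = c_at + 1.23 * radial / np.where(norms > 1e-9, norms, 1.0)
    bb = np.stack([n_at, ca, c_at, o_at], axis=1)
    if direction < 0:
        bb = bb * np.array([1.0, -1.0, -1.0])
    return bb


def build_bundle(spec: SyntheticSpec) -> tuple[Structure, BWMap]:
    """Ideal helix bundle plus a matching BW map.

    Helices are placed on a circle of ``bundle_radius`` with alternating
    up/down chain directions; residue ``100*h + i`` sits at position i
    of helix h, and the helix midpoint carries the x.50 label.  Raises
    :class:`InfeasibleSpecError` when any inter-helix CA pair comes
    closer than 2 A.
    """
    L = spec.residues_per_helix
    residues: list[Residue] = []
    entries: dict[int, BWEntry] = {}
    ranges: dict[str, tuple[int, int]] = {}
    mid = (L + 1) // 2
    serial = 1
    ca_by_helix = []
    for h in range(1, spec.n_helices + 1):
        theta = 2 * math.pi * (h - 1) / spec.n_helices
        center = np.array(
            [spec.bundle_radius * math.cos(theta), spec.bundle_radius * math.sin(theta), 0.0]
        )
        direction = 1 if h % 2 == 1 else -1
        bb = _helix_backbone(L, direction) + center
        ca_by_helix.append(bb[:, 1, :])
        ranges[str(h)] = (helix_seq(h, 1), helix_seq(h, L))
        for i in range(L):
            seq = helix_seq(h, i + 1)
            res_name = spec.residue_types.get(seq, "ALA")
            backbone = {"N": bb[i, 0], "CA": bb[i, 1], "C": bb[i, 2], "O": bb[i, 3]}
            side = sidechain_coords(backbone, res_name)
            atoms = []
            for name in ("N", "CA", "C", "O"):
                atoms.append(Atom(serial, name, _element_of(name), "", 1.0, backbone[name]))
                serial += 1
            for name, coord in side.items():
                atoms.append(Atom(serial, name, _element_of(name), "", 1.0, coord))
                serial += 1
            residues.append(Residue("A", seq, res_name, atoms))
            half = "intracellular" if backbone["CA"][2] < 0 else "extracellular"
            entries[seq] = BWEntry(f"{h}.{50 + (i + 1 - mid)}", str(h), half)
    # feasibility: no inter-helix CA pair below 2 A
    for a in range(len(ca_by_helix)):
        for b in range(a + 1, len(ca_by_helix)):
            d = np.linalg.norm(
                ca_by_helix[a][:, None, :] - ca_by_helix[b][None, :, :], axis=-1
            ).min()
            if d < 2.0:
                raise InfeasibleSpecError(
                    f"helices {a + 1} and {b + 1} clash (min CA-CA {d:.2f} A); "
                    "increase bundle_radius"
                )
    structure = Structure(residues, label=f"synthetic_bundle_seed{spec.seed}")
    return structure, BWMap(entries, ranges)


# ---------------------------------------------------------------------------
# ensemble generation
# ---------------------------------------------------------------------------

def _tilt_matrix(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    t = math.radians(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(t) * K + (1 - math.cos(t)) * (K @ K)


def _conformer_coords(
    spec: SyntheticSpec, base: Structure, program: ConformerProgram | None
) -> np.ndarray:
    coords = base.coords
    if program is None or not program.tilt_helices:
        return coords
    for h in program.tilt_helices:
        theta = 2 * math.pi * (h - 1) / spec.n_helices
        pivot = np.array(
            [spec.bundle_radius * math.cos(theta), spec.bundle_radius * math.sin(theta), 0.0]
        )
        # tangential axis: tilts the helix outward/inward in the radial plane
        axis = np.array([-math.sin(theta), math.cos(theta), 0.0])
        R = _tilt_matrix(axis, program.tilt_degrees)
        lo, hi = helix_seq(h, 1), helix_seq(h, spec.residues_per_helix)
        for res in base.residues:
            if lo <= res.seq_number <= hi:
                for i in base.atom_indices_of(res):
                    coords[i] = pivot + R @ (coords[i] - pivot)
    return coords


def _sidechain_indices(structure: Structure, seq: int) -> list[int]:
    res = structure.residue(seq)
    return structure.atom_indices_of(
        res, [a.name for a in res.sidechain_heavy_atoms()]
    )


def generate_ensemble(spec: SyntheticSpec) -> Ensemble:
    """Draw a fully reproducible synthetic ensemble from a spec.

    Per frame: a conformer is drawn by proportion; rotamer wells are
    chosen per program (Bernoulli on the first well's occupancy);
    programmed contact distances are imposed by translating the partner
    side chain along the closest-pair axis; waters are placed at their
    programmed distances; and isotropic Gaussian noise of
    ``noise_sigma`` is added to every atom last, so programmed
    quantities are noise-perturbed as in real data.
    """
    base, _ = build_bundle(spec)
    rng = np.random.default_rng(spec.seed)

    conformers: list[ConformerProgram | None] = (
        list(spec.conformers) if spec.conformers else [None]
    )
    proportions = (
        np.array([c.proportion for c in spec.conformers])
        if spec.conformers
        else np.array([1.0])
    )
    conf_coords = [_conformer_coords(spec, base, c) for c in conformers]

    # Pre-build rotamer wells per conformer: (conf, program, well) -> coords
    rot_atoms: list[list[int]] = []
    rot_wells: dict[tuple[int, int, int], np.ndarray] = {}
    for pi, prog in enumerate(spec.rotamer_programs):
        res = base.residue(prog.seq)
        names = ["CB"] + [e[0] for e in _SIDECHAIN_TEMPLATES[res.res_name]]
        idx = base.atom_indices_of(res, names)
        rot_atoms.append(idx)
        bb_idx = base.atom_indices_of(res, ("N", "CA", "C"))
        for ci, coords in enumerate(conf_coords):
            bb = {
                nm: coords[i]
                for nm, i in zip(("N", "CA", "C"), bb_idx)
            }
            for wi, angle in enumerate(prog.well_angles):
                side = sidechain_coords(bb, res.res_name, {prog.chi_index: angle})
                rot_wells[(ci, pi, wi)] = np.array([side[nm] for nm in names])

    # Pre-compute contact translations: (conf, program, bound?) -> shift
    contact_idx: list[list[int]] = []
    contact_shift: dict[tuple[int, int, bool], np.ndarray] = {}
    for pi, prog in enumerate(spec.contact_programs):
        ia = _sidechain_indices(base, prog.seq_a)
        ib = _sidechain_indices(base, prog.seq_b)
        if not ia or not ib:
            raise ValidationError("contact program residues need side chains")
        contact_idx.append(ib)
        for ci, coords in enumerate(conf_coords):
            pa, pb = coords[ia], coords[ib]
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
            k = np.unravel_index(np.argmin(d), d.shape)
            axis = pb[k[1]] - pa[k[0]]
            d0 = np.linalg.norm(axis)
            axis = axis / d0
            for bound, target in (
                (True, prog.bound_distance),
                (False, prog.unbound_distance),
            ):
                contact_shift[(ci, pi, bound)] = (target - d0) * axis

    # Waters: appended to the topology as single-O pseudo-residues
    water_refs = []  # (anchor coords index, direction)
    water_residues = []
    wseq = 9000
    serial = base.n_atoms + 1
    for wp in spec.waters:
        res = base.residue(wp.seq)
        cb = base.atom_index(res.chain_id, res.seq_number, "CB")
        ca = base.atom_index(res.chain_id, res.seq_number, "CA")
        if cb is None or ca is None:
            raise ValidationError("water program residue needs CA and CB")
        base_dir = base.coords[cb] - base.coords[ca]
        base_dir /= np.linalg.norm(base_dir)
        # an arbitrary perpendicular for fanning several waters out
        perp = np.cross(base_dir, [0.0, 0.0, 1.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(base_dir, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        for k in range(wp.count):
            ang = math.radians(20.0 * k)
            direction = math.cos(ang) * base_dir + math.sin(ang) * perp
            direction /= np.linalg.norm(direction)
            wseq += 1
            pos = base.coords[cb] + wp.distance * direction
            water_residues.append(
                Residue("W", wseq, "HOH", [Atom(serial, "O", "O", "", 1.0, pos)], True)
            )
            water_refs.append((cb, wp.distance, direction))
            serial += 1

    topology = Structure(
        list(base.residues) + water_residues, label=base.label
    )
    n_protein = base.n_atoms
    n_atoms = topology.n_atoms
    frames = np.empty((spec.n_frames, n_atoms, 3))

    conf_choice = rng.choice(len(conformers), size=spec.n_frames, p=proportions)
    rot_draw = rng.random((spec.n_frames, max(len(spec.rotamer_programs), 1)))
    contact_draw = rng.random((spec.n_frames, max(len(spec.contact_programs), 1)))
    noise = (
        rng.normal(0.0, spec.noise_sigma, size=(spec.n_frames, n_atoms, 3))
        if spec.noise_sigma > 0
        else np.zeros((spec.n_frames, n_atoms, 3))
    )

    for f in range(spec.n_frames):
        ci = int(conf_choice[f])
        coords = np.empty((n_atoms, 3))
        coords[:n_protein] = conf_coords[ci]
        for pi in range(len(spec.rotamer_programs)):
            well = 0 if rot_draw[f, pi] < spec.rotamer_programs[pi].occupancy else 1
            coords[rot_atoms[pi]] = rot_wells[(ci, pi, well)]
        for pi in range(len(spec.contact_programs)):
            bound = contact_draw[f, pi] < spec.contact_programs[pi].on_fraction
            coords[contact_idx[pi]] += contact_shift[(ci, pi, bound)]
        for wi, (anchor, dist, direction) in enumerate(water_refs):
            coords[n_protein + wi] = coords[anchor] + dist * direction
        frames[f] = coords + noise[f]

    return Ensemble(topology, frames, frame_spacing=spec.frame_spacing)


def generate(spec: SyntheticSpec) -> tuple[Ensemble, BWMap]:
    """Convenience: the ensemble together with its BW map."""
    _, bwmap = build_bundle(spec)
    return generate_ensemble(spec), bwmap


# ---------------------------------------------------------------------------
# study-condition presets
# ---------------------------------------------------------------------------

#: Helix length whose midpoint-anchored labels span offsets x.30-x.70,
#: covering every label the fingerprint battery addresses.
STUDY_HELIX_LENGTH = 41


def position_of_offset(offset: int, residues_per_helix: int = STUDY_HELIX_LENGTH) -> int:
    """1-based helix position carrying BW offset ``offset`` (x.50 = midpoint)."""
    mid = (residues_per_helix + 1) // 2
    pos = offset - 50 + mid
    if not 1 <= pos <= residues_per_helix:
        raise ValidationError(
            f"offset {offset} outside a {residues_per_helix}-residue helix"
        )
    return pos


def plain_spec(seed: int, n_frames: int = 100, noise_sigma: float = 0.2) -> SyntheticSpec:
    """A bare 7-helix poly-Ala bundle with coordinate noise only."""
    return SyntheticSpec(seed=seed, n_frames=n_frames, noise_sigma=noise_sigma)


def study_spec(seed: int, n_frames: int = 100, noise_sigma: float = 0.2) -> SyntheticSpec:
    """Default study conditions for the full fingerprint battery.

    A 41-residue-per-helix bundle carrying a Trp at 6.48, a Phe at 6.44
    and a Pro at 5.50; a two-state Trp chi2 program switching between
    the perpendicular (103 deg) and tilted (-25 deg) orientations with
    0.7 occupancy; a 5.50-6.44 contact program toggling between 3.5 A
    (bound) and 7.5 A with on-fraction 0.6; two waters at 2.8 A of the
    Trp; and a 0.7/0.3 backbone mixture where the minor conformer tilts
    TM6 outward.
    """
    L = STUDY_HELIX_LENGTH
    trp = helix_seq(6, position_of_offset(48))
    phe = helix_seq(6, position_of_offset(44))
    pro = helix_seq(5, position_of_offset(50))
    return SyntheticSpec(
        seed=seed,
        n_frames=n_frames,
        noise_sigma=noise_sigma,
        residues_per_helix=L,
        residue_types={trp: "TRP", phe: "PHE", pro: "PRO"},
        rotamer_programs=(RotamerProgram(trp, 2, (103.0, -25.0), 0.7),),
        contact_programs=(ContactProgram(pro, phe, 3.5, 7.5, 0.6),),
        conformers=(
            ConformerProgram(0.7, (), 0.0),
            ConformerProgram(0.3, (6,), 25.0),
        ),
        waters=(WaterProgram(trp, 2, 2.8),),
    )


def connector_shift_specs(
    seed: int, n_frames: int = 400, noise_sigma: float = 0.2
) -> tuple[SyntheticSpec, SyntheticSpec]:
    """A packed-connector / open-connector scenario pair.

    The packed variant pins the 5.50-6.44 minimum side-chain distance
    near 4.5 A in every frame, the open variant near 7.5 A -- the
    two-state contrast a receptor's connector shows between
    agonist-coupled and uncoupled ensembles.
    """
    L = STUDY_HELIX_LENGTH
    trp = helix_seq(6, position_of_offset(48))
    phe = helix_seq(6, position_of_offset(44))
    pro = helix_seq(5, position_of_offset(50))
    def make(dist: float, s: int) -> SyntheticSpec:
        return SyntheticSpec(
            seed=s,
            n_frames=n_frames,
            noise_sigma=noise_sigma,
            residues_per_helix=L,
            residue_types={trp: "TRP", phe: "PHE", pro: "PRO"},
            contact_programs=(ContactProgram(pro, phe, dist, dist, 1.0),),
        )
    return make(4.5, seed), make(7.5, seed + 1)
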