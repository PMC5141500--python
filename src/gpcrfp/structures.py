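"""Structural data model and PDB input/output.

The in-memory model is deliberately small: an ordered hierarchy of
:class:`Structure` -> :class:`Residue` -> :class:`Atom`, plus
:class:`Ensemble` for multi-model files (one fixed topology, a stack of
coordinate frames) and :class:`BWMap` for the Ballesteros-Weinstein
residue table that drives every receptor-aware selection.

Parsing and writing go through :mod:`gemmi`; this module enforces the
package's policies on top of it (altloc resolution by highest occupancy,
rejection of insertion codes, solvent flagging).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import gemmi
import numpy as np

from .errors import (
    BWLookupError,
    PDBParseError,
    SelectionError,
    TopologyMismatchError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Backbone heavy-atom names ("main chain" in the sense used for
#: TM-helix RMSD fitting).
MAIN_CHAIN_ATOMS = ("N", "CA", "C", "O")

#: Names that never count as side-chain atoms (terminal oxygen included).
_NON_SIDECHAIN = frozenset(MAIN_CHAIN_ATOMS) | {"OXT"}

_SOLVENT_NAMES = frozenset({"HOH", "WAT", "DOD", "SOL"})


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    altloc: str
    occupancy: float
    coord: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,):
            raise ValidationError(f"atom {self.name}: coordinate must be a 3-vector")
        if not np.all(np.isfinite(self.coord)):
            raise ValidationError(f"atom {self.name}: non-finite coordinates")
        if not self.name:
            raise ValidationError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    atoms: list[Atom]
    is_solvent: bool = False

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise ValidationError(
                f"residue {self.chain_id}/{self.seq_number} {self.res_name}: "
                "duplicate atom names after altloc resolution"
            )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.seq_number)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def sidechain_heavy_atoms(self) -> list[Atom]:
        """Heavy atoms excluding the backbone (N, CA, C, O, OXT)."""
        return [
            a
            for a in self.atoms
            if not a.is_hydrogen and a.name not in _NON_SIDECHAIN
        ]


class Structure:
    """One conformation: an ordered residue list with a flat atom index.

    Atoms are globally indexed in residue order; all per-frame numerics
    operate on the flat ``coords`` array so that :class:`Ensemble` frames
    can reuse the same indexing.
    """

    def __init__(self, residues: Sequence[Residue], label: str = "") -> None:
        self.residues: list[Residue] = list(residues)
        self.label = label
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (chain, seq_number) residue keys")
        self._residue_by_key = {r.key: r for r in self.residues}
        # flat indexing
        self._atom_res: list[int] = []
        self._atom_names: list[str] = []
        index = {}
        n = 0
        for ri, res in enumerate(self.residues):
            for a in res.atoms:
                index[(res.chain_id, res.seq_number, a.name)] = n
                self._atom_res.append(ri)
                self._atom_names.append(a.name)
                n += 1
        self._atom_index = index
        self.n_atoms = n

    # -- lookup ------------------------------------------------------------

    def residue(self, seq_number: int, chain_id: str | None = None) -> Residue:
        """Residue by author seq number; chain may be omitted if unambiguous."""
        if chain_id is not None:
            try:
                return self._residue_by_key[(chain_id, seq_number)]
            except KeyError:
                raise SelectionError(
                    f"no residue {chain_id}/{seq_number} in {self.label!r}"
                ) from None
        hits = [r for r in self.residues if r.seq_number == seq_number]
        if not hits:
            raise SelectionError(f"no residue {seq_number} in {self.label!r}")
        if len(hits) > 1:
            raise SelectionError(
                f"residue {seq_number} is ambiguous across chains "
                f"{[r.chain_id for r in hits]}; pass chain_id"
            )
        return hits[0]

    def atom_index(self, chain_id: str, seq_number: int, name: str) -> int | None:
        return self._atom_index.get((chain_id, seq_number, name))

    def atom_indices_of(self, residue: Residue, names: Iterable[str] | None = None) -> list[int]:
        if names is None:
            names = [a.name for a in residue.atoms]
        out = []
        for nm in names:
            i = self._atom_index.get((residue.chain_id, residue.seq_number, nm))
            if i is not None:
                out.append(i)
        return out

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom, int]]:
        i = 0
        for res in self.residues:
            for a in res.atoms:
                yield res, a, i
                i += 1

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in residue/atom order."""
        out = np.empty((self.n_atoms, 3))
        i = 0
        for res in self.residues:
            for a in res.atoms:
                out[i] = a.coord
                i += 1
        return out

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """A deep copy of this structure carrying new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValidationError(
                f"coords shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        new_res = []
        i = 0
        for res in self.residues:
            atoms = []
            for a in res.atoms:
                atoms.append(dataclasses.replace(a, coord=coords[i].copy()))
                i += 1
            new_res.append(
                Residue(res.chain_id, res.seq_number, res.res_name, atoms, res.is_solvent)
            )
        return Structure(new_res, label if label is not None else self.label)


@dataclass
class Ensemble:
    """Ordered frames over one topology (the atom list of frame 0)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_spacing: float | None = None  # time per frame, arbitrary units

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValidationError("an ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyMismatchError(
                f"frames carry {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    @classmethod
    def from_structure(cls, structure: Structure) -> "Ensemble":
        return cls(structure, structure.coords[np.newaxis, :, :])


# ---------------------------------------------------------------------------
# Ballesteros-Weinstein map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BWEntry:
    bw_label: str
    helix_id: str  # "1".."7", "H8" or "loop"
    half: str  # "intracellular" | "extracellular"


@dataclass
class BWMap:
    """Explicit residue-number -> BW label / helix / membrane-half table.

    The table is config: it is read from a TSV, never computed from x.50
    anchors (published labels are not always arithmetic).
    """

    entries: dict[int, BWEntry]
    helix_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [e.bw_label for e in self.entries.values()]
        if len(labels) != len(set(labels)):
            raise ValidationError("BW labels must be unique")
        spans = sorted(self.helix_ranges.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError("helix ranges overlap")
        self._by_label = {e.bw_label: seq for seq, e in self.entries.items()}

    def seq_of(self, bw_label: str) -> int:
        try:
            return self._by_label[bw_label]
        except KeyError:
            raise BWLookupError(f"BW label {bw_label!r} not in map") from None

    def label_of(self, seq_number: int) -> str | None:
        e = self.entries.get(seq_number)
        return e.bw_label if e else None

    def helix_of(self, seq_number: int) -> str | None:
        e = self.entries.get(seq_number)
        if e is not None:
            return e.helix_id
        for hid, (start, end) in self.helix_ranges.items():
            if start <= seq_number <= end:
                return hid
        return None

    def half_of(self, seq_number: int) -> str | None:
        e = self.entries.get(seq_number)
        return e.half if e else None

    def tm_residues(self, helix_id: str) -> range:
        start, end = self.helix_ranges[helix_id]
        return range(start, end + 1)

    # -- I/O: plain-text table --------------------------------------------

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BWMap":
        """Read a table with columns seq_number, bw_label, helix_id, half.

        Lines starting with ``#`` are comments.  An optional line
        ``#range <helix_id> <start> <end>`` declares a helix span
        (residues inside a span but without their own row still resolve
        to that helix).
        """
        entries: dict[int, BWEntry] = {}
        ranges: dict[str, tuple[int, int]] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#range"):
                _, hid, s, e = line.split()
                ranges[hid] = (int(s), int(e))
                continue
            if line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if parts[0] == "seq_number":
                continue
            seq, bw, hid, half = parts[:4]
            entries[int(seq)] = BWEntry(bw, hid, half)
        return cls(entries, ranges)

    def to_tsv(self, path: str | Path, header_comment: str = "") -> None:
        lines = []
        if header_comment:
            for cl in header_comment.splitlines():
                lines.append(f"# {cl}")
        for hid in sorted(self.helix_ranges):
            s, e = self.helix_ranges[hid]
            lines.append(f"#range {hid} {s} {e}")
        lines.append("seq_number\tbw_label\thelix_id\thalf")
        for seq in sorted(self.entries):
            e = self.entries[seq]
            lines.append(f"{seq}\t{e.bw_label}\t{e.helix_id}\t{e.half}")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """Structured selection expression over a structure's atoms.

    All constraints are conjunctive.  ``atom_names`` may be an explicit
    name set or one of the keywords ``"main_chain"`` / ``"side_chain_heavy"``
    / ``"heavy"``.  ``helices`` and ``bw_labels`` require a :class:`BWMap`
    at resolution time.
    """

    atom_names: tuple[str, ...] | str | None = None
    chains: tuple[str, ...] | None = None
    residues: tuple[int, ...] | None = None
    residue_ranges: tuple[tuple[int, int], ...] | None = None
    exclude_residue_ranges: tuple[tuple[int, int], ...] | None = None
    bw_labels: tuple[str, ...] | None = None
    helices: tuple[str, ...] | None = None
    include_solvent: bool = False

    def _residue_ok(self, res: Residue, bwmap: BWMap | None) -> bool:
        if res.is_solvent and not self.include_solvent:
            return False
        if self.chains is not None and res.chain_id not in self.chains:
            return False
        seq = res.seq_number
        if self.exclude_residue_ranges:
            for lo, hi in self.exclude_residue_ranges:
                if lo <= seq <= hi:
                    return False
        in_sets = []
        if self.residues is not None:
            in_sets.append(seq in self.residues)
        if self.residue_ranges is not None:
            in_sets.append(any(lo <= seq <= hi for lo, hi in self.residue_ranges))
        if self.bw_labels is not None:
            if bwmap is None:
                raise SelectionError("bw_labels selection requires a BWMap")
            wanted = {bwmap.seq_of(lbl) for lbl in self.bw_labels}
            in_sets.append(seq in wanted)
        if self.helices is not None:
            if bwmap is None:
                raise SelectionError("helix selection requires a BWMap")
            in_sets.append(bwmap.helix_of(seq) in self.helices)
        return all(in_sets) if in_sets else True

    def _atom_ok(self, atom: Atom) -> bool:
        names = self.atom_names
        if names is None:
            return True
        if names == "main_chain":
            return atom.name in MAIN_CHAIN_ATOMS
        if names == "side_chain_heavy":
            return not atom.is_hydrogen and atom.name not in _NON_SIDECHAIN
        if names == "heavy":
            return not atom.is_hydrogen
        return atom.name in names


def select(structure: Structure, spec: Selection, bwmap: BWMap | None = None) -> np.ndarray:
    """Resolve a selection to a sorted array of flat atom indices.

    Deterministic and set-like: the result is in global (residue-order)
    canonical order regardless of how constraints are phrased.
    """
    out = []
    for res, atom, i in structure.iter_atoms():
        if spec._residue_ok(res, bwmap) and spec._atom_ok(atom):
            out.append(i)
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _resolve_altlocs(raw_atoms: list[gemmi.Atom]) -> list[gemmi.Atom]:
    """Keep, per atom name, the altloc with highest occupancy (tie: first
    altloc character alphabetically)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in raw_atoms:
        by_name.setdefault(a.name, []).append(a)
    kept = []
    for name, group in by_name.items():
        if len(group) == 1:
            kept.append(group[0])
        else:
            group.sort(key=lambda a: (-a.occ, a.altloc or "~"))
            kept.append(group[0])
    # preserve original file order
    order = {id(a): i for i, a in enumerate(raw_atoms)}
    kept.sort(key=lambda a: order[id(a)])
    return kept


def _convert_model(model: gemmi.Model, label: str) -> Structure:
    residues: list[Residue] = []
    for chain in model:
        for gres in chain:
            if gres.seqid.icode not in ("", " ", "\x00"):
                raise PDBParseError(
                    f"{label}: insertion code {gres.seqid.icode!r} at "
                    f"{chain.name}/{gres.seqid.num} is unsupported"
                )
            atoms = []
            for ga in _resolve_altlocs(list(gres)):
                atoms.append(
                    Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name,
                        altloc="" if ga.altloc in ("", "\x00") else ga.altloc,
                        occupancy=ga.occ,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    )
                )
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_number=gres.seqid.num,
                    res_name=gres.name,
                    atoms=atoms,
                    is_solvent=gres.name in _SOLVENT_NAMES,
                )
            )
    return Structure(residues, label=label)


def _validate_records(path: Path) -> None:
    """Reject unparsable ATOM/HETATM records, naming the offending line.

    The underlying parser zero-fills malformed numeric fields silently;
    this pass catches them first.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated record")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PDBParseError(
                    f"{path}:{lineno}: unparsable coordinate field"
                ) from None


def read_pdb(path: str | Path, model_policy: str = "first") -> Structure | Ensemble:
    """Read a PDB file.

    ``model_policy="first"`` returns a :class:`Structure` from MODEL 1;
    ``"all"`` returns an :class:`Ensemble` whose topology is MODEL 1 and
    whose frames are every model's coordinates (all models must share
    MODEL 1's atom list).
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    _validate_records(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models found")
    label = path.stem
    topology = _convert_model(st[0], label)
    if model_policy == "first":
        return topology
    frames = np.empty((len(st), topology.n_atoms, 3))
    ref_sig = [
        (r.chain_id, r.seq_number, a.name) for r, a, _ in topology.iter_atoms()
    ]
    for mi, model in enumerate(st):
        s = _convert_model(model, label)
        sig = [(r.chain_id, r.seq_number, a.name) for r, a, _ in s.iter_atoms()]
        if sig != ref_sig:
            raise TopologyMismatchError(
                f"{path}: model {mi + 1} atom list differs from MODEL 1"
            )
        frames[mi] = s.coords
    return Ensemble(topology, frames)


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structures[0].label or "model"
    for mi, s in enumerate(structures, start=1):
        model = gemmi.Model(mi)
        chain_map: dict[str, gemmi.Chain] = {}
        for res in s.residues:
            ch = chain_map.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id or "A")
                chain_map[res.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_number, " ")
            if res.is_solvent:
                gres.het_flag = "H"
            else:
                gres.het_flag = "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element or a.name[0])
                ga.altloc = a.altloc or "\x00"
                ga.occ = a.occupancy
                ga.serial = a.serial
                ga.pos = gemmi.Position(*a.coord)
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in chain_map.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(obj: Structure | Ensemble, path: str | Path) -> None:
    """Write a Structure as a single-model PDB, an Ensemble as multi-model."""
    if isinstance(obj, Ensemble):
        frames = [obj.topology.with_coords(obj.frames[i]) for i in range(obj.n_frames)]
        st = _to_gemmi(frames)
    else:
        st = _to_gemmi([obj])
    doc_opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    st.write_pdb(str(path), doc_opts)
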