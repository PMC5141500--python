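#!/usr/bin/env python
"""Fetch and down-sample the neurotensin-receptor crystal structures.

Downloads PDB entries 5T04 (NTSR1-EL-T4L), 4XEE (NTSR1-ELF-T4L) and
3ZEV (TM86V-dIC3A) from the RCSB and writes receptor-only, down-sampled
single-model PDBs under ``data/crystal/``:

* every receptor-chain CA atom (author numbering <= 1000; the fused T4
  lysozyme domain of 5T04/4XEE is deposited with offset numbering and
  is dropped, as are ligands, lipids and waters);
* all heavy atoms for the residues addressed by the geometric
  comparisons (connector, microswitches, TM tips):
  157, 167, 231, 249, 257, 268, 300, 303, 317, 321, 332, 369.

The down-sampled files are exactly what the crystal-geometry
integration tests under ``tests/test_acceptance.py`` consume.  Requires
network access; run once from the repository root:

    python scripts/fetch_crystal_structures.py
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

import gemmi

ENTRIES = {
    "5t04": "NTSR1-EL-T4L (constitutively active, NTS8-13 bound)",
    "4xee": "NTSR1-ELF-T4L (low constitutive activity, NTS8-13 bound)",
    "3zev": "TM86V-dIC3A (inactive-like intracellular face)",
}

KEY_RESIDUES = {157, 167, 231, 249, 257, 268, 300, 303, 317, 321, 332, 369}

OUT_DIR = Path(__file__).resolve().parents[1] / "data" / "crystal"


def downsample(st: gemmi.Structure, code: str) -> list[str]:
    st.setup_entities()
    model = st[0]
    # receptor chain: the one containing residue 321 as TRP
    chain = None
    for ch in model:
        for res in ch:
            if res.seqid.num == 321 and res.name == "TRP":
                chain = ch
                break
        if chain:
            break
    if chain is None:
        raise SystemExit(f"{code}: no chain with TRP 321 found")
    lines = [f"REMARK 999 DOWN-SAMPLED FROM PDB {code.upper()} (RECEPTOR CHAIN "
             f"{chain.name}): ALL CA + KEY-RESIDUE HEAVY ATOMS"]
    serial = 0
    for res in chain:
        if res.seqid.num > 1000:  # T4L fusion numbering block
            continue
        if not gemmi.find_tabulated_residue(res.name) or not \
                gemmi.find_tabulated_residue(res.name).is_amino_acid():
            continue
        keep_all = res.seqid.num in KEY_RESIDUES
        for atom in res:
            if atom.element.name == "H":
                continue
            if not keep_all and atom.name != "CA":
                continue
            if atom.altloc not in ("", "\x00", "A"):
                continue
            serial += 1
            lines.append(
                f"ATOM  {serial:5d} {atom.padded_name():4s}{res.name:>4s} "
                f"A{res.seqid.num:4d}    "
                f"{atom.pos.x:8.3f}{atom.pos.y:8.3f}{atom.pos.z:8.3f}"
                f"{atom.occ:6.2f}{atom.b_iso:6.2f}          "
                f"{atom.element.name:>2s}"
            )
    lines.append("END")
    return lines


def main() -> int:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    for code, desc in ENTRIES.items():
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        raw = OUT_DIR / f"{code}_full.tmp.pdb"
        print(f"fetching {code.upper()} ({desc}) ...")
        urllib.request.urlretrieve(url, raw)
        st = gemmi.read_pdb(str(raw))
        out = OUT_DIR / f"{code}_receptor_ds.pdb"
        out.write_text("\n".join(downsample(st, code)) + "\n")
        raw.unlink()
        print(f"  wrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
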