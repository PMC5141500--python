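#!/usr/bin/env python
"""Crystal-geometry comparison of the deposited receptor structures.

Compares the constitutively active NTSR1-EL (PDB 5T04) with NTSR1-ELF
(PDB 4XEE) and the inactive-like TM86V variant (PDB 3ZEV): whole-
receptor CA RMSD, the TM5/TM6 intracellular tip displacements (V268,
V300), the TM5-TM6 extracellular approach (T231-C332), the W321 chi2 /
F317 chi1 microswitch rotamers, and the connector packing ordering.

Requires the down-sampled coordinate files under data/crystal/
(see data/crystal/README.md; network needed once to fetch them).

    python analysis/07_crystal_geometry.py
"""

from pathlib import Path

import gpcrfp as g

CRYSTAL = Path(__file__).resolve().parents[1] / "data" / "crystal"


def main() -> None:
    files = {c: CRYSTAL / f"{c}_receptor_ds.pdb" for c in ("5t04", "4xee", "3zev")}
    missing = [str(p) for p in files.values() if not p.exists()]
    if missing:
        print("crystal fixtures missing:")
        for m in missing:
            print(f"  {m}")
        print("populate with: python scripts/fetch_crystal_structures.py")
        return

    el = g.read_pdb(files["5t04"])
    elf = g.read_pdb(files["4xee"])
    tm86v = g.read_pdb(files["3zev"])
    ca = g.Selection(atom_names=("CA",))

    sup = g.superpose(el, elf, ca)
    print(f"CA RMSD NTSR1-EL vs NTSR1-ELF (T4L excluded): {sup.rmsd:.2f} A "
          f"over {sup.atom_count} atoms")
    for seq, label in ((268, "V268 (5.69, TM5 tip)"), (300, "V300 (6.27, TM6 tip)")):
        d = g.pair_displacement(el, elf, seq, ca)
        print(f"  {label} CA displacement: {d:.1f} A")
    d_el = g.ca_distance(el.residue(231), el.residue(332))
    d_elf = g.ca_distance(elf.residue(231), elf.residue(332))
    print(f"  T231-C332 CA distance: EL {d_el:.1f} A vs ELF {d_elf:.1f} A "
          f"(delta {d_elf - d_el:+.1f} A)")
    print(f"  chi2(W321) in EL: {g.chi_angle(el.residue(321), 2):.0f} deg")
    print(f"  chi1(F317) in ELF: {g.chi_angle(elf.residue(317), 1):.0f} deg")

    print("connector packing, 5.50-6.44 minimum side-chain distance:")
    for name, s in (("EL", el), ("ELF", elf), ("TM86V", tm86v)):
        d = g.min_sidechain_distance(s.residue(249), s.residue(317))
        print(f"  {name}: {d:.2f} A")


if __name__ == "__main__":
    main()
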