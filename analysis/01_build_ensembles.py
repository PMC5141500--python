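#!/usr/bin/env python
"""Generate the study's conformational ensembles.

Builds three synthetic ensembles standing in for the MD trajectories of
an activation study: the default study conditions (rotamer switching,
contact toggling, a two-conformer backbone mixture, waters) and the
packed/open connector scenario pair.  Writes each as a multi-model PDB
plus its BW-map table under results/ensembles/.

    python analysis/01_build_ensembles.py --seed 1 --frames 250
"""

import argparse
from pathlib import Path

import gpcrfp as g


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--frames", type=int, default=250)
    ap.add_argument("--out", type=Path, default=Path("results/ensembles"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    study = g.study_spec(seed=args.seed, n_frames=args.frames)
    packed, opened = g.connector_shift_specs(seed=args.seed + 1000,
                                             n_frames=args.frames)
    for name, spec in (("study", study), ("packed", packed), ("open", opened)):
        ens, bwmap = g.generate(spec)
        g.write_pdb(ens, args.out / f"{name}.pdb")
        bwmap.to_tsv(args.out / f"{name}_bwmap.tsv")
        print(f"{name}: {ens.n_frames} frames, {ens.topology.n_atoms} atoms "
              f"-> {args.out}/{name}.pdb")


if __name__ == "__main__":
    main()
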