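#!/usr/bin/env python
"""Connector packing distributions: the packed-vs-open contrast.

Measures the minimum side-chain heavy-atom distances between the
connector positions (5.50, 3.40, 6.44) over the packed and open
scenario ensembles and reports the modal shift of the 5.50-6.44 pair --
the distance whose two states separate an activation-competent
connector from an uncoupled one.

    python analysis/02_connector_packing.py --seed 1
"""

import argparse
from pathlib import Path

import gpcrfp as g


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--frames", type=int, default=250)
    ap.add_argument("--out", type=Path, default=Path("results/connector"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    packed_spec, open_spec = g.connector_shift_specs(
        seed=args.seed + 1000, n_frames=args.frames
    )
    _, bwmap = g.build_bundle(packed_spec)
    reports = {}
    for name, spec in (("packed", packed_spec), ("open", open_spec)):
        ens = g.generate_ensemble(spec)
        rep = g.fingerprint(ens, bwmap)
        reports[name] = rep
        for pair, hist in rep.connector.items():
            hist.to_tsv(args.out / f"{name}_{pair[0]}_{pair[1]}.tsv")
            print(f"{name} {pair[0]}-{pair[1]}: peak {hist.peak_location:.2f} A")

    diff = g.compare_reports(reports["packed"], reports["open"])
    diff.to_tsv(args.out / "packed_vs_open.tsv")
    shift = diff.connector_peak_shifts[("5.50", "6.44")]
    print(f"\n5.50-6.44 modal shift packed -> open: {shift:+.2f} A "
          "(the open connector sits ~3 A wider)")


if __name__ == "__main__":
    main()
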