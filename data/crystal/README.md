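# Crystal-structure fixtures (not bundled)

The crystal-geometry integration tests compare the deposited
neurotensin-receptor structures 5T04 (NTSR1-EL-T4L), 4XEE
(NTSR1-ELF-T4L) and 3ZEV (TM86V-dIC3A).  Coordinate files are not
redistributed with this repository; with network access, populate this
directory with receptor-only down-sampled copies by running, from the
repository root:

    python scripts/fetch_crystal_structures.py

which writes `5t04_receptor_ds.pdb`, `4xee_receptor_ds.pdb` and
`3zev_receptor_ds.pdb` (every receptor CA atom plus full heavy-atom
side chains for the residues the comparisons address).  Without these
files the two crystal-geometry acceptance tests fail with a message
pointing here; all other tests are self-contained.
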