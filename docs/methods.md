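# Methods

This note documents the models, conventions and design choices behind
the package; the numbers quoted are the ones the tests and
`scripts/acceptance.py` compute.

## Structural model and input conventions

Coordinates are read from single- or multi-model PDB files through
gemmi into a minimal hierarchy (Structure → Residue → Atom) with a
flat atom index shared by all per-frame numerics; a multi-model file
becomes an Ensemble whose topology is MODEL 1 and whose frames must
match its atom list exactly.  Author residue numbering is kept as
deposited.  Alternate locations are resolved at parse time to the
conformer with the highest occupancy (ties: alphabetically first
altloc), giving a deterministic single-conformer model.  Insertion
codes are rejected — the receptor entries in scope do not use them,
and silently renumbering them would corrupt the BW table.  Waters
(HOH) are retained and flagged solvent; hydrogens are kept when
present, and every "heavy-atom" selection excludes element H
explicitly, so the same code serves hydrogen-free crystal models and
MD-like input.

The Ballesteros–Weinstein table is **explicit config** (TSV:
seq_number, bw_label, helix_id, half), never derived arithmetically
from x.50 anchors: published labels are not reliably arithmetic (the
bundled NTSR1 table documents one residue, T231, that has been
labelled both 5.32 and 5.33 in the literature; the table uses 5.32 and
says so in its header).  The membrane-half assignment uses a
config-supplied midplane boundary per helix; for NTSR1 the boundary is
placed at the connector/microswitch level (3.40 / 5.50 / 6.48, and the
7.45 level on TM7), with boundary residues assigned extracellular.
The choice is coarse by design — the halves only bucket contact
counts — and is overridable by editing the table.

## Geometry

Torsions use the standard two-plane atan2 formulation with the IUPAC
sign convention (verified in tests against an independent
acos-plus-triple-product oracle to 1e-9°, and, during development,
against MDAnalysis and biotite); values live on (−180°, 180°].  χ
definitions are the standard side-chain quadruples (χ₂ of Trp/Phe =
CA–CB–CG–CD1).  A missing defining atom yields NaN with a logged
warning, never an exception — disordered side chains are a fact of
crystal models — while an undefined torsion for a residue type (χ₂ of
Ala) is an error.

Superposition is least-squares rigid-body (Kabsch), delegated to
scipy's `Rotation.align_vectors`, which applies the proper-rotation
determinant correction; atoms are paired strictly by (chain,
seq_number, atom name) intersection and unpaired atoms are dropped
with a logged count.  Fusion domains (e.g. a T4-lysozyme insertion)
are excluded by selection ranges, not hard-coded.  Per-residue
displacements between two structures are measured after the same
whole-selection superposition used for the RMSD — the frame of
reference is stated in the report rather than guessed per residue.

## Contacts

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance
≤ 3.5 Å, plus, when the donor carries hydrogens (attached = within
1.3 Å), at least one H within 30° of the D→A axis.  Without hydrogens
the criterion is distance-only.  Donor/acceptor typing is a bundled
N/O table per residue type (backbone N donor except proline, backbone
O acceptor, standard side-chain groups, water O both).  Van-der-Waals
contacts use the minimum side-chain heavy-atom distance ≤ 4.5 Å, with
glycine contributing CA and alanine CA+CB — small side chains pack
through exactly those atoms.  The cutoffs are common MD-analysis
defaults; they are config, logged into every report header, and the
detectors are property-tested for monotonicity in the cutoffs.
Hydrogen-bond and vdW channels are independent: a pair may count in
both.

The interhelical pipeline restricts pairs to residues on *different*
TM helices of the BW map (loop/H8 excluded by default, flag to
include), computes per-frame booleans over the ensemble, and retains
pairs whose persistence is **strictly** greater than 0.5 — a pair
present in exactly half the frames is out.  Contact counts are split
by the half assignment of both residues, with mixed pairs in a
separate "spanning" bucket rather than silently folded into either
half.  Water counts are the per-frame number of distinct waters with
any atom within 3 Å of any heavy atom of the chosen residue, averaged
over frames.

## Clustering

Frames are compared by pairwise fitted RMSD over a caller-supplied
selection — canonically main-chain atoms (N, CA, C, O) of the TM
helices, keeping flexible loops out of the metric.  Each pair is
fitted independently (the behaviour of the classical trajectory
clustering tools); the matrix is exact Kabsch RMSD via the
singular-value identity on pre-centred coordinates.  gromos (Daura)
clustering then iterates: take the frame with most neighbours within
the cutoff (ties: lowest frame index), assign it and its neighbours to
a cluster, remove them, repeat.  Cluster ids are ordered by
descending population.

"Representative structure" needs a definition of the cluster centre;
the centre *frame* is what Daura's algorithm yields, but "smallest
RMSD to the centre" is vacuous for the centre frame itself.  The
package therefore fits all top-cluster members onto the Daura centre,
averages the fitted coordinates, and returns the member closest to
that mean (ties: lowest frame index); both the Daura centre and the
representative are reported.  Frame subsampling is caller-controlled —
the module never thins a trajectory silently.

## Distributions

Histograms are normalised counts, no kernel smoothing — every
reported density is a raw population fraction, so downstream numeric
checks never depend on a bandwidth.  Default widths: 0.25 Å
(distances), 5° (angles), 0.5 Å (2-D grid); all logged.  Angular
histograms bin the fixed (−180°, 180°] support with edges anchored at
−180° so no bin straddles the wrap.  The peak is the midpoint of the
modal bin (ties: lower bin).  The 2-D interface map reports the modal
cell; reference points (e.g. crystal-structure distances) are overlay
material for the presentation layer and never enter the numbers.

## The synthetic generator

The generator emulates, at desk scale, the statistical features of an
MD ensemble of a 7-TM receptor that the analyses consume — not its
physics.  Ideal α-helices (1.5 Å rise, 100° twist per residue, CA
radius 2.3 Å) stand on a circle (default radius 11 Å) with
alternating chain directions; the backbone is poly-Ala with designated
residues built as full Trp/Phe/Pro side chains from ideal internal
coordinates (NeRF placement), so a programmed χ is exact by
construction (±1e-6°).  The BW map labels each helix midpoint x.50.
For the fingerprint battery, which addresses offsets x.30–x.58, the
study preset uses 41-residue helices so every required label exists.

Programs, per frame:

* **rotamer switching** — Bernoulli(p) selects between two χ wells,
  rebuilt from the frame's backbone;
* **contact toggling** — Bernoulli(q) selects a bound or unbound
  target for a residue pair; the partner's side chain is translated
  along the closest-pair axis to realise the target minimum distance;
* **conformer mixture** — a conformer drawn by proportion applies
  rigid tilts to *subsets* of helices.  A rigid motion of the whole
  frame would vanish under superposition, so the "rigid perturbation"
  of a conformer is internal by construction: tilting three helices
  by 55° about their membrane midpoints yields pairwise fitted
  backbone RMSDs ≥ 4.3 Å between conformers, against ~0.5 Å
  within-conformer noise;
* **waters** — single-O HOH pseudo-residues placed at a set distance
  from a residue's CB, fanned out when several are requested
  (sufficient for the 3 Å counting rule);
* **noise last** — isotropic Gaussian noise (default σ = 0.2 Å) is
  added after all placements, so programmed quantities are
  noise-perturbed exactly as measured quantities are in real data.

All randomness flows from one mandatory seed; the same seed is
bit-reproducible.

What the generator does *not* emulate — and what passing tests
therefore do not show about real trajectories: no force field, no
membrane, no correlated backbone fluctuations, no water dynamics, no
coupling between rotamer state and backbone conformation.  Two
artifacts are worth knowing: coordinate noise of σ = 0.2 Å induces
~30° of torsion noise on a rebuilt side chain, so two-state occupancy
recovery uses nearest-well classification and wells far apart (the
103°/−25° pair used in the study preset is 128° apart; recovered
occupancy is then within ±0.05 at 1000 frames); and the contact
translation detaches the partner side chain from its backbone
geometry, so the χ distribution of a contact-programmed residue is
not meaningful (the spec validator refuses a residue carrying both
program types).

## Determinism and reports

A fingerprint report is a directory of TSVs plus a provenance record
(tool version, config, config hash, input hash; no timestamps).
Floats are formatted at fixed precision, so identical input and config
produce byte-identical directories — verified by hashing two
independent runs.  Report comparison requires equal config hashes and
emits per-metric deltas (peak shifts in Å/degrees, contact-count
differences per half, modal-cell displacement).

## Problem sizes

The suite and the acceptance script run at desk scale by choice:
1000 frames for occupancy/persistence recovery (binomial s.e. ≈ 0.015),
200 frames for mixture clustering, 250 for the connector scenario,
50 random matrices / 20 random frames / 200 quadruples for the oracle
cross-checks.  Crystal-geometry comparisons operate on down-sampled
receptor-only copies of the deposited entries (all CA plus key-residue
side chains), which preserve every quantity the comparisons measure.

## Known limitations

* mmCIF and binary trajectory formats (DCD/XTC) are out of scope;
  multi-model PDB is the interchange format.
* Superposition pairing is numbering-based; there is no sequence
  alignment, so comparisons across different numbering schemes need a
  pre-mapped table.
* The hydrogen-bond model is geometric, not energetic, and does not
  detect π-stacking.
* Membrane-half assignment is a per-helix boundary, not a computed
  membrane plane.
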