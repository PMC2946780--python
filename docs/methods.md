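# Methods

`peptigrid` implements grid-based flexible docking of peptides into MHC
class I and class II binding grooves: receptor potential maps are
precomputed on a fixed lattice, a fully flexible peptide is sampled by
biased Monte Carlo with Metropolis acceptance, and poses are evaluated by
nonameric-core Cα RMSD and binding-register recovery.  This note records
the model, its assumptions, the parameters that matter, and the choices
made where the design was genuinely open.

## Protocol

Docking runs in two preparatory steps and one consolidated
docking-and-refinement step.

**Receptor preparation.**  A PDB complex is parsed (gemmi), waters are
discarded, alternate locations resolve to the highest-occupancy conformer,
and chains are classified: the peptide is the shortest polymer chain of
6–25 residues (overridable by chain ID), everything else polymeric is
receptor, and non-water hetero compounds (e.g. a groove-bound formic acid)
are kept aside and join the receptor side only on request.

**Docking grid.**  The docking box uses standardized class dimensions —
35.36 × 35.52 × 35.79 Å (class I), 58.32 × 56.36 × 48.87 Å (class II) —
centred on the groove-domain Cα centroid.  Binding-site atoms are selected
by 5.00 Å spheres ("in and on", inclusive) laid every 1.5 Å along the
groove principal axis and replicated on a ±2.5 Å cross-section pattern, so
the sphere chain covers walls and floor linings without gaps.  Per-channel
receptor potential maps (repulsive vdW, attractive vdW, electrostatic,
hydrogen-bond donor, hydrogen-bond acceptor, hydrophobic) are precomputed
on a 1.00 Å cubic lattice over the box, summing over binding-site atoms
plus all receptor atoms within 8 Å of the box.

**Docking and refinement.**  A probe pseudo-atom marks the most favourable
vdW node in the central third of the box; the extended ligand is anchored
on the groove axis line above it and settled deterministically (backbone
placement scan, rotamer repack, bounded rigid fit).  Biased Monte Carlo
then perturbs side-chain χ angles (favoured; half the side-chain moves
resample the torsion outright, letting rotamers jump between wells),
backbone φ/ψ, or the rigid-body placement; every move is locally minimized
over just the perturbed variables (Powell) and accepted with probability
min(1, exp(−ΔG/RT)) at T = 300 K.  Loose harmonic restraints
(k = 0.1 kcal mol⁻¹ Å⁻²) on the ligand Cα positions are measured from the
starting conformation, keeping the molecule close to its start.  A small
number of seeded replicas run per ligand (default 3: the two groove-axis
orientations plus a random one); every replica's best pose and start are
dropped into their basin bottoms by a deterministic polish (rigid fit,
rotamer scan, per-residue torsion descent, with canonical trans-rotamer and
extended-backbone restarts) and the lowest unrestrained docking energy
wins.  Interface refinement then mobilizes ligand torsions and receptor
side chains within 4.00 Å of the opposing molecule under the unweighted
refinement score, with harmonic Cα restraints; the refined score never
exceeds the input score and atoms outside the mobile set are returned
bit-identical.

## Energy model

Two weighted sums are used, one per stage:

* docking:     E = E_vw + E_en + 2.16·E_el + 2.53·E_hb + 4.35·E_hp + 0.20·E_solv
* refinement:  E = E_vw + E_hb + E_tors + E_elec + E_solv + E_en

The terms come from a deliberately small united-atom force field whose
parameters ship as versioned TSV tables (`peptigrid/data/*_v1.tsv`):

* **van der Waals** — Lennard-Jones 6-12 with geometric combining
  (per-atom √A, √B coefficients, which is also what makes the term
  separable into receptor grid fields).  Pair energies are capped at
  ±100 kcal/mol and distances floored at 0.1 Å so Monte Carlo stays finite
  through clashes.  Within the ligand, pairs up to three bonds apart
  (1-2/1-3/1-4) are excluded.
* **electrostatics** — Coulomb with the distance-dependent dielectric
  ε = 4r, i.e. pair energy k·q₁q₂/(4r²) with k = 332.06 kcal·Å/(mol·e²).
  Backbone partial charges form a neutral amide dipole; ionizable side
  chains and free peptide termini carry unit charges.
* **hydrogen bonds** — a purely attractive Gaussian distance well between
  donor and acceptor heavy atoms (depth 2.0 kcal/mol at 2.90 Å,
  σ = 0.70 Å), switched smoothly to exactly zero at 3.65 Å.  Donor–acceptor
  steric repulsion is left to the vdW term; an angular factor is omitted so
  the term is representable as per-atom grid fields (a united-atom model
  has no explicit polar hydrogens to define the angle robustly anyway).
* **hydrophobic contacts** — a smoothstep contact ramp between apolar
  atoms: full value (0.25 kcal/mol × the pair's strength product) below
  3.0 Å, zero at the 4.50 Å contact cutoff.
* **solvation** — atomic solvation parameters × solvent-accessible area.
  Reference SASA is Shrake–Rupley sphere sampling (960 points/atom, 1.4 Å
  probe); during sampling a fast smooth burial estimate (linearly decaying
  neighbour weights, saturating at ~14 effective contacts) stands in for
  per-step surface integration.
* **side-chain entropy** — per-residue maxima (0 for Gly/Ala/Pro, up to
  2.1 kcal/mol for Arg) scaled by the buried fraction of the side-chain
  terminal atom.
* **torsions** (refinement only) — a cosine series over χ (threefold,
  1.4 kcal/mol barrier) and ω (twofold, 10 kcal/mol, planar minima).

Every distance-dependent term switches smoothly to zero at its cutoff
(nonbonded terms between 6.5 and 8.0 Å), so all kernels are continuous.

## Grid representation

Raw 1/rⁿ fields diverge inside receptor atoms and interpolate terribly on
a 1 Å lattice.  Three numerical choices fix this, all applied inside the
single field routine shared by map construction and the direct evaluator
(so the two routes are always comparable and node values round-trip
exactly):

1. maps store the repulsive channel as Φ^(1/12) and the attractive channel
   as |Φ|^(1/3), which vary roughly like 1/r;
2. the electrostatic field saturates smoothly (tanh) at ±40 kcal/(mol·e),
   which only affects the physically meaningless region inside charged
   atoms;
3. interpolation is tricubic (Catmull–Rom): it reproduces node values
   exactly, is C1 between nodes, and cuts the error of trilinear by an
   order of magnitude on these fields.

With these choices the median per-atom difference between interpolated and
direct receptor–ligand energies over random near-groove poses is
~0.01 kcal/mol (the worst contact atoms reach a few tenths); whole-pose
sums for a 9-mer agree to a couple of kcal/mol.  Atoms outside the box pay
a +10 kcal/mol penalty each.

## The synthetic mini-groove

The packaged generator builds a desk-scale analogue of a peptide-binding
cleft (~410 atoms): two antiparallel poly-alanine helical walls
(leucine/tyrosine pocket linings offset ±2.8 Å from the anchor positions),
a two-strand floor whose inward-pointing residues carry phenylalanine
everywhere except at the anchor positions (discrete pits that pin the
register), and — for class-I-length peptides — single-residue aspartate
and lysine pocket chains placed under the peptide termini, pairing the
free N-terminal ammonium and C-terminal carboxylate the way the class I A
and F pockets fix peptide orientation.  The default peptide is the 9-mer
ALAVNAALA with leucine anchors at positions 2 and 8; longer fixtures pad
the same core with alanine flanks at a requested register, and the walls
span only the core, so the register is a constructed, recoverable
property.  The bound pose is locally energy-minimized after assembly
(same deterministic polish the pipeline uses, plus a small offset
multi-start), so the recorded native is a bona fide minimum of the
packaged energy model — the standard practice of minimizing reference
structures before a docking benchmark.  Everything is deterministic per
seed; optional Gaussian coordinate noise perturbs receptor atoms only.

What the fixture does *not* emulate: real MHC side-chain diversity and
polymorphism, bound waters, backbone bulges of long class II peptides,
receptor flexibility beyond side chains, and crystallographic noise.
Passing tests therefore demonstrate that the machinery — maps, sampling,
restraints, refinement, evaluation — behaves as specified, not that the
force field reproduces experimental binding modes of real alleles.

## Problem sizes and defaults

All defaults are chosen for minutes-scale runs of the pure-Python
implementation on one core: 500 Monte Carlo steps per replica with early
stop after 250 non-improving steps, 25 energy evaluations per per-move
minimization, 3 replicas.  A full re-dock of the default fixture
(maps + sampling + polish + refinement) takes a few minutes; fixture
generation with native relaxation takes about a minute.  Larger budgets
(`--steps`, `--replicas`) trade time for sampling depth.

## Numerical conventions and degenerate inputs

Angles live in (−180°, 180°]; torsion↔Cartesian rebuilding is exact and
involutive on ideal-geometry structures (the NeRF chain construction).
Peptides of nine or fewer residues are evaluated whole (no register
window); register window ties resolve to the smallest start; "highest
resolution" means the numerically smallest Å value, ties broken by PDB id.
Glycine-only peptides have no side-chain moves (the sampler falls back to
backbone moves) and zero entropy term.  Amino-acid analogues map to their
nearest standard parent for parameters while keeping their original names
in output.  Random draws all come from seeded NumPy generators; Powell
minimization is deterministic, so a fixed seed reproduces trajectories and
reports bit-for-bit.

## Known limitations

* The force field is internally consistent but not fitted to experimental
  data; energies are comparative, not transferable binding affinities.
* The hydrogen-bond term is distance-only; directionality is not scored.
* Receptor backbone motion during refinement is approximated by tethered
  Cartesian relaxation of binding-site side chains (the receptor has no
  internal-coordinate model).
* Whole-pose grid/direct agreement is limited by the mandated 1.00 Å
  lattice; atoms in tight contacts carry a few tenths of a kcal/mol of
  interpolation error each.
* The sampler is a local/biased scheme around groove-axis starts; it is
  not a blind global search over the whole box.
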