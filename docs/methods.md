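# Methods

## The QTY substitution model

The QTY code is a fixed four-pair substitution applied position-wise inside
annotated transmembrane (TM) spans: L→Q, I→T, V→T, F→Y.  The pairs were
chosen (in the original protein-design work this package operationalizes)
for near-identical side-chain electron-density envelopes, so the transform
is modeled as *sequence relabeling under an unchanged backbone*.  Everything
outside the TM spans — loops, termini, soluble domains — is untouched, and
the rule is deliberately not user-extensible: a closed alphabet and a fixed
mapping make every downstream metric deterministic.

TM spans are 1-based inclusive intervals (UniProt convention), ordered and
non-overlapping.  Span prediction is out of scope: spans are inputs, parsed
from UniProt-style `TRANSMEM a..b` lines or 2-/3-column TSV.

Sequences are restricted to the 20 canonical one-letter codes; non-canonical
letters (X, B, Z, U, ...) are rejected at parse time rather than skipped,
because silently dropping positions would make variation percentages and
masses depend on an undocumented cleaning step.

## Sequence characteristics

**Variation.**  `total %` = changed positions / sequence length;
`TM %` = changed positions inside spans / residues inside spans, both
reported to 2 decimals.  The denominator is the *native* annotation's TM
residue count; with no spans the TM percentage is 0 by convention.

**Isoelectric point.**  Net charge is the Henderson–Hasselbalch sum
Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH)) over the
N-terminus, C-terminus and D/E/C/Y/H/K/R side chains, with the
Bjellqvist/Expasy pKa set (residue-specific N-terminal values with a 7.50
fallback; C-terminal 3.55 with D/E exceptions).  Z is strictly decreasing,
so the pI is the unique root on (0, 14), found by bisection.  The bracket is
always narrowed below 1e-4 pH units; an |Z|-based early exit was rejected
because on shallow charge curves (few ionizable groups) a small residual
charge can still correspond to a pH error of several 1e-4.  A consequence
worth knowing: a variant's pI is *exactly* the native's whenever no F→Y
substitution occurs and the N-terminal residue is unsubstituted — Q and T
carry no ionizable group, while Y adds a phenol (pKa 10) and a substitution
at position 1 can switch the residue-specific N-terminal pKa.

**Mass.**  Average (not monoisotopic) Expasy residue masses plus one water
at 18.02 Da, matching Expasy-style MW output to the printed 2 decimals.
Per-substitution mass deltas are fixed constants (L→Q +15.0, I/V→T −12.1/+2.0,
F→Y +16.0 Da), so the variant MW shift is additive; its sign depends on
composition (I→T decreases mass), so "variants are heavier" is not an
invariant and is not asserted.

**Hydropathy.**  GRAVY is the arithmetic mean of Kyte–Doolittle values.
All four substitution pairs strictly decrease hydropathy, so the TM-segment
GRAVY strictly drops whenever at least one substitution occurs.

## Superposition

Structures are compared on CA atoms.  CA-only is the robust choice here:
the variant changes side chains wholesale, and cryo-EM models frequently
miss side-chain atoms, while CA traces survive both.  A flag for more atoms
was considered and deferred; nothing in the analysis needs it.

**Correspondence.**  `by_resnum` pairs residues sharing (res_seq, icode)
that have a CA in *both* models — this implements loop trimming: residues
unresolved in the experimental model (unstructured loops, termini) simply
drop out of the pairing.  `by_position` (i-th CA to i-th CA) exists for
models with incompatible numbering.  Insertion codes participate in residue
identity.

**Kabsch fit.**  Closed-form least-squares rotation from the SVD of the
cross-covariance of centered clouds, with the standard determinant
correction (flip the smallest singular vector) so the result is always a
proper rotation, det = +1, even for mirrored or near-planar inputs.
Degenerate (collinear) clouds and n < 3 are rejected.

**Refinement.**  Emulates the iterate-and-reject behavior of interactive
alignment tools: fit, discard pairs with post-fit distance >
`reject_factor × RMSD` (default 2.0), refit, for up to `cycles` (default 5)
cycles, stopping early when nothing is discarded or fewer than 3 pairs
would remain.  `rmsd_all` is the cycle-0 all-pair RMSD, `rmsd_refined` the
final retained-pair RMSD; the retained-pair RMSD is provably non-increasing
across cycles (each discard removes above-average contributors; each refit
is optimal).  Both knobs are configurable because reference tools do not
document their exact settings; published RMSDs from such tools are
reproducible only within tolerance, not bit-exact.

**TM-only superposition** cuts both models to the residues inside the TM
spans before building the correspondence, quantifying how well the membrane
domain itself is preserved independent of soluble-domain motion.

**Dimers.**  One chain per structure enters the comparison; the default is
the first chain in file order, matching the practice of cutting one monomer
out of a homodimer (or the partner out of a heterodimer) before comparing.

## Structure input

gemmi parses PDB and mmCIF.  Policy applied on top: first coordinate model
only; HETATM and waters excluded; for altloc duplicates the
highest-occupancy conformer is kept, ties broken by alphabetically first
altloc; mmCIF is read with author (auth_) chain names and residue numbers so
annotations aligned to UniProt numbering and PDB-format files agree.

## SASA and the hydrophobic surface fraction

Shrake–Rupley with `n_points` (default 960) points per atom placed by the
deterministic golden-spiral lattice — no RNG, so results are exactly
reproducible and convergence can be checked by raising the point count
(960 vs 4000 differs by < 1 % on test bundles).  Radii: C 1.70, N 1.55,
O 1.52, S 1.80 Å, default 1.70; probe 1.4 Å (water).  Hydrogens are
ignored.  The KD-tree neighbor cutoff only limits which spheres are tested
for occlusion; it cannot change which points are accessible.

The *hydrophobic surface fraction* — Σ SASA of residues in {A,V,L,I,P,F,M,W}
over total SASA — is this package's numeric operationalization of
"hydrophobic patches shrink", which source studies show only as colored
surface renderings; reports label it as such.  The set is the
Kyte–Doolittle-positive residues plus A/P/W by convention and is
configurable.  Since every QTY pair maps a member of the set to a
non-member, the fraction strictly decreases whenever a substituted residue
has any exposed surface.

For surface comparisons the variant structure is the native model with
residues *relabeled* (coordinates untouched).  That is not a dodge but the
model's own premise — backbones are assumed near-identical — and it isolates
the compositional effect from prediction noise.

## Synthetic data generator

Stands in for downloaded sequences, annotations and models.  Defaults were
fixed once at what a structural biologist would call a plausible
transporter TM domain:

| parameter | default | rationale |
|---|---|---|
| n_helices | 6 (range 2–12) | typical multi-pass TM domain |
| helix_len | 22 | residues to span a lipid bilayer at 1.5 Å rise |
| loop_len | 6 | short connecting loops |
| TM composition | L .22, I .13, V .13, F .10, A .12, G .08, rest polar | hydrophobic-enriched; ~58 % substitutable |
| loop composition | S/T/N/Q/D/E/K/R/G/P-rich | polar loops |
| helix geometry | rise 1.5 Å, twist 100°, CA radius 2.3 Å | ideal alpha helix |
| bundle packing | axes on a circle, adjacent spacing 10 Å, alternating up/down | antiparallel bundle |

Coordinates contain *only* the TM residues — loops are omitted, not built —
so residue-number correspondence against the full-length annotation
exercises exactly the trimming real cryo-EM gaps require.  `perturb_structure`
adds i.i.d. Gaussian noise (σ per coordinate) then a rigid motion, giving
superposition pairs with known ground truth: at σ and n CA pairs the fitted
RMSD concentrates at σ√3·√(1−6/(3n)) (6 degrees of freedom absorbed by the
fit), e.g. 0.862 Å at σ = 0.5, n = 200.

What the generator does **not** emulate: real helix kinks and tilts,
side-chain packing, sequence correlations, lipid contacts, or
prediction-model error structure.  Passing tests therefore demonstrate the
*machinery* (transform, trimming, fitting, rejection, SASA bookkeeping and
their statistics) — they do not certify accuracy claims about any real
transporter, which depend on downloaded experimental and predicted models.

## Pipeline

The study manifest (YAML/JSON) lists entries (id, FASTA, topology, optional
native/variant structure + chains) and options (cycles, reject factor,
whether to add TM-only columns).  Failures are isolated per entry — one
unreadable structure yields an `error` cell, not an aborted batch — and the
run fails only if every entry fails.  Report cells are rounded (metrics to
2 decimals, RMSD to 3) so reruns on identical inputs are byte-identical.

## Problem sizes

Tests and the acceptance script use desk-scale inputs chosen for tight
feedback: bundles of 40–200 CA atoms, 50-seed Monte-Carlo for the noise
recovery check, 100–200 random proteins for transform/pI properties, and
≤10-atom toys for SASA oracles.  The whole suite runs in well under a
minute on one CPU.

## Known limitations

- No gapped sequence-alignment correspondence: models must share numbering
  (or use `by_position`).  Fine for native-vs-variant pairs of the same
  protein; wrong tool for homologs.
- pI model ignores charge-charge interactions and assumes fixed pKa values,
  as all table-based pI calculators do.
- SASA is accessible surface only (no molecular/SES surface), heavy atoms
  only.
- The external reproduction of published transporter RMSDs requires the
  original downloadable structures and is left to the user; tolerances are
  inherently loose because the reference superposition settings and exact
  TM spans are unpublished.
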