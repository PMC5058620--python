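# Methods

This note documents the models, conventions and numerical choices behind
`fvforge`, what the synthetic fixtures do and do not emulate, and the known
limitations of the implementation.

## Numbering and region assignment

Sequences are numbered by global alignment (BLOSUM62, gap open −10, extend
−0.5) against bundled per-chain consensus sequences of 125 positions;
aligned residues inherit the consensus position, insertions receive codes
A, B, … on the preceding position, and alignments below 30% identity are
rejected as unnumberable. This is a deliberate simplification of
HMM-based antibody numbering: positions are sequential (the scheme has no
reserved gaps), so position labels are internally consistent but not
interchangeable with IMGT/Kabat labels from other tools. Pre-numbered PDB
input is accepted as-is, which is how the structure stores are normally
populated.

CDR intervals are read from an editable table
(`src/fvforge/data/cdr_definitions.tsv`). The default "north" set uses
CDR1 = 27–38, CDR2 = 56–65, CDR3 = 105–117 (both chains, inclusive); a
narrower "chothia"-style set is bundled for the alternate benchmarking mode.
Both are approximations of the literature boundary sets re-expressed in this
package's sequential numbering. Framework = complement of the three
intervals. The conserved intra-domain cysteine pair sits at positions 23 and
104.

## Superposition and accuracy protocols

All RMSDs are backbone RMSDs over {N, CA, C, O} (the atom set is
configurable; whether carbonyl O belongs to "backbone" differs between
communities). Rigid fits minimize least-squares error via SVD with a
determinant correction (proper rotations only); degenerate references
(< 3 points, collinear) are rejected. The test suite cross-checks the fit
against an independently implemented Horn quaternion eigenvalue fit.

Protocols: the Fv RMSD fits and measures all shared backbone atoms of both
chains; a chain's framework RMSD fits and measures its FW atoms; a CDR RMSD
fits the framework only (one chain by default, both chains in the stricter
variant) and then measures the loop *without refitting*, so loop error
includes displacement relative to the scaffold. Loop comparisons require
identical loop positions in model and native — there is no partial-loop
RMSD. χ1 accuracy is the fraction of comparable residues (identical type,
side chains present, Gly/Ala excluded) whose χ1 circular difference is
≤ 40°; the χ1+2 variant requires both torsions within tolerance.

## Template and fragment stores

Template records are structures with resolution ≤ 2.5 Å (configurable),
indexed per chain. Selection maximizes min(VH identity, VL identity) for the
global template; ties break by better resolution, then lexicographic id —
the tie-break is this package's choice, as is the use of the shared-position
intersection as the identity denominator. "Sequence-identical antibodies are
ignored" is implemented as an exclusion of records whose full chain
sequences equal the target's (string comparison, independent of numbering
gap placement).

Fragment databases store each CDR's backbone with `n_anchor = 5` flanking
framework residues per side (anchor length and span/score thresholds are
not published for the original fragment search; 5 residues, span tolerance
0.8 Å and score threshold 25 are package defaults, all configurable). The
Fv-wide fallback database indexes all contiguous backbone windows of the
CDR lengths present, from anywhere in either chain. Duplicate-sequence
loops are retained on purpose — a redundant set is what captures multiple
conformations of sequence-identical loops. The substitution score is a plain
BLOSUM62 sum standing in for environment-specific substitution scoring
(no environment tables are published); the scorer is pluggable and its
default threshold is of the magnitude of published accepted-decoy scores.
Decoy ranking is a total order: anchor RMSD, then higher score, then source
resolution, then id.

Grafting maps the fragment loop through the joint two-sided anchor fit
(both anchors as one rigid body — deterministic, and consistent with the
anchor-RMSD ranking semantics) and errors on a seam Cα–Cα step > 4.5 Å.
Oversized steps *inside* the fragment are warned, not raised: they are the
source fragment's own geometry, not a graft artifact.

## Side chains and clash control

Side chains are built by natural-extension-reference-frame construction
from ideal bond lengths/angles; rings use fixed in-plane torsions and close
only approximately (idealized geometry, not energy-minimized). The bundled
backbone-independent rotamer library carries 2–3 rotamers per residue type
with prior probabilities; the interface accepts any library with the same
shape, e.g. a backbone-dependent one. Placement takes the most probable
rotamer that introduces no new clash, falling back to the least-clashing
one.

Two atoms clash when their distance is strictly less than 0.65 × (sum of
van der Waals radii); radii are tabulated per element (C 1.70 Å, N 1.55,
O 1.52, S 1.80, H 1.20). Covalently bonded pairs and 1–3 neighbours are
exempt — without that exemption every covalent bond would register as a
clash. Resolution is staged and greedy: re-sample clashing residues only,
then all side chains; the first clash-free structure wins, otherwise the
minimum-clash-count structure is returned with a warning. The greedy
re-sampler is deterministic given library order; it does not emulate the
accuracy/clash trade-off a relaxation engine would exhibit, and no claim is
made about that trade-off.

## Confidence model

P(x | s) = P(x ∩ s) / P(s) over a calibration table of (conditioning value,
RMSD) observations. Identity conditioning uses a sliding ± 2.5-point window
evaluated on a 1-unit grid, so each reported bin is 1% wide while windows
overlap — this reading reconciles the two published statements about bin
geometry. The ordered-pair denominator |A|(|A|−1) double-counts unordered
pairs symmetrically, so tables may store unordered pairs without changing
any ratio. Loop-length conditioning matches the (discrete) length exactly.
Empty bins raise an explicit "confidence unavailable" signal, never 0/0.
Expected RMSD at confidence p (default 0.75) is the smallest x on a 0.1 Å
grid with P(x | s) ≥ p.

Framework calibration comes from all-vs-all framework superimpositions
(VH–VH and VL–VL separately — per-chain accuracy is decoupled from
orientation error); loop calibration from leave-one-out loop modeling over
the library, pairing loop length with achieved backbone RMSD.

## Pipeline

Build order: select template → assemble framework (hybrid donors are
superimposed chain-by-chain onto the best global candidate, transplanting
its inter-domain orientation; a direct-superposition simplification of
consensus-frame re-orientation) → graft CDRs in the fixed order L2, H2, L1,
H1, L3, H3 (single-domain targets keep the restriction of that order) →
partial side-chain prediction → staged clash resolution → confidence +
liability annotation. The modeling path contains no randomness: identical
inputs and configuration give byte-identical PDB and JSON outputs. One
model per target; no ensembles.

Liability scanning is sequence-only (overlapping matches allowed, one hit
per start position; a hit's region is its start residue's region). Relative
ASA is Shrake–Rupley ASA (probe 1.4 Å, 196 sphere points) normalized by
empirical Gly-X-Gly maximum-ASA reference values — with the Shrake–Rupley
radii used here, the empirical reference centres a fully extended residue
near 100%, which the theoretical reference set does not. Exposure is
strict: max relative ASA over the hit span > 10%. The N-glycosylation
sequon's X is unrestricted by default; the X ≠ Pro refinement is a flag.
The motif table is an editable TSV and deliberately conservative — it is a
documented stand-in, not a validated development panel.

## Synthetic fixtures

`fvforge.synthetic` generates idealized Fv structures: serpentine
regular-strand backbones (ideal trans-peptide internal coordinates, CA–CA
≈ 3.80 Å), full rotamer-library side chains, two domains placed ~25 Å
apart with optional orientation jitter. Families are produced by mutating a
consensus-derived base sequence with per-member mutation fractions spaced
from 0 to 35% (bracketing the 80% template threshold) and deforming
coordinates with a smooth low-frequency displacement field whose per-atom
RMS grows linearly with mutation fraction (σ = 1.0 Å × (0.05 + fraction)),
plus 0.02 Å local jitter — so pairwise framework RMSD grows stochastically
with sequence distance, as in real template libraries, while local bond
geometry stays intact. Resolutions are drawn from U(1.5, 2.4) Å so every
member passes the store filter unless a test overrides it. Ground-truth
parameters are serialized next to any data written to disk.

These fixtures are geometric/statistical stand-ins: they are not folded
immunoglobulin sandwiches, loops are not Ramachandran-valid, and sequence
variation is uniform rather than germline-structured. Tests passing on them
validate the pipeline's contracts (numbering, selection logic, grafting
geometry, counting statistics, calibration coverage) — they say nothing
about accuracy on real antibodies, which requires real template libraries.

## Problem sizes and defaults

The bundled test and acceptance runs use families of 8–20 structures,
leave-one-out calibration over the family, and 200 modeled query targets
for the calibration-coverage check (1600 region observations) — sizes
chosen so the whole suite exercises every code path in a couple of minutes
on one CPU while keeping binomial error on coverage estimates near one
percentage point. All thresholds live in `PipelineConfig` (identity 80%,
resolution 2.5 Å, confidence 0.75, exposure 10%, clash factor 0.65, span
tolerance 0.8 Å, score threshold 25, 5-residue anchors) and serialize to
YAML.

## Known limitations

- No ab initio loop building: the cascade ends in a structured signal
  carrying the closest unequal-length fragment for an external modeler.
- Consensus numbering can shift a CDR boundary by a residue for targets
  with unusual loop lengths, which then routes that loop through the
  Fv-wide database (and may make its length-conditioned confidence
  unavailable) — visible in the README example.
- Idealized side-chain geometry: rings close only approximately; no
  hydrogens; no energy model.
- Orientation transplant assumes the orientation source's chains are
  individually good frameworks for superposition; no consensus-frame
  averaging.
- Confidence estimates assume the calibration library is representative of
  the query distribution; for queries far outside it the estimates are
  extrapolations and the package does not attempt to detect that.
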