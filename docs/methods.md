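# Methods

This note records the models, conventions and numerical choices behind
`surfcharge`, and what its synthetic tests do and do not establish.

## Structure model and parsing

Structures are parsed from PDB files with gemmi and held in a small
immutable model (atoms → residue views → structure). Author residue
numbering is preserved verbatim and never renumbered, because the census,
diff and design layers identify residues the way the field writes them
(K3 … K238); insertion codes are carried as key suffixes. Hydrogens are
always discarded — every criterion in scope is a heavy-atom distance —
and HETATM groups (e.g. a chromophore) are ignored unless requested, as
they take part in none of the censused interactions. Multi-chain files
default to the first chain, and detection is intra-chain only: the
analyses target a monomer's own surface network even when the deposition
is a crystallographic dimer. Of two altloc conformers the blank/'A' one
is kept, else the highest occupancy.

SEQRES entries without coordinates become *unresolved* residues
(`resolved=False`, no atoms), assuming author numbering follows the
SEQRES index — true for single-chain depositions numbered from 1, which
is the intended scope. Disordered C-terminal residues (GFP's K238) thus
stay in the census with empty partner sets. Without SEQRES the sequence
is limited to resolved residues and a warning is logged.

## Solvent accessibility

SASA uses the Shrake–Rupley construction: each atom's van der Waals
sphere is inflated by the probe radius (1.4 Å water), sampled with a
deterministic golden-spiral (Fibonacci) point set — no RNG, so
exposed/buried labels are exactly reproducible — and points falling
inside any neighbour's inflated sphere are occluded. Defaults: 960 points
per atom, Bondi-type single-atom radii (C 1.70, N 1.55, O 1.52, S 1.80 Å),
both configurable. Neighbour search is a k-d tree.

A residue's side chain (CB and beyond; CA stands in for glycine) is
labelled **exposed** when side-chain SASA exceeds 25% of a residue-type
reference maximum — strictly "more than 25%". The shipped reference
maxima derive from the theoretical maximum-ASA scale of Tien et al.
(2013, PLOS ONE 8:e80635): side-chain maximum = theoretical total minus
the glycine value (104 Å²) taken as a backbone allowance; glycine itself
gets the alanine–glycine increment (25 Å²) for its CA proxy. This keeps
the table published-value-derived and residue-complete; it is a package
choice, configurable per call, and relative fractions may exceed 1 for
highly exposed residues. Unresolved residues default to *exposed*:
termini disordered enough to be missing from the density are solvent
accessible.

Discretization: per-atom SASA is quantized at 4π(r+probe)²/n per sphere
point (≈0.13 Å² at 960 points), so invariance properties (rigid-motion
invariance ≤0.5%) are asserted at residue and whole-structure granularity
with n = 4000 in the tests.

## Interaction criteria

* **Salt bridge**: basic side-chain nitrogen (Lys NZ; Arg NE/NH1/NH2) to
  carboxylate oxygen (Asp OD1/OD2; Glu OE1/OE2) at ≤ 4.0 Å, with a 1.5 Å
  clash guard. Histidine and chain termini are not censused.
* **Hydrogen bond**: heavy-atom donor–acceptor distance in [2.5, 3.2] Å,
  both bounds inclusive. Donors are the basic residue's side-chain
  nitrogens plus its backbone N (flagged `backbone_involved`); acceptors
  are any backbone carbonyl O plus side-chain O/N/S acceptors
  (Asp/Glu/Asn/Gln oxygens, Ser OG, Thr OG1, Tyr OH, His ND1/NE2, Met SD,
  Cys SG). No angular term by default — the criteria are distance-only —
  though a proxy-angle filter (donor–acceptor–antecedent ≥ 90°) can be
  switched on.

The two windows are independent: a 3.0 Å ion pair is both a salt bridge
and a hydrogen bond and appears in both censuses. Sequence-adjacent
pairs (|Δresnum| ≤ 1) are excluded from the H-bond census as
covalent-neighbour artifacts; the salt-bridge census carries no adjacency
exclusion. Census tables report residue granularity: atom-level records
are deduplicated to unique (basic residue, partner, kind) triples keeping
the shortest distance, so a carboxylate contacting through both oxygens
counts one partner. A basic residue with ≥2 distinct salt-bridge partners
forms a *complex* salt bridge, with exactly one a *simple* one.

Detection uses a k-d tree over candidate atoms; an exhaustive O(n²) scan
is kept solely as the test oracle and is asserted equal to the fast path
on randomly generated planted fixtures.

## Census summaries

Totals count residue-level partners (a complex bridge with two partners
counts two). Means are reported two ways: per residue of the type
(total/count) and per *interacting* residue (total over residues with ≥1
partner of that kind). For the packaged wild-type GFP census the Lys
H-bond mean is 29/20 = 1.45 per residue but 29/16 ≈ 1.8 per H-bonded
lysine; the often-quoted "about 2 per lysine and 3 per arginine" matches
the per-interacting-residue reading (Arg: 16/6 ≈ 2.7 either way). Both
statistics are exposed so the reader can pick the denominator. Stored
values are full precision; printed strings are produced only at the
reporting layer, with both round-half-away-from-zero and truncating
formatters, because published tables are not always consistent about
which was used (4/6 printed as 0.66 is truncation, 0.67 rounding).

## Network diffs

Interactions are matched as (basic-residue position, partner residue
key): the basic side matches by position so K79→R79 lines up across
variants, while partner identities must agree exactly — partner keys name
the residue type, so a partner's own mutation would (correctly) break a
match. `maintained = A∩B`, `lost = A∖B`, `new = B∖A`; the set identities
|maintained|+|lost| = |A| and |maintained|+|new| = |B| are property-tested.
Reports star newly formed interactions, the convention used in published
comparison tables.

## Mutation design

Surface targeting takes every *exposed* residue of the source type;
buried ones are excluded with a recorded reason. Core exclusion backs out
substitutions on β-strands in a configurable index set (default
{1, 3, 4, 5, 6}, GFP's superstable folding core). Strand indices come
from PDB SHEET records ordered by first residue, from census labels
("β-strand 5"), or from an explicit position→index map, because sheet
naming in PDB headers varies. For GFP, strands {3, 5, 6} carry
K41/K45/K107/K113/K126, reproducing the five published back-mutations;
the explicit list is also packaged
(`fixtures.GFP_CORE_BACKMUTATIONS`) for direct use. Note the rule is
strand-membership in the stated set; no strand-1 or strand-4 lysine
exists in GFP, so the set and the residue list coincide there.
Substitution plans validate source types against the sequence and apply
as pure string edits; structural placement of the new side chain is out
of scope.

## Protonation

Protonated fraction is the Henderson–Hasselbalch closed form
1/(1+10^(pH−pKa)), base-10 throughout; default side-chain pKa values are
Lys 10.53 and Arg 12.48. The implementation reports computed values —
e.g. Arg at pH 13.0 gives 0.2319 (23.2%), a figure sometimes rounded to
"about 20%" in the literature; no rounded constant is hard-coded.

## Decay kinetics

Stability time courses are modelled as single-exponential
F(t) = F₀·e^(−kt) with free amplitude, no plateau term by default (a
fixed-plateau option exists for traces that level off). This is the
simplest model consistent with reporting a bare half-life; a model-free
"time to 50% by linear interpolation" helper is provided for comparison.
Fitting is bounded least squares (scipy), k ∈ [1e-6, 10] min⁻¹,
tolerances 1e-12, initialised from a log-linear regression of the
positive signals — which makes noiseless traces recover their generating
parameters to machine precision. Non-decaying traces pin k at the lower
bound and flag `converged=False` with a warning instead of raising.
Standard errors come from the Gauss–Newton covariance (JᵀJ)⁻¹·RSS/(n−2),
with t½'s error by the delta method (ln 2/k²·σₖ). Panel summaries report
per-cell mean t½ and standard error = sample SD/√n over replicates,
absent for a single replicate.

## Synthetic data

The toy-structure generator plants chosen atom pairs at exact distances:
each pair occupies its own row (default 30 Å apart), the two contact
atoms sit on the 0.001 Å PDB coordinate grid so planted distances survive
a write/read round-trip exactly, and each residue gets a full backbone
plus a minimal idealised side chain. Side chains point away from the
partner unless they carry the contact atom; random per-pair rotation
about the contact axis and Gaussian jitter of non-contact atoms (seeded,
seed mandatory) vary the geometry without touching the planted distance.
The generator rejects specs whose placements create unplanned contacts
between pairs. Chemical realism is explicitly not a goal — bond lengths
are idealised and some side chains stretched — geometric ground truth is.

Simulated decay traces are 100·exp(−ln 2·t/t½) + N(0, σ), clipped at
zero, on the assay grids used in practice (default 0–60 min in 10 min
steps); σ defaults reflect percent-of-initial fluorescence readings with
a few percent noise. The Monte-Carlo recovery check uses σ = 2
percent-points and 500 seeded replicates of a 51-minute half-life.

Transcriptions of the GFP basic-residue censuses (wild-type crystal
census, 26 rows; energy-minimised control vs 14R variant, 19 aligned rows
each) and of the detergent half-life table ship as TSV data files guarded
by checksum tests. One transcription note: the wild-type table lists
partner "D134" where the aligned comparison table and the GFP sequence
have G134; the files transcribe their sources verbatim, and since diffs
never cross the two tables at that cell the discrepancy affects no
computed number. The packaged 238-residue GFP sequence is
cross-validated against every census residue key in the tests.

## What the tests show — and don't

Planted-fixture tests prove the detectors implement their geometric
definitions exactly (against a brute-force oracle and against
construction-time ground truth) and the census/diff/design algebra is
exact on the published tables. They do not validate the exposure
classification against experiment: real structures have correlated
packing, waters and B-factor-dependent disorder that toy geometry does
not emulate, and published exposure labels depend on an unstated SASA
protocol. Recomputing the wild-type census from the 1GFL crystal
structure is therefore kept as a separate structure-level check
(`tests/test_acceptance.py`), which requires the user to supply the PDB
file at `data/1gfl.pdb`; per-residue agreement with the published labels
is a validation goal, not a guarantee. Known open point there: the
published text counts R109 among complex salt-bridge formers while its
table row lists the single partner E111; the classifier implements the
definition (≥2 distinct partners) without special-casing.

Half-life fitting is validated on synthetic single-exponential data;
real denaturation traces can be multi-phasic or plateaued, where the
single-exponential t½ is an effective summary, not a mechanism.
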