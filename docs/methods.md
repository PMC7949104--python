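# Methods

This note documents the models and procedures implemented in `trxmine`,
their assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design decisions taken where
the underlying workflow left the choice open.

## Candidate mining

Four filters reduce a predicted-protein set to complete thioredoxin-fold
candidates. Their default order is redundancy → E-value → completeness →
active-site cysteine; the order is configurable because the stages commute
on counts (the conservation invariant `n_kept + Σ removals = n_input` holds
under any permutation) but not necessarily on which id is removed by which
stage.

- **Redundancy** (default 90% identity) is greedy incremental clustering:
  sequences sorted by decreasing length (ties by id) join the first earlier
  representative at or above the threshold. Identity is exact matches over
  the *shorter* sequence's length, from a global alignment with match 1,
  mismatch 0 and a linear gap penalty of 0.5 per gap position. This is the
  CD-HIT convention; lowering the threshold can only merge more, so the
  representative count is monotone non-increasing in the threshold.
- **E-value** keeps a sequence iff its best (smallest) hit E-value is
  *strictly* below the cutoff (default 1e-5). The cutoff is read as an
  E-value, not a bit score — a bit-score threshold at that magnitude would
  be meaningless.
- **Completeness** flags (`has_start`, `has_stop`) are inputs carried as
  annotations; the DNA scaffolds they derive from are out of scope here.
- **Active-site cysteine** uses the profile hit's 4-residue CXXC window when
  present (keep iff position 1 or 4 is C — a single attacking *or* resolving
  cysteine suffices); without a window it falls back to a C-x-x-C regex scan
  restricted to the hit's alignment span. The fallback exists because hit
  tables do not always carry active-site columns.

## Markov clustering

Subfamilies come from a dense, from-scratch MCL: weights are bit scores
(symmetric, max over duplicate pairs, self-pairs dropped), self-loops equal
each node's maximum incident weight (1 for isolated nodes), columns are
normalized to sum 1, and the loop alternates expansion (matrix squaring),
inflation (entrywise power, default 6, then renormalization) and pruning
(entries below 1e-5 zeroed — but never a column's maximum — then
renormalized). Iteration stops when the largest entry change falls below
1e-6 or after 100 iterations (a non-converged run is interpreted anyway and
flagged with a warning). Column sums stay within 1e-9 of 1 after every
normalization.

Interpretation: rows with a positive diagonal are attractors; node *j* joins
attractor *i* when M[i, j] > 0; overlapping attractor systems are merged by
connected components so the output is always a partition. Nodes in different
connected components of the input can never be co-clustered, and a
re-expansion/re-inflation of the converged matrix reproduces the same
partition (idempotence).

The inflation default of 6 is unusually high by general-purpose MCL
standards and produces fine-grained subfamilies; it is exposed along with
every other MCL knob. Dense `numpy` matrices cap practical problem size at
a few thousand nodes, which matches the intended scale.

## Trees, medoids and representatives

Per-cluster distance matrices use alignment p-distance (1 − identical
positions / aligned length, gaps counted in the length). No substitution
model correction is applied — the trees serve medoid selection, not
divergence dating — though the distance function is a single seam to swap.

UPGMA merges the closest cluster pair at height d/2 with size-weighted
average linkage; ties break to the smallest (row, column) index in the
current working matrix, which makes the tree deterministic. Output trees
are ultrametric to 1e-9, reproduce an ultrametric input matrix exactly, and
agree with SciPy's average-linkage cophenetic matrix (an independent
implementation used as a cross-check in the tests).

Patristic sums are computed in linear time from subtree leaf counts: an
edge with s leaves below it contributes bl·s to every outside leaf's sum and
bl·(n−s) to every inside leaf's. The medoid is the leaf minimizing the sum
(ties lexicographic). Sums rather than means are stored; the medoid is
invariant to the 1/(n−1) normalization.

Representative selection for a cluster of N members uses k = ⌈N/100⌉
representatives — the smallest count keeping every load ≤ 100, and for k so
chosen N/k ≥ 50 always holds. The medoid is always first; the k−1 others are
the members whose bit scores to the medoid are nearest to k−1 evenly spaced
target values strictly between the observed score minimum and maximum
(ties lexicographic). Members are then assigned in contiguous near-equal
blocks along the sorted bit-score axis, one block per representative in
score order, and the medoid is re-assigned to itself. The blocked assignment
is a deliberate choice over literal nearest-score matching: the medoid's
self-similarity score sits at the extreme of the score range, so
nearest-score assignment would starve the medoid's side of the axis and
push another representative's load far past 100, defeating the 50–100
coverage bound that representatives exist to satisfy; blocks keep every
load at ⌊N/k⌋ or ⌈N/k⌉ (±1 after the medoid's self-assignment).

Trees serialize to Newick with branch lengths at 10 significant digits;
parsing reports the character position of unbalanced parentheses or a
missing semicolon, and round-trips are byte-identical on canonical form.

## Gene design

Codon optimization is the one-amino-acid-one-codon rule: every residue maps
to the host's most frequent codon (equivalent to CAI maximization under
this rule, so no separate CAI machinery exists), the stop is the host's top
stop codon (TAA for the bundled *E. coli* K-12 table), and a methionine is
prepended when the protein does not start with one. The bundled usage table
is an ordinary *E. coli* K-12 codon-fraction table; any table can be
supplied as `amino_acid codon frequency` TSV (frequencies are renormalized
per amino acid on load).

Restriction-site exclusion scans the *insert context* — `CAT` + CDS + stop +
`GAATTC` — so sites straddling the vector junctions are caught. The NdeI
site formed at the 5′ junction (whose ATG is the start codon) and the EcoRI
site at the 3′ junction are the only sanctioned occurrences; defaults forbid
NdeI (CATATG), EcoRI (GAATTC) and BamHI (GGATCC). Each offending occurrence
is repaired by the synonymous swap over the ≤ 3 codons overlapping the
6-mer — single swaps first, then pairs and triples, ordered by total codon
frequency lost — that destroys the occurrence without creating a new one
anywhere. The search is bounded and terminating; an unclearable site sets
`feasible = False` with full substitution diagnostics rather than raising.

N-terminus correction trims to an internal start when a strict majority
(> 0.5, configurable) of homolog start positions agree on one internal
residue in {M, L, I, V} (leucine, isoleucine and valine act as alternative
start codons); the residue becomes M. Signal-peptide removal takes the
cleavage position as input (prediction is out of scope) and prepends M when
the mature chain needs one.

Protein properties use average (not monoisotopic) residue masses and the
standard 280-nm coefficients ε = 5500·nTrp + 1490·nTyr, plus 125 per
cystine for the fully oxidized form, via Biopython's ProtParam
implementation.

## Redox and biochemical analysis

Fraction reduced is i_red/(i_red + i_ox) per lane. Plateau rescaling maps
the means of the two lowest-ratio and two highest-ratio points (widths
configurable) to 0 and 1 without clipping, mirroring the practice of
anchoring fully oxidized/reduced control lanes. The midpoint fit is
nonlinear least squares of f(r) = bottom + (top−bottom)·r^s/(r^s + K^s)
with s fixed at 1 — the thermodynamic form for a single two-electron
disulfide — and K parameterized in log space, initialized at the ratio whose
rescaled fraction is nearest 0.5. A free-slope mode exists as a diagnostic
and annotates fits whose slope deviates from 1 by more than 0.2. Noiseless
data inverts exactly (K recovered to 6 significant digits across
1e-3…1e3 M).

The Nernst conversion uses R = 8.314 J mol⁻¹ K⁻¹, F = 96485 C mol⁻¹, n = 2,
T = 298.15 K by default (samples equilibrate overnight at 25 °C) and the
glutathione couple reference −240 mV. K = 1 M returns the couple reference
at any temperature; E0 is strictly decreasing in K; the K ↔ E0 round trip is
identity to 1e-9. GSSG concentrations are always per-series inputs, never
assumed, because buffer compositions differ between proteins.

Kinetic activity is the ordinary least-squares slope of fluorescence over a
window after enzyme addition (≥ 3 points required); relative activity is
blank-corrected and normalized so the reference enzyme is exactly 1. Ellman
thiol counts use Beer–Lambert with ε(TNB) = 14,150 M⁻¹cm⁻¹ by default
(configurable). SEC calibration is least squares of ln(mass) against
elution volume; the oligomer call divides the apparent mass by the monomer
mass and rounds to the nearest integer, ties rounding down.

For proteins whose oxidized species is a covalent dimer band, the dimer
band intensity is used as i_ox directly: band intensity scales with subunit
count under stain-per-mass assumptions, so no factor-of-two correction is
applied. This assumption travels with the result.

## Synthetic data

The generator emulates the statistical structure of a mined superfamily at
desk scale, with defaults of 3 families × 16 leaves of ~80-residue
proteins: seeded Yule (pure-birth) trees; a root sequence with a planted
CGYC active site at position 30; per-site Poisson substitution counts
proportional to branch length (rate 0.15 substitutions/site per unit
branch) with uniform replacement over the 19 alternatives and motif columns
frozen; a fragment fraction (default 0.2, applied as an exact seeded count)
truncating 25% off the head or tail of a copy and clearing the matching
completeness flag; within-family similarities of 40 + 60·identity versus
between-family scores drawn in (0.5, 5); and per-sequence hits with
E-values of 10^−U(6,30) and the motif span where it survives truncation.
Titrations invert the Nernst relation for a chosen true E0, add Gaussian
noise (default sd 0.03) to the fractions, and emit intensity pairs summing
to 1000 arbitrary units per lane; noise lives on the fraction scale, where
the densitometric error model is interpretable. Kinetic traces are flat
baselines with a linear (optionally saturating) rise; SEC ladders invert
the log-linear law with Gaussian volume noise.

What this does *not* emulate: realistic profile-search score distributions,
amino-acid substitution biases (the pipeline under test uses p-distances,
so a rate-matrix model would add nothing testable), indels, nucleotide-level
scaffolds, correlated densitometry noise, or gel-image artifacts. Passing
tests therefore demonstrate correctness of the algorithms and calibration
of the estimators under clean, well-separated conditions — not robustness
to the messiness of real metagenomic data, where family boundaries blur and
between/within score distributions overlap.

All generators are pure functions of (config, seed); identical inputs give
byte-identical outputs, and every emitted record is covered exactly once by
the accompanying truth table.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by design:
48-sequence simulated datasets for end-to-end recovery, 200 random graphs of
≤ 8 nodes for exhaustive MCL verification, 200 random trees of ≤ 64 leaves
for patristic brute-force comparison, 1000 random 50-mers for the codon
sweep, and 100 seeded titrations per benchmark potential (12 ratios
spanning 5 decades around the midpoint). Tolerances: 1e-9 for ultrametricity
and patristic identities, 1e-6 relative for noiseless fit inversion, ±3 mV
for median potential recovery at noise sd 0.03. Degenerate inputs (flat
titrations, empty graphs, single-leaf matrices, both-zero band intensities)
raise typed errors rather than returning silently wrong numbers; the CLI
maps them to exit code 3.

## Known limitations

- Dense MCL and O(n²) alignment loops cap practical inputs at a few
  thousand sequences; no sparse or heuristic modes are provided.
- The greedy redundancy filter and p-distance trees are faithful simplified
  counterparts of CD-HIT and aligner guide trees, not drop-in replacements;
  absolute cluster compositions can differ from those tools on real data.
- The site-repair search is bounded to the codons overlapping one motif
  occurrence at a time; adversarial motif sets denser than 6-mers in
  low-degeneracy regions could defeat it (reported via `feasible=False`,
  never silently).
- Midpoint fitting assumes a single two-electron transition; proteins with
  multiple coupled disulfides need the free-slope diagnostic at minimum.
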