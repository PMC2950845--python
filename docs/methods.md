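# Methods

## The screening model

The package identifies glutamate-receptor-like channels by architecture: the
two halves of the clamshell glutamate-binding domain (S1, S2) must flank a
pore-loop channel module — two full transmembrane helices (M1, M2) around a
re-entrant partial helix (P). The screen is a monotone cascade (probe hits →
membrane filter → taxonomy filter → dual-probe intersection → topology), so
survivor sets can only shrink; this invariant is enforced by the report
validator.

### Local alignment and E-values

Probe search uses single-pass Smith–Waterman with affine gaps (BLOSUM62;
gap open 11, extend 1 in the BLAST convention, so a length-k gap costs
11 + k). Raw scores are converted to expectations with the standard gapped
Karlin–Altschul calibration for these parameters, λ = 0.267 and K = 0.041,
and the search-space length n is the total residue count of the database.
The engine is `Bio.Align.PairwiseAligner`; unknown residues (X) are scored 0
against everything. Scores are validated against an independent brute-force
Gotoh dynamic program in the test suite. Among co-optimal tracebacks the
engine's canonical first alignment is reported; no downstream contract
depends on the choice. The default cutoff E < 10 is deliberately permissive
(it *admits* roughly ten chance hits per search by construction); precision
comes from the later stages, and tests of "no random decoy survives" use the
stricter E < 1e-3.

### Membrane prediction

Transmembrane helices are a documented hydropathy surrogate for an HMM
predictor: the mean Kyte–Doolittle hydropathy over a sliding window of 19
residues, thresholded at 1.6. A maximal run of qualifying windows (gaps of
fewer than 3 window positions merged) is reported as one helix whose
interval is the *center span* of the qualifying windows, padded symmetrically
to the window length when the run is short. The center span, not the union
of windows, is reported because union intervals systematically over-extend
across short loops — far enough to swallow an adjacent pore segment or the
hydrophobic C-terminal stretch of S1. Each segment carries the logistic
score 1/(1+exp(−2·(mean−1.6))), so "passes the membrane test" is exactly
score ≥ 0.5.

Pore-loops are partial helices, so regions outside passing helices are
rescanned with a shorter window (9 residues). Candidates whose logistic
score falls in [0.25, 0.5) — hydrophobic enough to be membrane-like, below
the full-helix threshold — are reported as sub-threshold segments. The
pore detector picks the highest-scoring such candidate strictly between the
two flanking helices. The band floor 0.25 is configurable.

### Topology and group typing

A protein is a channel iff end(S1) ≤ start(M1) < end(M1) ≤ start(P) <
end(P) ≤ start(M2) < end(M2) ≤ start(S2). When more than two helices pass
(the eukaryotic receptors have an extra C-terminal helix, and signal
peptides often read as helices), M1/M2 are the outermost passing pair inside
the S1…S2 span, so extra helices cannot break classification. Group 1
requires a potassium-type selectivity-filter signature in the pore sequence:
`[TS].[GA][YF]G`, with a permissive fallback on the invariant `G[YF]G` core.
The published source of this partition names the filter but never prints a
pattern; the signature is therefore this package's own definition and is
configurable per run.

The signal-peptide check is a stated heuristic, not a trained model: at
least one positively charged residue (K/R) in the first five positions
(n-region), followed by a hydrophobic core — some 7-residue window with mean
hydropathy ≥ 1.8 starting no later than position 10, so the h-region
directly follows the n-region. The late-start restriction exists because
the binding domain itself contains hydrophobic stretches that would
otherwise fire the test when the N-terminal linker is short. Output labels
the flag as heuristic.

## Evolutionary Domain Network

Nodes are distinct domain *sets* (multiplicity and coordinates ignored;
overlapping annotations retained as distinct accessions); edges join sets
whose symmetric difference has exactly one element, which forces the
endpoints onto adjacent cardinality rows. Annotations weaker than E > 1e-3
are excluded from composition by default (the upstream annotation pipeline's
score handling is unspecified, so the threshold is ours and configurable).
Proteins with no surviving annotation keep an empty composition; the empty
set is a legitimate row-0 node adjacent to every singleton. Edge discovery
uses single-domain-removal lookups (the all-pairs symmetric-difference
criterion is reserved as the test oracle). Exchange paths between
compositions come in two flavors: virtual (removals then additions of the
symmetric difference; length |AΔB|; intermediates need not be observed —
they may have vanished or never been sequenced) and observed-only
(shortest path along network edges, which can only be longer).

## Conservation

Region alignments (S1, channel = M1+P+M2, S2) are aligned separately and
joined with recorded column boundaries. Column classes follow the ClustalX
conventions behind `*`/`:`/`.`: identical (one residue type, no gaps),
strong (all residues within one of STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF,
HY, FYW), weak (within one of CSA, ATV, SAG, STNK, STPA, SGND, SNDEQK,
NDEQHK, NEQHRK, FVLIM, HFY), otherwise none; any gap makes a column none,
because the consensus line marks nothing under gaps. The package consumes
alignments (aligned FASTA or Clustal); the bundled center-star aligner
(global pairwise alignments merged on the longest sequence's coordinates)
exists only so synthetic tests are self-contained and is explicitly
non-authoritative — it replaces a guide-tree progressive aligner because at
the low divergences the generator produces the two are equivalent and the
star construction is simpler to verify. Key-residue checks confirm total
conservation of the ligand-contacting S1 arginine and S2 aspartate at their
anchor columns.

## Trees, congruence and transfer inference

Trees are neighbor joining (Saitou–Nei) on p-distances (gap columns excluded
pairwise), with deterministic tie-breaking (lowest label-index pair) and
negative branch lengths clamped to zero with a warning. NJ on p-distance
replaces legacy guide-tree/display programs as the reproducible surrogate;
correctness is anchored by exact recovery on additive matrices.
Congruence between region trees is the unrooted Robinson–Foulds distance.

Horizontal transfer is bounded from below by small parsimony: with each
organism's channel group as a character on the species tree, the minimum
number of transfers is the parsimony score minus one, because a single
vertical divergence of the two groups already explains one state change.
The parsimony score is computed by unit-cost dynamic programming over
observed states (Sankoff recursion), which handles the trifurcating root of
unrooted trees exactly and is invariant to rooting.

Orthology uses reciprocal best hits: best = lowest E-value, ties broken by
higher raw score then lexicographic id, so the best hit is always unique;
a pair is reported iff each member is the other's best cross-proteome hit.
Retrieval ratios report hits/denominator of a reference set recovered by a
single probe at E < 10.

## Synthetic data: what it emulates and what it does not

The generator plants the architecture the screen must find. Channel
proteins are: optional signal peptide (M + two K/R + 10 hydrophobic core +
SGA), background linker, mutated S1 copy, linker, M1, linker, P, linker,
M2, linker, mutated S2 copy. Decoys omit the stated parts (soluble binders:
S1+S2 without helices; permeases: three helices without S1/S2; random:
background composition, 200–300 aa). Coordinates are 0-based half-open and
recorded exactly.

Key generator decisions:

* Only the S1/S2 probe copies are mutated at `substitution_rate` (per-site
  substitution to a uniformly random different residue; indels default off
  so coordinates stay exact). Helices, pores and linkers are structural
  features drawn fresh per protein, not mutated templates.
* Membrane helices are 19 residues from {A,I,L,F,V,M} with 10% background
  admixture. Linkers are i.i.d. background (Robinson–Robinson frequencies),
  length uniform on [5, 30].
* Pore segments (12 residues; Group 1 embeds TVGYG at a random interior
  offset, Group 2's scaffold alphabet contains no glycine so the filter
  signature cannot arise by chance) are rejection-sampled so every
  9-residue window mean sits inside [1.08, 1.55] — within the detector's
  sub-threshold band with a safety margin. The assembled membrane section
  is additionally redrawn until it presents exactly two passing helices
  with the best sub-threshold candidate covering the pore (and the full
  filter motif for Group 1): a draw whose random linkers lift the pore over
  the full-helix threshold does not represent the architecture being
  planted, so it is discarded rather than labeled a channel.
* The ligand-contacting S1 Arg and S2 Asp anchors and the Group-1 filter
  motif are excluded from mutation by default, mirroring their total
  conservation in real alignments; both protections are configurable off.

Species scenarios are two random bifurcating clades (branch lengths uniform
on [0.05, 0.3]) joined at the root; groups follow vertical descent and
exactly `transfers` leaves are reassigned across groups, alternating donor
clades. Reassigned leaves are chosen with distinct parents and never
directly off a clade root — otherwise two flips can collapse into one
parsimony change (a cherry) or merge into the root boundary (a basal leaf),
making the planted count unrecoverable. Region alignments evolve under an
infinite-sites model (each edge mutates a disjoint site set, about
branch-length × length sites, at least one; no site mutates twice), so
pairwise Hamming distances are exactly tree-additive and NJ recovery is
guaranteed by consistency rather than by luck of the seed.

What passing tests therefore show: the cascade, topology rules, group
typing, network, conservation and tree machinery behave exactly as
specified on data whose ground truth is known and whose planted signals are
unambiguous. What they do not show: performance on real proteomes, where
binding domains diverge far beyond 5% point substitution, helices vary in
length and composition, signal peptides defeat simple heuristics, and
region alignments are neither additive nor indel-free. The membrane and
signal predictors in particular are classical surrogates, not re-trained
models, and the conservation denominators of real alignments depend on gap
treatment the synthetic data never exercises.

## Benchmark sizes and numerical choices

The reference benchmark is 199 proteins (50 + 50 channels, 33 of each decoy
class) at substitution rate 0.05 — large enough that the ≥0.95 recall and
accuracy bounds are meaningful, small enough that the whole suite runs in
seconds. Tree checks use 50 random additive matrices (6–8 leaves) and
12-leaf transfer scenarios, where exhaustive parsimony oracles are still
feasible. Determinism: all randomness flows through seeded numpy
generators; identical (spec, seed) reproduce FASTA and reports byte for
byte. Degenerate inputs are errors, not silent defaults: empty databases,
missing lineages for survivors (a survivor is never silently assumed
eukaryotic), overlapping S1/S2 hits, anchor columns outside their region,
pairs with zero comparable columns.

## Known limitations

* The transcribed annotation table lists 98 protein numbers across its rows
  although the source text speaks of 100 sequences; the fixture reproduces
  the table as printed and checks per-row consistency only.
* Conservation counts on real data depend on the upstream aligner; the
  bundled star aligner is for tests.
* The transfer bound is a parsimony lower bound on the species tree; it
  does not infer donors, recipients or timing.
* Retrieval ratios against the real human receptor complement require the
  actual human sequences, which are referenced by accession in the packaged
  table but not distributed.
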