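# Methods

This note documents the models and procedures implemented in `cubkit`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make results
reproducible.

## Sequence handling

Coding sequences are uppercased on read and RNA-style input (U) is mapped
to T. A CDS must have length divisible by 3 and contain only A/C/G/T;
records violating either are always rejected (ambiguity codes are not
distributed fractionally — the simplest defensible contract, logged per
record). Strict validation (default) additionally requires an ATG start and
a TAA/TAG/TGA terminal stop; lenient mode keeps non-canonical records and
flags them. The terminal stop is excluded from codon counts, composition
and every index, so a canonical CDS of L nt yields L/3 − 1 counted codons
and an equally long translation. Only the standard genetic code is shipped
(a table-id parameter is reserved); the 6-fold families Leu, Ser, Arg are
treated as single families of size 6 throughout, giving the degeneracy
census {1: 2, 2: 9, 3: 1, 4: 5, 6: 3}.

## Composition

GC1/GC2/GC3 are computed over *all* sense codons, Met and Trp included, so
the identity GC = (GC1 + GC2 + GC3)/3 holds exactly and is asserted in
tests. GC3s and the silent base frequencies A3s/T3s/G3s/C3s are restricted
to synonymous codons; following CodonW semantics the X3s denominator for
base x counts only codons whose family offers at least one x-ending codon
(ending in x must be a silent option). GC3 and GC3s are both emitted, since
published tables sometimes relabel one as the other.

## Protein metrics

GRAVY is the mean Kyte–Doolittle hydropathy; aromaticity the fraction of
F/Y/W. Molecular weight sums ExPASy average residue masses plus one water.
The isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14] to
1e−4, using a single bundled Lehninger-style pKa set (N-term 9.69, C-term
2.34, D 3.86, E 4.25, C 8.33, Y 10.07, H 6.00, K 10.53, R 12.48). The
net-charge function is strictly decreasing in pH, so the root is unique.
Published pI values depend on the pKa set of the tool used, which is
frequently unstated; absolute agreement with third-party pI tables is
therefore not claimed.

## Wright's ENc

Per degenerate family with n ≥ 2 observed codons,
F = (n Σ p² − 1)/(n − 1). Families with n < 2 carry no information and are
excluded; so are families with F = 0 (the estimator 1/F̄ would diverge —
the CodonW-like convention). Class means F̄ₖ are taken over
k ∈ {2, 3, 4, 6}; if the single 3-fold family (Ile) is missing, F̄₃ is
imputed as (F̄₂ + F̄₄)/2; a missing 2-, 4- or 6-fold class makes ENc
undefined for that gene (reported as NaN in profile tables and dropped by
ENc-dependent analyses). ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at
61: on finite genes the unbiased estimate can exceed the analytic maximum,
and published tables print exactly 61.000 in that case.

## CAI, CBI, Fop and the reference

Relative adaptiveness is w(c) = count(c)/max-family-count in a reference
pool; codons absent from the pool get w = 0.01 (rare, never impossible).
CAI is the geometric mean of w over codons of degenerate families (Met,
Trp, stops excluded); Fop the optimal-codon fraction among synonymous
codons; CBI = (N_opt − N_rand)/(N_tot − N_rand) with N_rand the optimal
count expected under uniform within-family usage. When reference counts tie
within a family, several codons share w = 1; the designated optimal codon
is then the lexicographically smallest, so results are deterministic. The
default reference pools the dataset's five lowest-ENc genes — the only
self-contained, reproducible choice when no external reference organism is
given; consequently absolute CAI/CBI/Fop values are comparable within a
dataset, not across tools.

## Selection diagnostics

The ENc–GC3s expected curve is ENc* = 2 + s + 29/(s² + (1 − s)²). A gene is
"on" the curve within a purely presentational tolerance of 0.5 ENc units
(configurable); bias classes are strong (ENc ≤ 35), weak (50 ≤ ENc ≤ 61)
and intermediate. PR2 coordinates are x = G3/(G3+C3), y = A3/(A3+T3) over
synonymous third positions by default, with a `fourfold_only` scope for the
classic formulation restricted to 4-fold boxes. The neutrality plot is an
OLS fit of GC12 on GC3 (scipy `linregress`); slope×100 is reported as the
mutation-pressure percentage. Correlation matrices use two-sided Pearson
tests with star tiers * p<0.05, ** p<0.01, *** p<0.001 (the middle tier is
added for completeness). Expression analysis regresses FPKM on ENc per
condition and on a "total" condition defined as the per-gene sum across
conditions; both Pearson r and the OLS slope are reported, because
published "correlations" below −1 are recognisable as slopes.

## Optimal codons

Genes ranked by (ENc, gene_id) — the tie-break makes pool membership
deterministic — give the bottom-k pool (high-expression stand-in) and
top-k pool (low-expression), k = 5 by default. Over the 59 informative
codons the criteria are RSCU > 1 in *both* pools (strict inequality) and
ΔRSCU ≥ 0.08 (inclusive; an `inclusive=False` flag gives the strict
variant, since published wordings differ). Stop codons are never
candidates. Codons of families absent from either pool are marked
non-evaluable rather than scored.

## Multivariate analyses

RSCU matrices hold genes (or species "super-gene" pools) × 59 codons, with
missing families imputed by column mean by default (alternatives: drop the
gene, or zero). PCA runs on centered, unscaled values — RSCU is already
family-normalised, and column scaling would inflate rare-family noise; a
`scale=True` mode exists. Component signs follow a fixed convention (the
largest-magnitude loading is positive). Clustering uses squared Euclidean
dissimilarity with between-groups average linkage — the standard reading of
SPSS "intergroup linkage" — via scipy, and serialises merge heights as
Newick branch lengths.

## Phylogenetics

p-distance is the proportion of differing sites; complete deletion
(default) removes every column with a gap in any row, matching the
"gaps removed" convention, with pairwise deletion available. Neighbor
joining is the Saitou–Nei algorithm with the Studier–Keppler Q-criterion;
ties resolve to the smallest index pair and negative branch lengths are
clamped to zero (deficit logged). On additive matrices the generating tree
is recovered exactly (fuzzed in tests up to 12 taxa). Bootstraps resample
alignment columns with replacement, rebuild the NJ tree, and score each
internal split of the full-data tree by the percentage of replicates
containing it; rows are sorted by id internally so supports are independent
of input order, and the seed is mandatory. Alignment itself is out of
scope — pre-aligned input is required.

## Synthetic-data generator

Each gene draws a length uniformly over 393–1116 nt (multiples of 3, the
span observed in small heat-shock families), amino acids i.i.d. from an
average protein composition, and codons within each family with probability
∝ exp(s_g·1[c preferred] + γ_g·nGC(c)). The bias strength is
s_g = s₀ + U(0, S) with S = 3 by default and a baseline s₀ = 0.5 shared by
all genes: real genomes keep preferred codons at RSCU > 1 even in weakly
expressed genes, and without that floor the "RSCU > 1 in both pools"
optimal-codon criterion degenerates into a coin flip on the low-ENc pool.
The drift weight γ (default −0.2, mildly AT-rich) acts on third positions
only, or on all positions in the mutation regime — there codons are drawn
jointly (amino-acid frequency × Boltzmann weight on the codon's full GC
count), which moves GC12 and GC3 together and yields neutrality slopes
near 1; the selection regime (third positions only, γ fixed) yields slopes
near 0. Preferred codons are drawn per synonymous family, with each of the
12 default subfamilies re-drawing a family's preference with probability
0.3, so clustering follows subfamily rather than species. Expression is
log-linear in bias strength, log FPKM = a + b·s_g + condition offset +
N(0, σ) with a = 3, b = 0.8, σ = 0.6 over conditions normal/salinity/
drought — enough to induce the negative FPKM–ENc correlation the expression
analysis expects. Every run is fully determined by the seed (byte-identical
FASTA), and a truth JSON echoes the config plus per-gene s_g, γ_g and the
planted preference maps.

What the generator does **not** emulate: codon autocorrelation along a
gene, realistic protein domain structure, indels (so its output doubles as
a gap-free alignment only when lengths are fixed), isochore structure, or
any coupling between amino-acid composition and expression. Passing tests
therefore demonstrate correctness of the estimators and the internal
consistency of the diagnostics under the stated model — not that real
genomes satisfy the model.

Deterministic worked fixtures complement the generator: a 393-nt and a
1116-nt CDS (length spread 723 nt, proteins of 130 and 371 residues), a
140-value ENc vector with exactly 94 values in the weak-bias band and none
at or below 35, and four per-species optimal-codon sets whose union has 12
codons with third-base tally A:4, T:3, G:3, C:2. The per-species sharing
pattern is fixed; membership of the eight species-unique codons is an
arbitrary deterministic assignment consistent with the per-species counts.
One of the published codons in that list, UGA, is a stop codon and is kept
verbatim in the fixture data only — the scan itself can never emit it.

## Problem sizes

Defaults keep everything desk-scale: oracle-equivalence suites run on ≥100
random tables of 60–400 codons, clustering oracles on ~20-row matrices, NJ
fuzzing up to 12 taxa, regime comparisons on 500 genes, and bootstrap
examples at 100 replicates (the API default is 1000). The full test suite
runs in well under a minute on one CPU.

## Known limitations

- Only the standard genetic code; no ORF finding or sequence repair.
- CAI/CBI/Fop absolute values are reference-dependent by construction.
- ENc is undefined (NaN) for genes with too little synonymous usage rather
  than extrapolated from partial classes.
- p-distances need not satisfy the triangle inequality, and NJ on strongly
  non-additive matrices is a heuristic like any other NJ.
- The PR2 and optimal-codon procedures inherit the arbitrariness of their
  published thresholds (0.5 center, ΔRSCU 0.08, k = 5); all are exposed as
  parameters.
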