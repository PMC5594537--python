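# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the package. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinates and formats

All internal coordinates are 0-based half-open; user-facing TSV reports are
1-based inclusive (genome-browser convention). Minus-strand features report
the reverse-complemented (5'→3') sequence on extraction. FASTA, GFF3
(1-based closed on disk), BED (0-based half-open), newick, TSV/JSON and a
single YAML run configuration are the only on-disk formats. A `RunConfig`
holds every tunable of every stage; it serializes to YAML and reloads with
identical effect, and all random streams derive from its seed.

## Homology search and acceptance filters

The search is a self-contained seed-and-extend local aligner: exact
`word_size` (default 11) matches on either strand seed a gapped affine
Smith–Waterman extension (numba kernel) in a window around the seed
diagonal. Nearby diagonals (within 2× the word size) share one window;
separated diagonal groups are extended independently, so tandem copies ~100
nt apart are each reported. Scoring defaults are blastn-like: match +1,
mismatch −2, gap open 5, gap extend 2 (a gap of length *k* costs
`open + k·extend`). Significance uses E = K·m·n·e^(−λS), with λ solved
numerically from Σᵢⱼ pᵢpⱼe^(λsᵢⱼ) = 1 under the background frequencies and
K fixed at the tabulated ungapped value for the +1/−2 scheme (0.62); both
are explicit config fields. E-value cutoff 10⁻⁴. Overlapping hits at one
locus are merged to the lowest-E hit (ties: higher identity, then leftmost
coordinate); because a hairpin is nearly self-complementary the same locus
is found on both strands, so merging ignores strand.

The six acceptance criteria and their defaults:

| flag | quantity | default bound |
|------|----------|---------------|
| c1 | query length − aligned subject span | ≤ 20 nt |
| c2 | edit distance (substitutions + indel columns) between candidate and reference mature | ≤ 2 |
| c3 | candidate folds into a hairpin with the mature on one arm | — |
| c4 | hairpin MFE | ≤ −15 kcal/mol |
| c5 | max one-sided bulge/internal-loop size in the stem | ≤ 12 nt |
| c6 | mature positions unpaired in the miRNA/miRNA\* duplex | ≤ 6 |

Criterion c1 counts the aligned subject span (genomic extent of the hit).
The mature is located inside the candidate by infix edit-distance alignment
(edlib); c2's count is substitutions plus indel columns of the global
alignment of the two matures. For c6, bulged (unpaired) mature positions
count as mismatches; the star interval is inferred from the partners of the
mature with the canonical 2-nt 3'-overhang rule. A mature that merely
shades a base or two into the terminal loop is tolerated (those positions
count as duplex mismatches); the candidate is rejected as a non-hairpin
only when the mature spans the loop onto both arms, lies entirely in the
loop, or misses the stem.

Paralogue grouping treats hits of one query as distinct loci when they lie
on different chromosomes or more than 200 nt apart (config field; the
underlying study describes its grouping only as "rigorous criteria", so
this is the package's explicit operationalization). Context classification:
intergenic iff no gene overlap; intron–exon iff the locus overlaps both
exon and intron sequence of a gene; otherwise exonic or intronic by the
containing feature (introns are derived from gene/exon records when
absent). TE screening aligns the candidate against each library entry on
both strands and reports families with ≥ 50 aligned columns at ≥ 80%
identity — a library-alignment approximation of a RepeatMasker screen, not
a reimplementation of repeat discovery.

## Hairpin folding

Pre-miRNAs are single stem-loops, so the structure class is restricted to
one hairpin: a chain of nested WC/GU pairs separated by stacks, bulges and
internal loops (each side capped at 15 unpaired nt), closed by one terminal
loop ≥ 3 nt. This bounds the DP at O(L²·cap²) and keeps the energy model
auditable; there is no multiloop recursion, no partition function, no
pseudoknots, no dangles or coaxial stacking. The energy model is a minimal
nearest-neighbor table: Turner-style stacking energies for the 36
outer/inner pair combinations plus tabulated hairpin/bulge/internal-loop
penalties with Jacobson–Stockmayer log extrapolation and a capped asymmetry
term. Absolute MFE values therefore differ from RNAfold; the −15 kcal/mol
threshold is a config default chosen for this model, and an adapter ingests
dot-bracket + energy from an external folder when exact Turner energies are
wanted. Ties are broken deterministically: prefer more pairs, then the
first optimum in scan order. The open chain has energy 0, so reported MFE
is ≤ 0. The brute-force oracle in the tests enumerates every nested pair
chain explicitly and rescopes the same energy tables — the DP and the
enumeration agree exactly for all test sequences ≤ 30 nt.

## Multiple alignment and substitution analyses

Ortholog sets are aligned progressively: all-pairs affine Needleman–Wunsch
→ Jukes–Cantor distances → neighbor-joining guide order → profile–profile
alignment (numba kernel; profile columns scored by average pairwise
substitution score). Alignment parameters: match +2, mismatch −1, gap open
4, gap extend 1. The procedure is deterministic given the inputs.

Distances use pairwise deletion (each row pair compared at mutually
ungapped sites): p = mismatches/compared sites and
N = −(3/4)·ln(1 − 4p/3), flagged undefined at p ≥ 0.75 and excluded from
averages. Absolute rates use R = N/2T with T defaulting to 15 MY — the
divergence depth of the whole panel. That formula is exact only when every
pair's divergence equals T, so the rate-recovery experiments evolve
families on a star tree of depth 15 MY; on the real, highly unbalanced
species tree the mean pairwise divergence is much smaller than 2T and the
per-family mature regions carry too few substitutions (~0.3 per family at
3.2×10⁻¹⁰/site/year) for a tight per-cohort estimate.

Transition/transversion counts are raw pairwise counts at complete column
pairs; the reported ratio ti/tv has a no-bias expectation of 0.5 (one
transition vs two transversion types per site), and the transition fraction
ti/(ti+tv) is reported alongside to avoid ambiguity. Directional
substitution patterns assign direction by column consensus (majority state;
ties split equally) over complete-case columns — an auditable approximation
of a maximum-likelihood pattern estimate, not a reproduction of one.
Regional conservation splits a region into three contiguous blocks
(remainder left-first; 21 nt → 7/7/7); a column is conserved iff all taxa
share one non-gap base. Base composition excludes N and gaps from the
denominator.

## Neutrality statistics

All neutrality statistics use complete deletion (columns containing a gap
or N dropped), the default of the standard desktop tools for these tests.
Per locus: S (polymorphic columns), η (k-allele columns contribute k−1
mutations), singletons (alleles observed in exactly one sequence, capped at
k−1 per column), π (mean pairwise differences; per site when divided by
complete columns), θ_W = S/(a₁L), Tajima's D with the 1989 constants, and
Fu & Li's F (with an outgroup polarizing external mutations) or F* (the
singleton variant, the default when no outgroup is supplied) with the
corrected variance constants. Degenerate cases (S = 0, or zero variance as
at n = 3, S = 1) are reported as NA and excluded from distributions. The
statistics are verified against independently coded straight-from-formula
oracles to 10⁻¹² and, for D and π, against tskit on coalescent-simulated
data.

Significance comes from a fixed-S neutral null: constant-size,
no-recombination coalescent genealogies (simulated with msprime; the time
scale cancels under fixed S), with the observed S mutations dropped on
branches with probability proportional to branch length, and two-sided
empirical p-values p = 2·min(P(null ≤ obs), P(null ≥ obs)). The null mean
of D at n = 10, S = 20 is within ±0.15 of zero and the p-values are
uniform under the null (both are asserted in the acceptance tests).

**Interpretation caveat.** The species panel is a cross-species sample,
not a within-population one. The "sample genealogy" is the fixed,
unbalanced species tree: long outgroup branches concentrate variants on few
lineages, so strongly negative D and F* arise on perfectly neutral
simulations. The package computes the statistics exactly as standard tools
do on such panels; negative values should be read against this null, which
is why significance is assessed by simulation rather than against the
textbook N(0,1)-ish reference. The cultivated-vs-wild diversity summary
defaults to cultivated = {O. sativa indica, O. glaberrima} and wild = the
remaining taxa, over the loci significant for both tests (falling back to
all loci when none are).

## Phylogeny

Saitou–Nei neighbor joining with the standard Q-criterion, deterministic
lowest-index tie-break and two-point branch-length formulas; exact on
additive matrices (asserted over 100 random 5–10-taxon trees). Negative
estimated branch lengths can be clamped to zero with the deficit moved to
the sibling (config flag, off by default, on in the pipeline for display
trees). Rooting places the root at the midpoint of the branch separating a
user-specified outgroup clade; a non-monophyletic outgroup is an error.
Distances default to JC from the alignment module. No bootstrap, ML or
Bayesian inference.

## Tandem clusters

Same-chromosome, same-strand loci of one family are chained by single
linkage with gap ≤ 1000 nt (default; the known two-membered rice clusters
are ~100 nt spaced and transcribable as single units, so 1 kb keeps
compactness while tolerating spacer variation). Percent identity is
identical columns / alignment length × 100 from global alignments
(Biopython pairwise aligner; verified against an independent DP oracle).
The deletion signature globally aligns the two members of a 2-member
cluster, canonically right-shifts score-equivalent gap runs (repeatful
sequence makes gap placement ambiguous), and reports the longest gap run in
member 2 starting within 5 nt downstream of its mature 3' end, flagged as
matching when within ±2 nt of the expected 22. The hand-curated
duplication-order narrative for the nine rice clusters is out of scope; the
identity matrix and an NJ dendrogram are emitted for manual interpretation.

## Synthetic-data generator

The generator is first-class, tested code that defines the study
conditions. Defaults: the 10-taxon ultrametric species tree with the
FF genome splitting 15 MYA, the BB genome 9.11 MYA and the AA crown at
2.93 MY; 50 families plus one tandem-cluster family; per-region rates
r_mature = 3.2×10⁻¹⁰, r_star = 8×10⁻¹⁰, r_loop = 2×10⁻⁹ substitutions/site/
year (the conservation ordering mature ≤ star ≤ loop is enforced);
transition/transversion rate ratio κ = 2; loop-only indels at 10⁻¹⁰
events/site/year with mean length 3 (the study system gives no empirical
indel rate for precursors, so this is an order-of-magnitude choice exposed
in config); duplication probability 0.3 per lineage per locus, copying the
locus to a different chromosome; TE-derived probability 0.29 per family;
nine planted clusters (five 2-membered with ~100-nt spacers and a 22-nt
deletion immediately downstream of the mature in member 2, four
1-membered); background GC 0.44; three chromosomes of 30 kb per species —
a scaled-down genome that keeps the full pipeline and its tests fast while
preserving locus density low enough for unambiguous truth matching.

Sequence evolution is a per-site Poisson jump chain: a branch of t MY at
per-site rate r contributes Poisson(r·10⁶·t) substitution events, each a
transition with probability κ/(κ+2). Indels are confined to the terminal
loop so mature/star coordinates stay exact by construction. An optional
`seed_rate_factor` scales the rate of mature positions 2–7 (the seed-like
block) for conservation-profile experiments; the default is 1 (uniform
within the mature).

Ancestral precursors are built as flank + mature + loop + revcomp(mature) +
revcomp(flank) and rejection-sampled until they pass the structural filters
with margin (MFE ≤ −20, bulge ≤ 8, duplex mismatches ≤ 2) — a real
pre-miRNA passes the filters by definition, and without this screen
long-loop ancestors occasionally fold with oversized bulges. The cluster
family additionally evolves without loop indels (so the planted deletion
stays exactly 22 nt in every lineage) and the whole evolved set, including
the shortened second members, is re-sampled until every species' copies
remain valid precursors — mirroring the fact that the modelled tandem
family is observed across the panel. TE "derivation" is simulated as the
detectable signature only: each TE-derived family's library entry embeds a
70-nt exact fragment of the family ancestor inside random flanks (plus
decoy entries with no fragment); no transposition machinery is modelled.
Queries are the query taxon's leaf precursors, plus the shortened second
member for the cluster family (each member of a tandem family is its own
reference precursor).

What the generator does **not** emulate: genome-scale repeat landscapes and
low-complexity sequence (backgrounds are i.i.d.), real TE families,
recombination, selection (neutrality-test calibration uses the coalescent
module instead), rate variation across families, and assembly artifacts.
Passing the planted-truth tests therefore demonstrates correctness of the
analysis chain under the stated generative model, not annotation
performance on real genomes.

## Problem sizes and checks

The default test and acceptance configuration runs 10 species × 51 families
on 90-kb genomes (≈ 790 planted loci), 200-family rate-recovery
experiments, and 10,000-replicate coalescent nulls — sizes chosen so the
whole suite completes in about a minute while every Monte-Carlo assertion
retains comfortable margin. The per-locus neutrality p-values in the
pipeline default to 500–2000 replicates; raise `neutrality_reps` for
publication-grade p-values.

Two acceptance checks depend on the original study's supplementary
sequences (per-locus ortholog alignments; the nine rice cluster
sequences), which this repository does not redistribute. The corresponding
tests compute nothing until those files are placed under
`data/supplementary/` as described in their failure messages.
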