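# Methods

This note documents the models and estimators `fadevo` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that make runs
reproducible.

## Genetic codes and synonymous families

A `GeneticCode` binds the 64 codons to amino acids via an NCBI translation
table and derives the synonymous-family partition (codons grouped by
encoded amino acid).  Under table 1 there are 61 sense codons in 20
families — 2 one-fold, 9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold.
Under table 6 (ciliate nuclear) TAA and TAG encode glutamine, giving 63
sense codons and a four-fold Gln family; only TGA remains a stop.  Table 6
is the CLI default because silent mistranslation of a ciliate input would
corrupt every downstream count-based statistic; the table in force is
recorded in every output.

CDS validation is strict: length must be divisible by 3, ambiguity
characters (including N) are rejected with positions rather than imputed
(codon-usage statistics are count-based and imputation would bias them),
internal stops are errors, and a terminal stop is stripped and recorded.
Genes that fail validation are reported and skipped in pipeline runs, not
repaired.  Coordinates everywhere are 0-based, half-open.

## Codon-usage statistics

**RSCU.**  `RSCU(c) = count(c) · k / family total` with k the family
degeneracy.  Families with zero observations give NA (never 0): a silent
zero would distort the PCA and regressions downstream.

**GC3s** is G+C at third positions of codons in families with degeneracy
≥ 2.  The neutrality plot instead uses **GC3** (third position over all
codons) against **GC12** (mean of first- and second-position GC), fitted
by ordinary least squares; slope ≈ 1 reads as mutation pressure dominating,
≈ 0 as selection on codon choice.

**ENc** follows Wright's estimator with CodonW-compatible conventions.
Per family with n ≥ 2 codons observed, `F = (nΣp_i² − 1)/(n − 1)` — the
unbiased homozygosity estimator.  F is averaged within each degeneracy
class; families with F = 0 are treated as uninformative and excluded from
the class mean (as CodonW does — a class mean of zero would make the
estimator blow up on short genes).  `ENc = Σ_k N_k / F̄_k`, with one-fold
families contributing their count, a missing three-fold class imputed as
`(F̄₂ + F̄₄)/2`, the result capped at the code's sense-codon count (61 or
63), and NA when any other class has no informative family.  Genes under
30 codons trigger a warning; gene-set analyses exclude genes under 10
codons by default (both thresholds configurable).

**PR2** pools third-position nucleotide counts over four-fold-degenerate
families only (the standard Sueoka formulation) and reports
`A3/(A3+T3)` and `G3/(G3+C3)`, NA when a denominator is zero.

**RSCU PCA** operates on the matrix of RSCU values over codons of
families with degeneracy ≥ 2, imputes NA entries with column means
(logged), column-centers, and decomposes by SVD on the covariance scaling
(correlation scaling would up-weight rare codons whose RSCU is mostly
sampling noise).  Component signs are fixed so each loading vector's
largest-magnitude entry is positive, making scores reproducible.

**HGT screen.**  The family-vs-background comparison uses two-sample
Mann–Whitney rank-sum tests on ENc and on GC3s (exact null distribution at
small sample sizes, via scipy).  The paper-style comparison is visual; the
rank-sum test is the minimal distribution-free quantitative analogue and
is labeled as an addition.  Verdict language is descriptive — "consistent
with host genome CUB" / "CUB outlier" — never causal, and raw p-values are
reported alongside Benjamini–Hochberg-adjusted ones.

## NG86 dN/dS and the branch screen

**Sites.**  Each codon position carries one site of mass, split by the
fraction of viable single-nucleotide changes that are synonymous.  Changes
into stop codons are excluded and the position's mass renormalized over
the remaining changes; if all three changes at a position create stops the
position contributes nothing (so s + n ≤ 3).  Site counts for a pair are
averaged over the two sequences.

**Differences.**  Per codon pair, synonymous/nonsynonymous differences are
averaged over all minimal mutational pathways (orderings of the differing
positions); pathways through stop codons are discarded, and the rare pair
whose every pathway is blocked is skipped and tallied.  Proportions
`pS = Sd/S`, `pN = Nd/N` are Jukes–Cantor corrected,
`d = −(3/4)ln(1 − 4p/3)`; a proportion ≥ 3/4 raises an error naming the
distance (the correction is undefined — note this makes single-codon
"pairs" with one synonymous difference uncorrectable, which is why the
per-codon-pair difference counts are also exposed directly via
`pathway_differences`).  ω = dN/dS, NA when dS = 0.  Codons containing a
gap are dropped pairwise (pairwise comparisons) or by complete deletion of
the column (tree-wide reconstruction), matching common cleandata behavior.

**Branch screen.**  Ancestral codon sequences are reconstructed by Fitch
parsimony over the sense-codon state set: bottom-up intersection/union per
column, then a top-down pass in which the root takes its set's
lexicographically smallest state and each child keeps its parent's state
when possible, else its own set's smallest.  Lexicographic tie-breaking is
a determinism device, not a biological claim — note it can place the less
frequent state at the root (e.g. with tips TTT, TTT, TTC the root set is
{TTC, TTT} and the rule picks TTC); the parsimony length is unaffected.
Every (parent, child) branch then gets its own NG86 estimate, and named
clades (a user declaration: clade name → node labels, resolved to the
induced subtree's branches) are aggregated by **pooling raw S, N, Sd, Nd
before distance correction** — ω values are never averaged.

This counting screen deliberately replaces an ML free-ratio codon-model
fit.  The scientific readout it supports is qualitative — a relaxed
post-duplication stem standing above a purifying background — and a
self-contained counting method reproduces that contrast at desk scale
while being exactly testable against enumeration oracles.  Numerical
equality with ML branch-model estimates is not claimed; in particular,
counting on parsimony ancestors compresses elevated-ω branches toward the
background (the simulated ω = 0.48 stem is typically recovered around
0.4), and NG86 itself is biased when transition/transversion bias is
strong.

## The simulator

**Codon model.**  GY94-style rates over sense codons:
`q_ij = π_j · κ^[transition] · ω^[nonsynonymous]` for single-nucleotide
neighbors, zero otherwise, diagonal completing rows to zero, globally
rescaled to one expected substitution per codon per unit branch length at
stationarity.  The parameterization is time-reversible, so transition
matrices are computed exactly by eigendecomposition of the π-symmetrized
matrix — no step-size tuning, exact at this state-space size (61/63).
Per-branch ω overrides select a different rate matrix per branch.  Default
frequencies are either uniform or F1×4 built from a GC target (G=C=gc/2,
A=T=(1−gc)/2 at all positions, restricted to sense codons) — the minimal
mechanism that realizes both an AT-rich background and GC-shifted alien
controls.

All randomness flows from one seeded numpy Generator in a fixed traversal
order; identical configurations give byte-identical output.

**Biased-genome sampler.**  Genes are iid: amino acids uniform over the
code's families, codons within a family weighted by the third-position
nucleotide tilt toward the GC3 target.  This emulates the compositional
(mutation-pressure) signature of an AT-rich genome — it does **not**
emulate translational selection, gene-length/expression structure, amino
acid composition bias, or anything position-specific.  Consequences worth
knowing:

* mean GC3s tracks the target closely (the Ile family, with third
  positions T/C/A, pulls it down slightly);
* genes **straddle Wright's expected ENc curve with a small positive
  offset** (~+1–2 ENc units at GC3 0.25) rather than falling below it.
  The curve `2 + s + 29/(s² + (1−s)²)` lumps all 29 multi-fold families
  into a two-fold-like homozygosity term, while the exact class-structured
  expectation under third-position tilt gives four-fold families much
  lower F (e.g. 0.3125 vs 0.625 at s = 0.25), i.e. a higher true ENc.
  Real selection-shaped genomes fall clearly *below* the curve; passing
  tests on this generator therefore demonstrate the statistics and the
  screens, not that the generator reproduces selection-shaped codon usage.

**Duplication scenario.**  Two ladder clades of 10 tips (terminal and
internal branches 0.05 substitutions/codon), joined at a root, with the
branch leading to one clade (the "stem", length 0.3) carrying ω = 0.48
over a 0.06 background, κ = 2, 300 codons, AT-rich F1×4 frequencies
(GC 0.25) — the relaxed-then-purifying scenario at the family sizes and ω
values such a study reports.  The bundle carries the true per-branch ω map
so recovery can be scored.

**Calibration simulations** (two-taxon ω recovery) use κ = 1 and uniform
codon frequencies: the neutral calibration of a counting estimator is
informative when the generating model matches the estimator's symmetry
assumptions; with κ > 1 the check would measure NG86's known
transition-bias artifact rather than the implementation.

## Curation

**Motif scanning.**  PROSITE-style patterns (literals, classes `[..]`,
negated classes `{..}`, wildcard `x`, repeat ranges, stray whitespace
tolerated) compile to anchored regular expressions with lazy quantifiers:
matches are enumerated leftmost-start, and at each start the first
(shortest-expansion, lexicographic in element repeat counts) match is
reported — deterministic, and equal by construction to explicit
shortest-first enumeration, which the tests verify against an independent
oracle.  Full PROSITE grammar (anchors, class repetitions beyond ranges)
is out of scope.

**Alignment.**  Needleman–Wunsch with affine gaps via Biopython's
PairwiseAligner; defaults BLOSUM62, gap open 10, gap extend 0.5 (EMBOSS
conventions, with a gap of length L costing `open + L·extend`).  Percent
identity is identical aligned pairs over alignment length; percent
similarity counts pairs with a positive substitution score — the only
widely reproducible definition of "similarity".  The reported alignment is
the aligner's first optimum, which is deterministic; the score is
tie-invariant.  End gaps are penalized (true global optimum).  Published
identity/similarity figures for the Des22 paralogs came from an unstated
tool and parameters, so the scoring is exposed rather than guessed at; the
reference protein sequences themselves (UniProt I7M1E1, Q236U7) are not
bundled with this repository, so the accession-anchored comparison in the
test suite reports as unavailable, and the acceptance script aligns a
clearly labeled synthetic divergent pair instead.

**Clustering.**  CD-HIT-style greedy incremental clustering without the
k-mer prefilter: sort by length descending (ties by id), seed clusters in
order, join the first seed matched at identity ≥ threshold, where identity
is identical aligned pairs over the shorter sequence's length.  Default
threshold 0.99 (redundancy removal, not family clustering).

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` size their simulations for a
desk-scale run: ω recovery uses 2,000-codon two-taxon alignments
(50 replicates per ω in the tests, 20 in the script), the duplication
screen 20 replicates of the 300-codon/20-tip scenario, the HGT
calibration 20 replicates of 100 background + 10 family genes at 300
codons, and the oracle-equivalence checks 1,000 random 50-codon pairs.
Every stochastic quantity is driven by explicit integer seeds (the
acceptance script derives all sub-seeds from `--seed`), and screen reports
are byte-identical across reruns of the same configuration.

## Known limitations

* NG86 counting, not ML: ω estimates are compressed at elevated branches
  and biased under strong transition/transversion or codon-frequency bias.
* Fitch reconstruction ignores branch lengths and can misassign states on
  long branches; clade pooling mitigates per-branch noise.
* The simulator has no indels, no among-site rate variation, no empirical
  codon preferences; the genome sampler has no translational selection.
* The HGT screen tests compositional difference only; compositional
  amelioration of ancient transfers or same-composition donors are
  invisible to it (a limitation of parametric HGT detection generally).
* Jukes–Cantor correction saturates at p ≥ 3/4; deeply diverged pairs
  raise an explicit error rather than returning a number.
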