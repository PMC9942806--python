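# Methods

This note records the models, estimators and numerical conventions used
in `macsome`, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## Telomere model and run detection

The MAC telomere is treated as a tandem repeat of a single unit
(default `CCCTAACA`, 8 bp; the *Tetrahymena* comparison unit `CCCCAA`
works identically). A sequencing read can enter a tract at any phase of
the repeat and on either strand, so "a telomeric repeat" on a read is
any cyclic rotation of the unit, or of its reverse complement. A
**telomeric run** is a maximal substring of the read that is a substring
of the infinite repetition of the unit (one strand at a time); the run
qualifies when it contains at least `min_repeats` (default 3) complete
units. The reported span includes flanking partial units — this matters
for trimming, where the full matched span is removed — while the
complete-unit count decides whether the run qualifies.

"Permutation of the unit" is implemented as cyclic rotation: arbitrary
letter permutations would match large amounts of non-telomeric
sequence, while rotation is exactly the ambiguity introduced by an
unknown entry phase. Matching is exact by default; a per-run mismatch
budget (`max_mismatches`) exists as a configuration option but is off
everywhere results are reported, because HiFi-class reads make exact
matching appropriate and a budget makes "maximal run" ambiguous.

Detection is seed-and-extend: any qualifying run (≥ 3 complete units,
span ≥ 2·8−1) necessarily contains the unit itself as a substring, so
exact occurrences of the unit seed phase-consistent extension in both
directions. Where maximal candidates of different phase or orientation
overlap, the leftmost (then longest, then C-rich) wins and later
candidates are truncated at its end; the test suite checks equivalence
against a brute-force oracle that tests substrings directly against the
infinite-repeat criterion on random and adversarially constructed
sequences.

A run is **terminal** when it lies within `end_tol` (default 50 bp) of a
read end — tolerating residual adapter or junk bases — and a read is
telomere-bearing when it has any qualifying run. Classification is
`both_ends` / `five_prime` / `three_prime` / `internal_only` / `none`.

## ATAS calling

Molecule ends appear on the assembly as positions where a read's
terminal telomeric run abuts its aligned interval. For a primary
alignment whose query start (end) lies within `junction_tol` (default
20 bp) of a 5′ (3′) terminal run, one junction is emitted at the
strand-appropriate reference boundary; `side = left` means the telomere
extends toward decreasing reference coordinates (the molecule starts at
the junction). Junctions are aggregated exactly by `(contig, pos,
side)` with no positional clustering (merge window 0): HiFi-scale
accuracy makes exact coordinates meaningful, and any clustering rule
would be an extra assumption. Coverage at a site counts all qualifying
primary alignments spanning the position; secondary and supplementary
alignments are excluded outright, since a telomere junction must be
anchored uniquely.

Sites that are majority-telomeric (`telo_frac >= 0.5`) *and* within
`end_margin` (default 100 bp) of a contig end are labelled contig
termini and excluded from ATAS summaries; the 0.5 threshold is this
package's default, chosen to separate "the" molecule end from
minority-usage alternatives, and is configurable.

## Inter-telomere spacing estimators

Let *p* be the fraction of telomere-bearing reads and *L̄* the mean
telomere-trimmed read length. Each DNA molecule of length *M* carries
two telomeres, and a read intercepts a given telomere with probability
≈ *L̄*/*M*, so

* linear: *M̂* = 2·*L̄*/*p*;
* Poisson: *M̂* = 2·*L̄*/(−ln(1−*p*)), which corrects for reads that
  would span more than one telomere when molecules are not much longer
  than reads.

Both are reported; the linear form is the headline estimator. The
confidence interval is a percentile bootstrap (default 200 resamples)
over reads, seeded. Degenerate inputs (*p* = 0, or *p* = 1 for the
Poisson form) raise errors rather than returning infinities.

Under the read-placement model used by the simulator (below) the linear
estimator is exactly unbiased: the identity Σ(trimmed read lengths) =
Σ(molecule core lengths) over a fragment tiling makes 2·*L̄*/*p* equal
the mean realised molecule length up to sampling noise. At 10,000 reads
and *M* = 130 kbp the sampling SE is ≈ 2.8%, which sets the scale of
the recovery tolerances in the tests.

## Architecture classification and genome summaries

Genome architectures are classified from the median molecule length and
mean genes per molecule: nanochromosomal when the median is ≤ 10 kbp or
genes per molecule ≤ 2 (single-gene molecules of a few kbp),
chromosomal when the median is ≥ 500 kbp (hundreds of genes per
molecule), minichromosomal in between. The category boundaries are
acknowledged to be rough and are configurable.

Heterozygosity is plain *n*/*L*: heterozygous SNP count over callable
length, reported to 3 significant figures. The callable denominator
defaults to assembly length and accepts an explicit callable-site count
(the worked examples use ≈ 41.46 Mbp, the value consistent with both
published rate/count pairs). Intron lengths come from gaps between
consecutive exons of each transcript in a GFF3 file, using 1-based
inclusive arithmetic (`next_start − prev_end − 1`).

## NG86 dN/dS

Nei–Gojobori (1986) counting with equal pathway weighting:

* **Sites.** At each codon position the synonymous fraction is
  (synonymous one-step neighbours)/(valid one-step neighbours), where
  mutations into stop codons are excluded from the valid set
  (mutational-opportunity convention). Each position contributes one
  site, so N + S = 3 × n_codons identically; site totals are averaged
  over the two sequences.
* **Differences.** Codons differing at d positions are scored by
  averaging synonymous/nonsynonymous step counts over all d! minimal
  pathways that avoid stop codons. If every pathway is blocked (a rare
  corner the convention leaves undefined), all pathways are used and
  the codon is flagged in the result.
* **Distances.** Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is
  reported as a per-component saturation flag with a NaN distance.
  ω = dN/dS, with 0/0 reported as NaN (undefined) and dN/0 as +inf.

Gapped columns are dropped pairwise in whole-codon units (complete
deletion); partial-codon gaps are an input error. The *Blepharisma*
nuclear code (UGA → Trp) is built from the standard code by reassigning
TGA; a terminal TGA under this code is a tryptophan codon and is *not*
stripped, whereas shared terminal stops are. This counting estimator
stands in for likelihood codon models deliberately: it is transparent,
exactly testable against pathway enumeration, and sufficient for the
screening question (ω ≪ 1 vs ω ≈ 1); no numeric agreement with ML
implementations is claimed.

## Expression ranking

The developmental screen is a ranking, not a test: fc = (x_target +
ε)/(mean of baselines + ε), sorted descending with ties broken
lexicographically by gene id. ε defaults to 0.5. The ranking is applied
to the count matrix by default: on TPM values at the simulated scale a
fixed ε of 0.5 is negligible relative to per-gene TPM shares, so
zero-baseline noise genes can outrank genuinely induced genes, while on
counts (with comparable library sizes, as in the generator) ε = 0.5
meaningfully damps zero-baseline ratios and planted-gene recovery is
essentially perfect. TPM normalisation is provided for inputs whose
library sizes or gene-length effects require it; the unit used is
recorded in output headers. No dispersion modelling or significance
testing is done — the method is the ranking itself.

## Synthetic data: what is emulated, what is not

The generator family produces every input the pipeline consumes, with
truth tables.

**Genome.** AT-rich (66% by default) random contigs (default 5 ×
300 kbp) with planted one-sided junctions: a junction `(pos, side,
usage)` terminates molecules on its stated side only, with the stated
usage probability; this mirrors the `(contig, pos, side)` identity of
an ATAS call. Junction counts are Poisson per contig at a configurable
density (or pinned exactly), positions are kept ≥ 1 kbp from contig
ends and ≥ 100 bp apart.

**Reads.** Per read: a genomic anchor picks a contig (length-weighted)
and a position; the molecule containing the anchor is realised by
walking outward until a junction fires or a contig end is reached;
telomere tracts (3 complete units minimum plus a geometric excess,
random phase) are appended. The molecule is then tiled into fragments
of the drawn read length (truncated lognormal, mean 8 kbp on
[1, 12] kbp — a modelling choice for a HiFi-like library, not a
published value) at a random offset, and one fragment becomes the read;
molecules shorter than the drawn length are returned whole. This
fragmentation model is what makes the telomere-bearing fraction
converge to 2·*L̄*/*M*, the linear estimator unbiased, and the
"read longer than every molecule ⇒ two telomeres" limit exact. Tract
phases are constrained so the repeat pattern never continues into the
adjacent genomic base, so scanned runs stop exactly at tract boundaries
and truth flags match the scanner bit-for-bit on error-free reads.
Errors are substitutions only at a constant rate (HiFi-like; no
indels). Truth-derived PAF alignments are emitted so downstream stages
are testable without an aligner. A layout-only mode skips sequence
construction for estimator-scale studies.

Not emulated: structural variation and indels, quality-score
distributions beyond a constant, chimeric molecules, coverage biases,
and real chromosome-breakage sequence signals. Passing recovery tests
on these simulations therefore demonstrates correctness of the
*counting and estimation logic* under the stated generative model, not
robustness to alignment artefacts or biased real libraries.

**Codon pairs.** Two lineages evolve from a random stop-free ancestor
under a continuous-time Markov codon process: single-nucleotide moves,
synonymous rate 1, nonsynonymous rate ω, moves into stops forbidden;
time is scaled so the planted t is the expected substitutions per codon
separating the pair. Because the mutation process is symmetric across
nucleotides, NG86 is approximately unbiased here; neutral recovery at
t = 0.3, 2,000 codons is within [0.9, 1.1] on average.

**Expression.** Negative-binomial counts (dispersion α, default 0.1;
variance μ + αμ²) with lognormal base means, lognormal library-size
factors, and planted genes scaled in the target sample only. Planted
fold changes default to log-uniform on [69, 825], the observed range of
the strongest developmental inductions; recovery tests use a harder
floor of 20.

## Problem sizes used in tests

Desk-scale conditions were chosen so the full suite and the acceptance
script each run in well under a minute of compute: 5 × 300 kbp contigs
with 200 junctions and 20,000 reads for junction recovery (≈ 100×
coverage; expected support at the lowest usage ≈ 2–3 reads, which is
what bounds recall); 10,000 reads for spacing recovery; 2,000 codons ×
50 replicates for ω recovery; 1,000 genes with 20 planted for ranking
recovery. The published dataset-scale numbers (41 Mbp assembly, 46,705
ATASs, 25,711 genes) require the archived sequencing runs and are out
of scope here; the package reproduces the *procedures* and the
printed-count arithmetic.

## Known limitations

* The ATAS caller trusts the alignments it is given; it does not
  realign or split-map reads, and clustering of near-identical
  junctions is off by default.
* CRD detection is a generic cysteine-cluster heuristic (≥ 5 Cys in a
  ≤ 60-residue window within the C-terminal 35%); it flags candidates
  for inspection and is not a zinc-finger classifier.
* Triad calling is alignment-column based and inherits any alignment
  errors; the D′ tolerance is fixed at one column.
* NG86 with Jukes–Cantor correction saturates near p = 3/4 and is
  reported as flagged NaNs rather than extrapolated.
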