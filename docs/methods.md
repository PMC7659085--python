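# Methods

This note documents the models, procedures and design choices behind
`ohnorhythm`, in the order the pipeline applies them.

## Normalization and the expressed-gene rule

Raw gene-level read counts are normalized to counts per million,

    cpm = counts / library size × 10^6,

with the library size taken as the per-sample column total unless the
sample sheet carries an explicit `library_size` override. Replicate cpm
values are averaged per (organ, zeitgeber time), and every gene profile
is rescaled to *relative expression*: each timepoint's mean cpm divided
by the gene's across-timepoint mean, so an expressed gene averages
exactly 1 over the day. A gene counts as expressed in an organ when its
replicate-averaged cpm is **strictly** greater than 1 at two or more of
the eight timepoints. Two readings were open here: the threshold is
taken as strict (`> 1`, a literal reading of "larger than 1"), and the
rule is applied to replicate-averaged cpm, consistent with the
per-timepoint averaging used everywhere else in the chain. An all-zero
profile cannot be rescaled and is flagged degenerate rather than
divided by zero.

Zeitgeber convention: Zt 0 is lights-on; the eight samples sit at
Zt 0.5, 3.5, ..., 21.5 h on a 13 h light / 11 h dark cycle.

## The umbrella rank test for cyclic expression

For one gene in one organ the data are the per-timepoint groups of
replicate cpm values on the circular 24 h axis. The alternative is an
umbrella: a monotone rise from a trough timepoint to a peak timepoint,
then a monotone fall back to the trough. Each arc is scored by summing
Mann-Whitney U counts over **all** ordered group pairs within the arc
(the Jonckheere–Terpstra construction, chosen over adjacent-pairs-only
because it is the standard rank statistic for a monotone alternative),
ties counting ½. The statistic for a (peak, trough) hypothesis is the
sum of the two arc scores; because both arcs include the peak and
trough groups, the peak–trough pair is counted once per arc, and the
reported maximum `S_max` counts it the same way. With the ½-tie
convention `S` lives on an exact half-integer grid.

Every (peak, trough) placement on the sampled grid is tested — with 8
timepoints, 56 hypotheses. The per-hypothesis p-value is the right tail
of the permutation distribution of `S`; the combined p-value is the
Bonferroni bound `min(1, H · min_h p_h)`. Bonferroni was chosen over
sharper combinations because the hypotheses are strongly dependent and
a conservative bound keeps the 0.01 cutoff honest. A gene is called
cyclic when the combined p-value is **below** 0.01 (strict). No
across-gene multiple-testing correction is applied by default, matching
the raw-p cutoff convention for this analysis; a Benjamini–Hochberg
flag (`bh_correct`) is available.

### Null distribution

The permutation null holds group sizes fixed and treats all orderings
of the pooled values as equally likely. With 10 or fewer observations
the null is enumerated exactly over all N! position permutations
(duplicate orderings induced by ties carry the correct weight
automatically); above 10 observations a seeded Monte-Carlo sample
(default 10,000 permutations; the calibration studies use 100,000) is
drawn, and the p-value uses the add-one estimator `(1 + #{S* ≥ S}) /
(n_perm + 1)`. Because `S` is a rank statistic, its null depends only
on the group sizes and the multiset of tie multiplicities, so null
distributions are cached and shared across genes; Monte-Carlo child
seeds are derived from the user seed and a hash of the tie pattern, so
results do not depend on gene processing order. After cpm scaling by
unequal library sizes, almost all genes are tie-free and share a single
cached null, which is what makes the 500-gene calibration runs take
seconds rather than hours.

### Peak descriptors

For genes that pass the test, peak Zt is the timepoint of maximum
relative expression, peak shape is the circular forward distance in
hours from the maximum to the minimum, and amplitude is max − min in
relative units. Ties in the argmax/argmin resolve to the earliest
timepoint; an all-equal profile is degenerate (amplitude 0, peak NaN).

### What the calibration shows

At the study design (8 Zt × 2 replicates, 500 genes, negative-binomial
noise at dispersion 0.1), the seed-1 acceptance run measures a null
rejection rate of 0.4% at α = 0.01 (the Bonferroni bound plus the
discreteness of the permutation distribution make the test
conservative), power 0.98 at planted relative amplitude 1.0 and 0.11
at amplitude 0.3, and exact peak-phase recovery for ~59% of detected
strong-amplitude genes with the modal recovered phase equal to the
planted phase at every planted phase (neighboring-bin confusions
account for the rest at the 3 h sampling resolution).

## Ohnolog and singleton identification

Candidate paralog pairs come from a Biomart-style table (one row per
gene × paralog, with the gene's gar-ortholog and coordinate columns
repeated per row). Five conjunctive predicates reduce them to ohnolog
pairs: no "Clupeocephala" duplication ancestor; exactly one distinct
gar ortholog in the union over both genes' rows; no gene occurring in
more than one candidate pair (the offending gene's pairs are all
removed); both genes anchored to chromosomes; and at least 5 Mbp
between start coordinates when on the same chromosome (separating
whole-genome duplicates from tandem duplicates). The separation is
measured between start positions, coordinates being 1-based inclusive.
"Anchored" means the chromosome name is on a caller-supplied list; by
default, names that are plain numbers or `chr`-prefixed numbers count
as chromosomes and everything else (scaffolds, contigs, MT) does not.

Singletons are genes with: no paralog row carrying a TGD or post-TGD
lineage ancestor label (the label list includes both the misspelled
variants found in public exports — "Cyprinodontlformes",
"Cyprinodontoldel", "Poecllilnae" — and their corrected spellings); no
"Neopterygii" ancestor (a node that can arise from tree-reconstruction
artifacts); no "one of many" / "1 of many" marker in the gene name
(case-insensitive substring); and exactly one gar ortholog of type
`ortholog_one2one`. The ancestor exclusions remove the *gene* when any
of its paralog rows carries a listed label, not just that row. A final
guard drops any surviving gene that the ohnolog chain resolved into a
pair, so the two calls are disjoint even on internally inconsistent
annotation tables (on consistent tables it is a no-op).

### Synteny score

For a fish gene *i* and a candidate gar ortholog, the windows are the
n genes on each side of *i* and the n genes on each side of the
candidate, in coordinate order, truncated at chromosome ends. The
score is the fraction of the focal-side neighbors whose gar ortholog
set intersects the gar-side window. The printed formula
`#orthologs / (window size n) × 2` is read as `#orthologs / (2n)` —
the share of the 2n-gene neighborhood with conserved co-linearity —
because the other operator precedence exceeds 1 and has no
interpretation; truncated windows divide by the actual neighbor count
so the score stays in [0, 1]. Window size defaults to n = 10 genes per
side (no value is standard; 10 keeps the neighborhood within a typical
conserved block) and is configurable. When several candidates tie at
the maximal score, the lexicographically smallest gar id wins and a
warning is logged.

## Divergence classification

Inputs are the cyclic calls and peak times. A pair with no cyclic call
in any organ is reported as NOT_CYCLIC and excluded from both scopes.
A pair whose cyclic calls are confined to one organ is *intra-organ*:
ONE_CYCLIC if only one gene is cyclic there, otherwise
BOTH_CYCLIC_SAME / BOTH_CYCLIC_DIFFERENT by peak equality. A pair
whose calls span two or more organs is *inter-organ*:
ONE_CYCLIC_MULTI if only one gene is ever cyclic, SYNCHRONIZED_MULTI
if both genes are cyclic with equal peaks in at least one shared organ
and in every shared cyclic organ, otherwise DIFFERENT_BY_ORGAN — in
particular, a pair whose two genes are each cyclic in a single but
different organ is inter-organ. Singletons cyclic in two or more
organs are SYNCHRONIZED when one common peak holds everywhere, else
DIFFERENT. "Equal peak" means identical peak Zt at the 3 h sampling
resolution; a circular tolerance in hours (default 0) is exposed
because pattern equality is otherwise undefined. All categories are
symmetric in the gene labels, and intra + inter totals equal the
number of pairs with at least one cyclic call by construction.

## NanoString nCounter normalization

Per sample, the scaling factor is the cohort mean of positive-control
probe means divided by the sample's own positive-control mean; samples
with a factor outside [0.3, 3] are disqualified. Scaled counts are
divided by the sample's housekeeping geometric mean and re-centered on
the cohort geometric mean of those values, so a cohort-average sample
passes through unchanged. Background — the mean of the negative-control
probes — is subtracted last and floored at zero. The ratio orientation
and the cohort re-centering follow standard nCounter practice; cohort
references are fit once (`NCounterNormalizer.fit`) and then applied per
sample, which makes the chain idempotent on an average sample and
invariant to rescaling any single sample's counts.

## The synthetic-data generators

`simulate_counts` emulates the study design: 9 organs × 8 timepoints ×
2 replicates. Per organ, exactly `round(cyclic_fraction × n_genes)`
genes are planted cyclic (planting, not sampling, so recovery tests
have exact targets); a cyclic gene's mean is
`b · (1 + A · cos(2π(t − φ)/24))` with baseline `b` log-uniform on
20–500 counts, amplitude `A` uniform on 0.3–1.0, and phase `φ` drawn
uniformly **on the sampled Zt grid** so planted peaks are recoverable
exactly at the sampling resolution. Counts are negative-binomial with
a single shared dispersion (default 0.1, variance = μ + 0.1 μ²), the
simplest overdispersion model adequate for type-I and power studies.
Library-size variation is produced by drawing each column from an
oversampled matrix via multinomial thinning to a target size uniform
on 150,000–250,000 reads; column totals land exactly on the targets,
relative means are preserved, and cpm normalization has real work to
do. Truth labels are written as sidecar tables and never embedded in
gene identifiers.

What the generator does *not* emulate: gene–gene correlation,
organ-specific dispersion, asymmetric waveforms, phases off the
sampling grid, batch effects, or mapping/quantification artifacts.
Passing recovery tests therefore demonstrate correctness of the
statistics under the stated model, not performance on real libraries.

`simulate_homology` plants ohnolog pairs (one shared gar ortholog,
TGD-era ancestor label "Osteoglossocephalai", well separated),
singletons (half with an ancient "Vertebrata" paralog row to exercise
the no-TGD-rows inclusion path), and one unit per decoy class, each
built to violate exactly the filter it is named for: a Clupeocephala
pair, a pair with two gar orthologs, a triplet sharing one gar gene so
one gene occurs in two pairs, a pair with one gene on an unanchored
scaffold, a tandem pair 3 Mbp apart, a "Neopterygii" pair (each gene
with its own 1:1 gar ortholog, so the pair also cannot sneak through
the ohnolog chain), a "(1 of many)"-named gene, and a one2many-typed
gene. Genes sit on a 24-chromosome karyotype at 250 kb spacing, which
makes the 5 Mbp radius 20 gene slots.

`simulate_probe_counts` reuses the planted cosine curves to produce
Poisson probe counts with per-sample hybridization-efficiency and
RNA-input factors plus constant positives and low negatives, so the
nCounter chain's ability to recover planted rhythms is testable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the calibration studies at
500 genes × 1 organ with 100,000 Monte-Carlo permutations, the
super-uniformity check at 500 genes × 1 replicate (8 observations, so
the exact 40,320-permutation null applies), and homology recovery at
50 pairs / 100 singletons / 2 decoy units per class — sizes chosen so
the whole suite completes in a few seconds on one core while keeping
binomial error on the measured rates below about 1.5 percentage
points. Exact enumeration is capped at 10 observations (10! ≈ 3.6 M
permutations, streamed in chunks); requesting `method="exact"` above
that raises a configuration error. Monte-Carlo requires at least 100
permutations. All randomness flows from `numpy.random.default_rng`
seeds; identical seeds give bit-identical outputs everywhere,
including across gene processing orders.

## Known limitations

* The Bonferroni combination over 56 dependent phase hypotheses is
  conservative; at 2 replicates the test has little power below
  relative amplitude ~0.3.
* With Monte-Carlo permutation the smallest attainable combined
  p-value is `H/(n_perm+1)`; `n_perm` must exceed ~5,600 for any gene
  to clear the 0.01 cutoff at 8 timepoints.
* The 5 Mbp tandem-exclusion radius and the synteny window size are
  heuristics inherited from the analysis being reimplemented, not
  estimated from data.
* The divergence classifier treats peak time as the whole expression
  pattern; waveform differences at equal peak time are invisible to it.
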