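# Methods

## The problem

Resequencing of the human mitochondrial genome (a 16,569-bp circular,
double-stranded molecule) after long-range-PCR enrichment can show a severe
strand-specific coverage bias: read depth on the plus (light, L) strand —
the C-rich strand the canonical reference is written on — collapses in
regions whose local base composition is rich in A+C, while the minus
(heavy, H) strand is unaffected. Because heteroplasmic variants are called
from allele fractions at each position, a strand whose representation drops
one to two orders of magnitude makes low-level heteroplasmy calling
unreliable exactly where it matters. This package implements the complete
desk-side analysis of that phenomenon: strand-resolved relative coverage,
coverage-fraction threshold tables, base-class composition bias curves,
sequencing-error baseline calibration with a detection-threshold policy,
and variant-concordance plus heteroplasmy summaries — all drivable from a
synthetic-data generator so the entire pipeline is testable offline.

## Relative coverage and the fraction table (`strand_coverage`)

For a depth series d (plus, minus, or pooled), the relative coverage is
rc_i = d_i / mean(d). Each series is normalized by its own mean, so
mean(rc) = 1 by construction (asserted to 1e-9) and rc is invariant under
scaling all depths by a constant. A strand with zero depth everywhere has
no meaningful mean; its series is reported as undefined (NaN) rather than
divided by zero.

The coverage-fraction table reports, for descending thresholds
(0.50, 0.25, 0.10, 0.05, 0.01 by default), the percentage of positions
with rc strictly below each threshold, per series. Strict inequality makes
the columns non-increasing as the threshold decreases. Display rounding is
two decimals; full precision is retained internally.

Depth can be ingested two ways: from coordinate-sorted SAM/BAM via pysam
(mapped primary records only; a read contributes one to its orientation's
strand at every aligned base — base-level counting, so deleted reference
positions inside a read add neither depth nor base counts), or from the
package's plain-text pileup TSV (one row per position × strand with A/C/G/T
counts).

Down-sampling to a comparison depth (default 3000) is per-base binomial
thinning with retention probability target/current: the natural operation
on a pileup, preserving strand and base proportions in expectation. Its
effect on rc is pure noise: rc profiles before and after thinning correlate
>0.95 whenever the profile has genuine structure at depth ≥ 1000.

## Composition bins and bias curves (`motif_bias`)

"AC-rich" is interpreted as two-letter base-CLASS content — the percentage
of positions in a window holding an A or a C — not adjacent-dinucleotide
(ApC) frequency. Only the base-class reading permits contents of 80%+ and
respects the complement identities AC+GT = CT+AG = GC+AT = 100 that link
the two strands (the plus strand's AC content is the minus strand's GT
content). Contents are computed once on the reference strand; minus-strand
contents follow from the identities.

The genome is divided into consecutive 150-nt bins starting at position 1.
16569 = 110×150 + 69, so on the circular genome the final 69-nt remainder
borrows its missing 81 bases from the genome start, keeping all 111 bins
exactly 150 nt wide — the band statistics assume equal-width bins. A
truncated-final-bin mode (`wrap=False`) exists for linear genomes.

A bias curve takes each bin's mean rc (of a chosen series), groups bins
into content bands [0,10), [10,20), …, [90,100] (top band closed), and
reports each band's mean-of-bin-means with its bin count. Empty bands are
reported with n = 0 and an undefined mean rather than dropped, so the band
axis is stable across datasets.

## The generative model (`synthetic_data`)

The simulator is the study's conditions expressed as a generative model,
not a general-purpose read simulator.

* **Reference**: segments of prescribed base-class content. Exactly
  round(target × length) positions of each segment get a base from the
  class (uniformly one of its two letters), the rest from the
  complementary class, in random order — realized content is within half a
  point of target at any segment length, so composition is a controlled
  variable, not a noisy one.
* **Depth**: per-position, per-strand Poisson. The minus strand at rate
  mean_depth/2 everywhere; the plus strand at rate mean_depth/2 × w(c),
  where c is the local class content on a centered circular window
  (default 150 nt, matching the bin width) and w is a monotone
  non-increasing weight with w(0) = 1. The default weight is a step: 1
  below 80% content, 0.02 at or above — plus-strand coverage "drops almost
  to zero" in rich regions while the minus strand is untouched. The
  mechanism behind the real bias (amplification enzymology) is not
  modeled; w is a user-suppliable phenomenological dial.
* **Variants**: substitutions at given allele fractions, drawn
  Binomial(depth, fraction) per strand *before* errors, so truth fractions
  are well defined. Realized fractions land within binomial sampling error
  of their targets at any depth.
* **Errors**: each sequenced base is substituted, strand-symmetrically and
  uniformly to one of the three other bases, with probability error_rate.
  Indels, homopolymer/flow-space artifacts, quality scores, PCR duplicates
  and paired-end geometry are deliberately out of scope: the error index
  downstream counts non-reference bases without typing them.

The default demo genome is 16,569 nt with a 62% AC background (the real
molecule's overall A+C content) and two 900-nt blocks at 92% AC (~11% of
the genome, matching the reported scale of the affected fraction). Blocks
are multiples of the 150-nt bin, aligned to bin boundaries, and long
relative to the bias window: the centered window straddles block edges, so
the first/last ~20-75 positions of a block sit below the step threshold
and keep full plus coverage; 900-nt blocks make bin means inside the rich
bands dominated by the suppressed interior. Blocks richer than the 80%
step threshold (92% vs 80%) keep the window content criterion satisfied
throughout the interior despite sampling noise.

Demo heteroplasmies span 2-53% minor-allele fraction, including two below
the 5% working threshold, mirroring the range at which heteroplasmy is
clinically reported.

A read-level simulator (fixed-length reads placed uniformly without
crossing the origin, plus-strand candidates thinned by the bias weight at
the read midpoint) exists to build SAM fixtures for the alignment-ingest
path; the pileup-level model is the tested default. Everything is driven
by one integer seed through `numpy.random.default_rng`; identical seeds
give byte-identical outputs.

What passing on synthetic data does **not** show: robustness to alignment
artifacts (mapping quality, soft-clipping, reference bias), to indel and
homopolymer error modes, to non-uniform fragment-length effects, or to the
real (unknown, enzyme-dependent) functional form of the bias. The tests
demonstrate that the measurement machinery detects a bias of the stated
shape when present and invents none when absent.

## Error baseline and detection threshold (`error_calibration`)

At each covered, non-excluded position of a control (or self) sequence the
non-reference fraction is (bases ≠ reference, strands pooled) / (total
bases); true-variant positions are excluded so genuine heteroplasmy does
not inflate the baseline. The average error rate is the *unweighted* mean
of per-position fractions (each position one observation, regardless of
depth). Multiple control runs are aggregated as a mean of per-sample means
with an (n−1) standard deviation. Strands are pooled for the index; a
per-strand breakdown would be diagnostic only.

The threshold policy is explicit and configurable: the detection threshold
is the smallest whole percent lying strictly above multiplier × mean error
(default multiplier 5), never below a floor (default 1%). "Strictly above"
keeps a margin even when the scaled baseline lands exactly on a percent
boundary; at the ~0.2-0.35% error rates of a well-behaved short-read run
this yields the 2% working point, and a 5% threshold remains available as
a conservative override. A candidate allele fraction is callable iff
strictly greater than the threshold. The policy is monotone in the error
rate; with zero measured error it returns the floor.

## Concordance and heteroplasmy (`variant_concordance`)

Variants are parsed from m.-notation (substitution `m.7989T>C`, insertion
between flanking positions `m.5899_5900insC`, deletion `m.3106del` /
`m.8470_13446del`) into records whose identity is (kind, position/interval,
alleles); allele fraction and sample/dataset labels ride along without
affecting identity. Matching against a truth panel is exact by default. An
optional equivalence-region list handles homopolymeric stretches where
insertion placement is not unique (the classic 302-316 region): within a
declared interval, unmatched insertions are compared by net inserted
length. The default remains exact matching, which counts such a case as a
false negative — the conservative reading.

Concordance rows satisfy detected + false-negative = truth by
construction. The pooled detection rate is 100 × Σdetected / Σtruth,
rounded half-up to one decimal. Heteroplasmy summaries are the mean and
*sample* (n−1) standard deviation of per-method minor-allele percentages,
rounded half-up to one decimal for display (full precision available);
the n−1 convention is what reproduces published summary cells of this
kind. Fractions above 50% are reported as given, not folded.

The package ships two small text panels of published counts and
per-method fractions (six samples, three library preparations per
platform) so the concordance stage runs with no download; the `concord`
subcommand uses them by default.

## Numerical and interface choices

* Coordinates are 1-based at every public interface (mtDNA community
  convention); arrays are 0-based internally.
* Rounding for display is decimal half-up (not banker's), one decimal for
  rates/fractions, two for coverage-fraction cells; all statistics keep
  full precision internally.
* Output TSVs carry `#`-prefixed metadata headers (tool version, seed,
  key parameters — never file paths or timestamps), so repeat runs with
  the same seed are byte-identical wherever they are written.
* The circular plot is a simplified two-ring polar rendering (plus ring
  outer, minus ring inner, optional annotation rim), linear by default
  with a log option; nothing numeric is ever asserted on pixels.
* Degenerate inputs: all-zero strands are undefined series, not division
  errors; empty bands report n = 0; down-sampling above the current mean
  warns and passes the input through; fewer than two heteroplasmy values
  have no defined sd.

## Problem sizes

The shipped analyses run at the study's own scales — 16.6-kb genome at
mean depth 3000-6000, a 2.7-kb control at depth ~30,000, 20-seed
replication for calibration — which complete in seconds; nothing is scaled
down from the conditions the analysis models.

## Known limitations

* The bias weight's functional form is phenomenological; no mechanistic
  model of amplification enzymology is attempted.
* Substitution-only error model; platforms with dominant indel error modes
  need a different baseline index.
* The simulator draws per-position depths independently (no fragment-level
  autocorrelation), so coverage noise is slightly whiter than real data.
* Insertion equivalence handles net length only; it does not attempt full
  indel normalization/left-alignment.
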