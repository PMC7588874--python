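# Methods

## The measurement model

One rDNA repeat unit (~43 kb in mouse) is modeled as a linear coordinate
system carrying restriction sites, a Southern probe interval, and a set of
known per-copy variants on the sequenced 28S amplicon coordinate. A cell
holds an integer number of repeat copies; each copy independently carries
(or not) the polymorphic internal BamHI-2 site, CpG methylation of the
SacII site, and a transcriptionally active state. All assays in the
package are deterministic or probabilistic functions of these quantities,
which is what makes a round trip — simulate, then estimate — a meaningful
test of every estimator.

### ddPCR

Template copies are partitioned uniformly at random into droplets; a
droplet is positive if it holds at least one copy. For n droplets and
total copies T, occupancy is Binomial(T, 1/n) per droplet, Poisson in the
limit, so the positive fraction p estimates 1 − e^(−λ) with λ = T/n and
the inversion is λ = −ln(1 − p). The 95% CI propagates the binomial SE of
p through the transform (SE_λ = SE_p/(1 − p)). A saturated assay (p = 1)
is an error, not an estimate. Per-cell conversion uses the duplex
single-copy reference at a configurable 2 copies per diploid cell;
input-mass-based conversion is not implemented.

### Single-cell qPCR

The standard curve Cq = intercept + slope·log₁₀(copies) is an ordinary
least-squares fit (scipy); the implied efficiency is E = 10^(−1/slope) and
must land in (1, 2.2]. Inversion is exact by construction; a reaction with
no template yields a sentinel, which the estimator reports as 0 copies
with a flag rather than as a numeric Cq. Per-mouse summaries use the
sample SD (n − 1); a single-cell mouse reports SD and CV as missing, never
as zero.

### WGS read fraction

Reads land in the array with probability p = c·u/(G + c·u) for c copies of
unit length u and non-rDNA genome length G. The default estimator inverts
this exactly (c = f·G/((1 − f)·u)); a "simple" mode (c = f·G_total/u) is
kept for comparison with analyses that treat the genome length as fixed.
The constants (G = 5.3×10⁹ bp, u = 43 kb) are arguments, not assumptions,
because diploidy handling and the reference genome length materially move
the estimate.

### Mutation-rate tracks and calling

The mutation rate at a position is (non-reference base calls + insertions
+ deletions) / depth, with depth = base calls + deletions (an inserted
base does not cover the position; the insertion event is counted at the
preceding reference position, once per event). Zero-depth positions are
masked (NaN), never zero. Rates above 0.9 are fixed differences between
the amplified array and the reference assembly and are excluded from
thresholding, calling, and window sums.

The artifact threshold is the maximum rate observed anywhere on a
single-copy control gene, across samples — the largest value the PCR +
sequencing error process produced where true variation is impossible. A
site is a candidate when |old mean − young mean| exceeds the threshold; it
*passes* when additionally every sample of the higher group exceeds every
sample of the lower group. The separation requirement is this package's
interpretation of a per-sample screen; it can be disabled
(`require_separation=False`) to reproduce a means-only criterion. Both
signs are called: a young-high site is reported with a negative
difference.

Hot-spot windows tile the locus from position 1 (non-overlapping, width 20
bp by default); only rates in (threshold, 0.9] contribute; the final
partial window is kept and labeled. Window sums from two mice of the same
group add linearly, which is how the per-graph "two mice" totals are
produced.

### In-silico digestion and intensity ratios

A cut is placed immediately before each matching site position on the
linear unit; fragments therefore tile the unit exactly, which is asserted
as an invariant. Methylated SacII sites are removed from the cut set
before digestion. Band intensity is the expected number of
probe-hybridizing copies (one probe, one hybridization event per fragment
— intensity does not scale with fragment length), scaled by one exposure
constant; the loading control SWI5 contributes 2 copies per cell and is
not exposure-scaled, so rDNA/SWI5 ratios carry the exposure constant
explicitly. With independence of the per-copy states, the SacII+/SacII−
undigested-band ratio equals the population methylated fraction in
expectation, and the psoralen ratio equals a/(1 − a) for active fraction
a.

## The synthetic cohort

Per-cell copy numbers are log-normal, moment-matched to the configured
mean and CV (σ² = ln(1 + cv²), μ = ln(mean) − σ²/2) and rounded half-up to
integers. The log-normal was chosen because it is strictly positive,
right-skewed, and fully determined by the two moments the assays report;
single-cell dot plots do not constrain the family further, so the choice
is config-exposed rather than load-bearing. Per-cell state fractions are
Beta-distributed around the group fraction with concentration 150 (SD
≈ 0.04 at f = 0.5) — enough cell-to-cell spread to make per-mouse ratios
non-degenerate without crossing the group effects.

Defaults are one strain per run: young mean 471 copies/cell (the
BALB/cA-like configuration; 1,025 for C57BL/6-like), old/young mean ratio
1.2, CV 0.35 young / 0.20 old, 4 mice per group, 96 cells per mouse,
methylated fraction 0.10/0.25 (young/old), active fraction 0.50/0.35,
BamHI-2 fraction 0.50/0.35, sequencing depth 10,000 with an error floor of
5×10⁻⁴ per base. The young means are measured anchors; the ratios and
fractions are free defaults that encode only the qualitative age
directions and are all overridable in the `[cohort]` TOML table.

Amplicon pileups are generated directly (no read-level FASTQ or
alignment): at each position, variant reads are Binomial(depth, f) and the
remaining reads err with probability e uniformly over the three other
bases, so the expected non-reference rate is f + (1 − f)·e — a read is
non-reference if it carries the variant or an error struck a reference
copy. The planted 28S variant set mirrors the measured group frequencies,
including the three substitutions that convert the internal BamHI site
GGATCC to GGGGTC. The 28S amplicon coordinate is 5,100 bp long — longer
than the mature 28S — so that the BamHI-site positions around 5050 lie on
it. Indel errors are not simulated (the readers and rate definition handle
them; the generator plants substitutions only).

What passing tests therefore do *not* show: robustness to alignment
artifacts, position-dependent or strand-biased error, PCR jackpots and
chimeras, or copy-linked variant phasing. The generators draw independent
errors per position at a flat rate; real amplicon data are messier, and
a threshold learned from real amplicon data (0.0028 is a typical value)
is accordingly larger than the ~0.0014 the flat 5×10⁻⁴ floor produces at
depth 10⁴.

## Randomness and determinism

Every generator accepts a seed or NumPy `Generator`. The pipeline derives
named substreams from one root seed via
`SeedSequence(root, spawn_key=(stage, ...))`, so a stage re-run in
isolation reproduces its draws exactly; the manifest records the root seed
and a SHA-256 per output file, and identical seeds give byte-identical
outputs.

## Rounding conventions

All statistics are carried at full precision and rounded once, at report
time, operating on the shortest decimal representation of the float so
binary dust one ulp from a decimal tie cannot flip a digit. Nonnegative
rates, averages and ratios round half-up (the convention of printed
tables); signed differences round half-to-even, the unbiased tie-break for
quantities whose sign is the finding. Group means are computed from
full-precision per-sample values, not from their rounded forms.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data at
the following scales, chosen so every stochastic assertion sits at ≥3
standard errors from its decision boundary: droplet assays at 10⁴ droplets
(200 replicates per occupancy), amplicon depth 10⁴ over 5,100 + 460
positions with 2 + 2 samples (100 replicate experiments for the recovery
and null rates), cohorts of 4 + 4 mice × 96 cells (up to 2,000 cells for
moment-recovery checks), and 10⁶–10⁷ draws where a single estimate needs
sub-percent precision (duplex ddPCR, WGS round trips). The full suite runs
in well under a minute on one CPU.

## Known limitations

- The digest model carries a single representative SacII site inside the
  probe fragment; real units have several, and partial digestion is not
  modeled (a copy is cut or protected, never intermediate).
- Band intensities are numbers, not densitometry: hybridization
  efficiency, background, and saturation are out of scope.
- The mouse→yeast coordinate annotation is a two-entry lookup for the
  conserved called sites, not an alignment-based lift-over.
- Real-data mode consumes aligned reads and tables; mapping itself, base
  quality, and recalibration are upstream of this package.
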