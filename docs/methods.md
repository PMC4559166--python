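# Methods

This note documents the models implemented in `evotrace`, the choices made
where the underlying procedures were underdetermined, and what the synthetic
data do and do not emulate.

## Coordinate and distance conventions

All coordinates are 0-based half-open internally; files meant for humans
(truth tables, call TSVs) print 1-based positions, and masks are written as
0-based half-open BED. The mate-pair "distance" is the **outer distance**:
leftmost mapped coordinate of one read to the exclusive rightmost coordinate
of its mate, in reference space. For an event-free fragment this equals the
fragment length; a deletion of L bp between the reads adds +L and an
insertion subtracts L. (Inner distance would work identically up to a
constant 2×read-length offset; outer was chosen because it equals TLEN in
SAM convention.)

## Synthetic genomes and planted events

`generate_reference` draws an i.i.d. nucleotide sequence at a configurable
GC fraction (default 0.508, the *E. coli* genome average), lays
non-overlapping ~1 kb gene annotations on an even grid, and attaches an IS
catalog with freshly drawn element sequences. The catalog carries the four
length variants seen at the evolved strains' insertion sites (IS5 1199 bp
and a 1195 bp variant; IS186 1343 and 1342 bp) so fixtures reproduce each
documented length exactly.

`plant_events` applies non-overlapping events sorted by position in one
left-to-right walk, producing the mutated sequence and a piecewise-linear
liftover between reference and sample coordinates. Duplications are tandem;
the second copy lifts onto the same reference interval, which is what makes
the read-depth signal double there. Length conservation
(len(sample) = len(reference) + Σ signed lengths) is asserted on every call.

Built-in fixtures transcribe the evolved strains' endpoint mutation
catalogs (strains B–F; the mutator strain A's ~131-mutation catalog lives
in supplementary material and is out of scope). Native genome positions are
kept as metadata and rescaled linearly onto the synthetic reference; event
**lengths are never rescaled**, since the callers' accuracy is measured
against the printed lengths. The duplication's native position is not
printed anywhere, so a mid-replichore placeholder (1.5 Mb) is used. When a
rescaled SNV's target base coincides with the synthetic reference base, the
next base in ACGT order is substituted so the event remains observable.

## Read and pileup simulation

Mate-pair fragments are drawn Normal(insert_mean, insert_sd) and placed
uniformly on the *sample* genome (no GC or mappability bias); end reads are
mapped back to reference coordinates through the liftover. A read
overlapping inserted novel sequence by ≥ 50 % is absorbed by the insertion:
if the insertion is a named IS element, the pair is kept as
counterpart-read evidence (mapped flank coordinate + element name),
otherwise it is dropped as unmapped. Pair mapq and minimum base quality are
drawn as high-quality constants with configurable low-quality fractions —
enough structure to exercise the mapq < 10 / baseq < 30 gates without
simulating base-level sequences (an explicit non-goal).

Pileups are simulated per platform directly: site depth ~ Poisson(coverage);
at a planted SNV of population frequency f the variant-supporting count is
Binomial(depth, f(1−ε) + (1−f)ε) with per-base error ε; elsewhere counts are
pure error draws. Small indels emit supporting counts Binomial(depth, f) at
their positions. The two platform profiles differ in insert/read geometry
(1200 bp / 2×50 vs 2×250) and seed; both default to study-like coverages,
scaled to 50× in the shipped scenarios (see Problem sizes).

## Variant calling

A site is called iff depth ≥ min_depth (10) AND variant_count/depth ≥
min_ratio (0.6) AND P(X ≥ variant_count | depth, ε) < p_threshold (10⁻⁷).
The depth/ratio gates are inclusive at the printed values; the p-gate is
strict. "Ratio" is variant/total, not variant/wild-type: a variant-to-wild-
type reading of 0.6 would accept 37 % minority alleles, contradicting the
goal of calling mutations fixed in the majority of the population. The
binomial tail is a transparent stand-in for the original platform's
proprietary caller score: same role (error-aware confidence), auditable
formula. The simulator emits a single alternate allele per site, so no
multi-allelic tie-breaking is needed; real-data pileup readers should
pre-reduce to the majority alternate.

Consensus: calls agreeing by (kind, position, alt) are accepted; each
discrepant call is queried against a confirmation oracle (in synthetic runs,
the planted truth — the programmatic stand-in for Sanger confirmation) and
kept iff confirmed; with no oracle the discrepancy is flagged unresolved
rather than silently resolved either way. Low-coverage masking collects
maximal intervals with depth strictly below 10 reads; calls inside masks are
suppressed and reported separately. Parent subtraction removes calls whose
(kind, position, alt) key appears in the parent call set.

## Large-indel scan

Windows of size = library mean distance (step = window/4) tile the
reference; a pair belongs to the window containing its leftmost coordinate;
windows with ≥ 20 distance observations and |median − μ_d| > 3 σ_d are
flagged (two-sided; deletions deviate up, insertions down) and merged when
overlapping or adjacent.

Two refinements matter at desk-scale genome sizes:

* **Background re-estimation.** On a 100–500 kb reference the flagged
  regions' own distance-shifted pairs are a non-negligible share of the
  library and drag the global mean toward the event, biasing
  |median − mean| size estimates low by several percent. Classification
  therefore re-computes μ_d, σ_d on pairs outside flagged regions. (On a
  full-size genome the two estimates coincide.)
* **Spanning-population median.** The size estimate takes the median of
  pairs within 3 σ_d of the most deviant window's median. Event-free pairs
  sit > 3 σ_d away by construction (the window only flags beyond 3 σ_d), so
  this strips their dilution without biasing the spanning median.

IS classification: counterpart hits in the region vote by element name; ≥ 3
supporting pairs set `is_element`, with an ambiguity flag when two elements
both reach support. When an insertion's length approaches the fragment
length (insert_mean < L + 2·read_length + 3·insert_sd) the both-flank pairs
vanish — fragment-length censoring — and the window median may never
deviate. Counterpart-read clusters (≥ 3 same-element hits within 2 kb)
recover such insertions as calls flagged `censored=True`; their size, when
estimable at all from the few short spanning pairs, is biased low and
should be read as a lower bound. This mirrors why the original procedure
leaned on counterpart-read evidence for IS insertions rather than on sizing.

The breakpoint estimate is the median midpoint of the deviant pairs' spans;
it is accurate to roughly half the insert length and is intended for
matching calls to loci, not for base-pair breakpoint resolution (split-read
assembly is a non-goal).

## Duplication detection

Coverage is profiled as read starts per window (default 5 kb) scaled to
fold coverage. Windows at ≥ 1.5× the genome-median depth, in runs of ≥ 10,
are reported with length and mean ratio. The 1.5×/10-window
operationalisation of "significantly higher coverage" is a package choice;
both knobs are exposed. A tandem duplication's copy junction also leaves a
discordant-pair signal in the distance scan; the pipeline treats scan calls
at a detected duplication's boundaries as secondary evidence of the same
event rather than as independent indels.

## Fixation timelines and clones

Frequencies are classified absent (f < 0.2) / polymorphic (0.2 ≤ f < 0.8) /
fixed (f ≥ 0.8). The 0.2/0.8 thresholds emulate typical Sanger chromatogram
minor-peak sensitivity — the original two-peak criterion is not quantified —
and are configurable. The three statuses partition [0,1]; boundaries belong
to the upper class. No monotonicity is assumed or enforced (clonal
interference produces non-monotone trajectories), and missing cells map to
an explicit `missing` status. Clone summaries count genotype signatures
over a locus list; counts always sum to the clone count. Interference
reporting stays descriptive (timeline + co-occurrence counts); no formal
inference statistic is attached.

## Convergence analyses

Quantile normalization maps each column's ranks onto the across-column mean
of sorted values; ties receive the mean of the reference values their ranks
span. The quantification-limit filter keeps genes strictly above 100 a.u.
in **every** sample. Log ratios are log₁₀ (base configurable). PCA is an
SVD of the gene-centered matrix with samples as observations, fit jointly
on all strain × timepoint samples plus the parent, so per-strain orbits
(scores ordered by time, anchored at the parent) are directly comparable —
a per-strain fit would destroy that comparability. Strain-pair convergence
is the Pearson correlation of endpoint log-ratio vectors; zero-variance
vectors yield NaN rather than an error. Metabolite concentrations follow
the internal-standard double-ratio:
conc = [(A_sample/A_IS,sample) / (A_std/A_IS,std)] × C_std, with zero
sample area reading as below detection.

The expression simulator generates per-gene smooth non-monotone
trajectories (random cubic through the origin, normalised to unit peak)
shared across strains, with amplitude ~ Normal(0, 0.4 log₁₀ units),
independent Normal noise (default SD 0.05 log₁₀ units ≈ the 1.7-fold
replicate reproducibility band of the original arrays), and an optional
divergent strain whose contiguous 10 % gene block is up-shifted 2-fold —
the expression footprint of a large duplication. It emulates the *rank
structure* the convergence statistics consume, not microarray physics:
no probe effects, no heteroscedastic intensity noise, no gene–gene
correlation beyond the shared trajectories. Passing tests therefore
demonstrate that the statistics recover convergence and divergence under
the stated noise model, not that they are robust to array artefacts.

## Growth

μ is the least-squares slope of ln OD₆₀₀ vs time. Without an explicit
window the contiguous sub-window (≥ 4 points) maximising R² is used, with
ties broken toward the longest window (so a noiseless exponential uses the
whole series). Dunnett's many-to-one adjustment draws max|T| from the
equicorrelated multivariate-t (ρ_ij = λ_iλ_j, λ_i = √(n_i/(n_i+n₀)))
by seeded Monte-Carlo (default 10⁵ draws; quantile SE ≈ 0.001 near
p = 0.05); the adjusted p is floored at the unadjusted pooled-t p. A table
lookup would cap the group count; an independent implementation
(`scipy.stats.dunnett`) is used in the test suite as a cross-check oracle
only.

## Problem sizes used

Shipped scenarios run on desk-scale genomes: 150–500 kb references (1 Mb
for the duplication scenario) at 25–50× coverage, against the study's
native 4.6 Mb / ~200× scale. All thresholds are identical to the printed
ones; only genome length, coverage and replicate counts are scaled. The
recovery and sizing behaviour of every caller is scale-free in the regimes
tested (sampling errors scale as σ_d/√n and are asserted at that
tolerance). Monte-Carlo suites use 10–20 seeds per condition; the Dunnett
family-wise error check uses 2000 null simulations against a 4×10⁵-draw
reference distribution.

## Known limitations

* No base-level reads, aligner, or quality recalibration; mapping is exact
  via the liftover, so mapping artefacts (repeats, paralogs) are absent.
  The low-coverage mask exists but synthetic coverage rarely triggers it.
* The distance scan reports one event per merged region; two large events
  within ~2 insert lengths would merge.
* Censored IS insertion sizes are lower bounds by construction.
* The binomial caller ignores strand bias and base-quality weighting.
* Growth-window auto-selection can overfit short high-R² stretches on very
  noisy series; pass an explicit window when the exponential phase is known.
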