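# Methods

`picolib` validates the computational side of low-input (picogram to
femtogram) tagmentation-based shotgun metagenomic libraries: it simulates
how such libraries are made from a defined mock community, and implements
the QC statistics and composition-fidelity analyses used to judge them.
This note records the model, its parameters, the numerical choices, and
what the synthetic data can and cannot show.

## The generative model

A library from a mock community is modeled in four stages.

**Mock community.** Each member contributes a DNA mass `m_i` (fg) from a
genome of length `L_i` (bp) and GC fraction `g_i`. Because shotgun reads
sample nucleotides proportionally to mass, the expected read-level
relative abundance is the mass fraction `m_i / Σm`; the genome-copy
(cell) abundance is `(m_i/L_i)` normalized. The packaged default
community has 54 members, genomic GC evenly covering 0.28–0.70 and mass
abundances spanning exactly 0.04%–25%. Abundances follow a warped
geometric ladder `s_i = s_min · (s_max/s_min)^((i/(n−1))^γ)` with the
warp exponent γ solved so the shares sum to one — a pure geometric ladder
cannot pin both endpoints and the total simultaneously. Genome lengths
are drawn uniformly from 1.6–6.0 Mb (a realistic prokaryotic range; the
total of ≈214 Mb also makes coordinate collisions between distinct
templates negligible at the depths used here). Reference sequences are
i.i.d. random genomes matching each member's length and GC; they stand in
for real genomes and carry none of their repeat structure (see
*Limitations*).

**Tagmentation.** The transposase cuts DNA into fragments whose length
distribution depends on the transposase:DNA ratio, i.e. on the ATM
(amplicon tagment mix) dilution. Fragment lengths follow a normal law
truncated below at 20 bp (the steric lower bound from adjacent
transposase footprints). The dilution→(mean, sd) calibration table is
anchored at 1:5 → 190±75 (below the 200 bp seen at strong
over-tagmentation), 1:10 → 240±90, 1:50 → 300±110, with log-linear
interpolation in dilution; the undiluted standard protocol (1 ng input)
uses 307±115. Undiluted ATM on sub-nanogram input is anomalous in
practice (it behaves like a 1:10 dilution, consistent with a diluted
transposase inhibitor); the table reproduces the observation directly
rather than modeling the inhibitor. Total fragment bases equal the input
mass converted at 0.978×10⁹ bp per pg of double-stranded DNA, split
across members by mass abundance; start positions are uniform on a
circular genome (avoiding edge-length bias), with an optional AT-preference
acceptance weight `P(accept) = 1 − w·GC₁₀(site)` to emulate the slight
AT-richness of transposase insertion flanks.

Because insert sizes are conventionally *reported* as two-tail 1%-trimmed
statistics, the truncated-normal location and scale are calibrated by a
two-parameter solve so that the *population trimmed mean and trimmed sd*
equal the table values. Calibrating the raw mean instead leaves a small
but systematic offset (≈−0.4 bp in the measured trimmed mean at the
standard-protocol anchor, and a trimmed-sd deficit of ≈8%), which a
100k-pair round trip can resolve.

**Bottleneck and PCR.** Library creation loses most input DNA; each
fragment survives independently with probability `retention` (default
0.1, i.e. 90% loss). Survivors are the unique amplifiable templates —
the *effective template complexity* T that determines duplicate levels.
Limited-cycle PCR is a Galton–Watson branching process: each copy
duplicates per cycle with probability `efficiency` (default 0.9), so the
copy-number CV² after c ≥ 12 cycles saturates at
`e(1−e)/(µ(µ−1)) ≈ 0.053` (µ = 1+e). This saturation is why the
duplicate fraction is insensitive to the cycle count (12 vs 20 cycles
differ by far less than 2 percentage points at fixed depth) — duplicates
are made by template scarcity, not by extra cycles.

**Sequencing.** Read pairs of 150 bp (2×150 chemistry) are drawn from
templates with probability proportional to copy number: the forward read
is the fragment's first 150 bases, the reverse read the reverse
complement of its last 150 (the whole fragment when shorter, so mates
overlap on short inserts). Substitution errors are i.i.d. per base
(default 0.001 in presets; round-trip analyses use 0); qualities are
constant Q30 phred33. Truth output records member, fragment coordinates
and template id per pair, and a truth SAM carries 1-based positions with
signed TLEN (+length on the leftmost mate).

## Library presets and the occupancy calibration

Presets bundle the five study conditions: `sop` (1 ng, undiluted ATM, 12
cycles, inserts 307±115), `100pg`, `10pg`, `1pg`, `100fg` (1:10 ATM, 20
cycles, insert means 257/240/222/204 spanning the observed 204–257 bp
range). Each preset's `effective_templates` replaces the physically
derived template count, because observed duplicate levels fold in
unknown amplifiable-fraction losses. It is calibrated by inverting the
occupancy model

    E[unique] = T · (1 − (1 − 1/T)^n)

at n = 5×10⁶ pairs against the observed mean duplicate percentages of
the two anchor conditions — 1.2% for the standard protocol and 78.8% for
100 fg — giving T ≈ 2.07×10⁸ and ≈ 1.07×10⁶ respectively; intermediate
presets interpolate log₁₀T linearly in log₁₀(input mass). The inversion
assumes uniform draws; PCR copy-number dispersion multiplies collision
rates by (1+CV²) ≈ 1.05, shifting simulated duplicate percentages by
about +0.06 pp (sop) and +0.13 pp (100fg). The calibration is left on
the plain occupancy inverse — the shift is well inside the round-trip
tolerances, and keeping the inverse analytic keeps it a right inverse of
the forward expectation.

## QC statistics

**Duplicates.** `pair_signature` concatenates the first 30 bp of each
mate (case-folded; N compares literally); exact 60-mer identity defines
duplication, and duplicates = total − unique over a uniform
without-replacement subsample. Pairs with a read under 30 bp are skipped
and counted separately. `rmdup_reference` implements the mapped
definition: identical (reference, start, stop), both coordinates.
`rarefaction` uses nested subsamples (one permutation consumed
prefix-wise): unique and duplicate *counts* are then monotone pathwise;
the duplicate *fraction* is monotone in expectation but can fluctuate on
adversarial inputs, so only the former are asserted pathwise.
`invert_occupancy` returns the real-valued root (rounding would break
the right-inverse property at small T; presets round on storage).

**Insert size.** One TLEN per proper pair (the positive mate), uniform
subsample (default 10⁶), then two-tail trimming: after sorting,
`floor(trim·n)` values are cut from each end (trim = 0.01 by default,
applied identically to mean and sd; sd uses n−1). `trim=0` reproduces
the plain mean/sd exactly.

**Read GC.** Mean of per-read GC fractions, (G+C)/(A+C+G+T) ignoring N,
over the first 10,000 forward reads (a pooled-bases mode is available;
the per-read mean is the default reporting convention).

**Insertion-site composition.** A uniform subsample of 1,000 forward
reads trimmed to their first 10 bases gives a position×ACGT frequency
matrix, per-position information content 2−H bits (no small-sample
correction; ≈0.01–0.02 bits of upward bias remains at n=1000), and the
pooled flank GC.

**Fidelity.** Profiles count one primary forward-mate alignment (or
truth label) per pair; relative abundances are over community members
only, while the breakdown (community / human / contaminant / phiX /
unmapped) partitions all pairs. Fidelity is the Pearson correlation of
untransformed relative abundances (a log option exists but is off by
default), with the two-sided t-test p-value and Bonferroni correction by
the family size; the `exclude_top` variant drops the t most abundant
members *of the baseline profile* (ties by member id) and renormalizes,
keeping one fixed member set for both vectors. Replicate variability is
the mean coefficient of variation (sd/mean, n−1) over members whose mean
count exceeds 20 — the same trimming threshold used for taxon tables.
GC-class bias partitions members into genomic-GC tertiles (ties to the
lower class; 54 members → 18/18/18), sums class abundances per
replicate, and compares libraries by one-way ANOVA with Tukey HSD
follow-up; the exact class cutoffs are a documented choice, as only
"high/median/low" classes are conventionally reported.

## Numerical and implementation choices

- **Large-T amplification.** For presets with T > 2×10⁷ templates the
  per-template branching recursion is replaced by an exact equivalent:
  the copy-number distribution after c cycles is computed by dynamic
  programming (support ≤ 2^c, feasible for the 12-cycle standard
  protocol), templates are partitioned multinomially into copy-number
  classes, and each read draw samples a class (∝ class weight) then an
  index within it. Copy numbers are i.i.d. across templates and
  independent of member assignment and coordinates, so the scheme is
  distributionally identical to materializing all 2×10⁸ templates; the
  two paths are cross-checked in the test suite.
- **Lazy coordinates.** Fragment coordinates are generated only for
  templates actually hit by a read draw — again exactly equivalent,
  since coordinates are i.i.d. and independent of copy numbers.
  Preset-path members are assigned i.i.d. by mass share; the extra
  share noise (≤0.4% relative for the rarest member at T ≥ 10⁶) is far
  below read-sampling noise.
- **Determinism.** Every stochastic entry point takes a seed; internal
  streams are spawned from one `SeedSequence`, and identical seeds give
  byte-identical FASTQ/SAM/TSV output. Iterating a simulated library's
  reads twice yields identical records.
- **Degenerate inputs.** Fragments longer than a genome are clipped to
  it; fragments spanning the origin wrap (circular genomes); reads
  shorter than the signature prefix are skipped and counted; profiles
  with no community counts return zero abundances rather than dividing
  by zero; identical ANOVA groups short-circuit to p = 1.

## Problem sizes

Round-trip analyses use the depths the statistics are defined at:
duplicate percentages at 5×10⁶ pairs (the calibration depth) and insert
sizes from ≥10⁵ pairs. Property checks (estimator equivalence, pooling,
cycle invariance, recovery) run on smaller communities at 10⁴–10⁵ pairs,
which already give sub-percent statistical resolution.

## What the synthetic data does not show

The simulator emulates the *statistical* structure of low-input
libraries: calibrated insert-size laws, input-mass-dependent template
complexity and hence duplicate levels, library-specific template subsets
(independent bottlenecks per replicate), contamination admixture, and
optional insertion-site AT preference. It does not emulate real genome
sequence (repeats, conserved regions, inter-genome homology — so
ambiguous mapping never occurs and truth-label profiles are cleaner than
aligner output), GC-dependent amplification efficiency (GC-class bias
enters tests only as an imposed distortion), quality decay, indels,
optical/flow-cell duplicates, or index hopping. Passing round trips
therefore validate the estimators and the calibration logic, not the
behavior of any aligner, and real libraries will show additional
variance from the mechanisms listed above.
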