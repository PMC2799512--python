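# Methods

This note documents the models, estimators and numerical choices behind
`haplomap`, and what its synthetic data do and do not emulate.

## Meiosis and screen model

Gametes are simulated marker-to-marker: a gamete starts on a uniformly
chosen maternal haplotype and switches haplotype independently in each
inter-marker interval with that interval's recombination fraction
`r_i`. There is no crossover interference. Map distance converts as
`cM = 100·r` by default, valid below 50 cM and numerically exact at the
sub-centimorgan distances of a fine-mapping screen; a Haldane conversion
(`r = (1 − e^(−2d/100))/2`) is available for longer maps. The two-locus
recombination fraction across several intervals is the probability of an
odd crossover count, `(1 − Π(1 − 2r_i))/2`.

Only haploid male offspring are simulated for screens (virgin mothers);
the recessive lethal is 100% penetrant in males, so survival is simply
"does not carry the lethal allele". With one heterozygous lethal the
surviving fraction converges to 1/2. Because the lethal is in coupling
with the donor focal allele, *survivor ∧ donor-carrier ⇒ recombinant*
holds exactly, which the tests assert as an identity. Double crossovers
are allowed (independent intervals) and counted separately; at ≤ 0.6 cM
they are negligible (~r² per gamete).

**Enrichment definition.** The fold-enrichment of a lethal-assisted screen
is defined as `1 / P(recombinant | focal-donor carrier)` — the number of
donor-allele males one would have to genotype per recombinant found
without the lethal, versus 1 with it. At recombination fraction r this
converges to `1/r` (≈ 175 at r = 0.0057). Definitions based on all males
screened rather than donor-allele carriers differ by a factor of ~2; the
choice is fixed here and recorded in every pipeline summary.

**Screens conditioned on survivors.** Screened-male totals are counts of
*living* males, so the simulator can condition on a fixed number of
survivors: batches are generated until the target is reached and truncated
at the conceived index of the target-th survivor, preserving the exact
binomial law of the recombinant count among survivors.

## Backcross introgression

Repeated backcrossing with selection on a donor allele is simulated on
the genetic (Morgan) line: each generation draws a Poisson(length)
crossover process and a uniform phase, intersects the carried donor
segments with the regions inherited from the carried haplotype, and
rejection-samples until the gamete retains the donor allele at the
selected locus. Physical coordinates are recovered by linear interpolation
between markers. The expected retained one-sided flank after t
generations is `(1 − e^(−Lt))/t` Morgans for a flank of length L — the
mean of the minimum of t unit-exponential draws capped at L — and the
simulator is tested against this closed form.

## Interval calling

A recombinant panel has one row per recombinant male: a genotype call
(donor/recipient/untyped) at each ordered marker, and the wing phenotype.
Under a single causal locus, a large phenotype requires the donor allele
at the causal position, a small one the recipient allele. Genotype at a
candidate position is inferred by crossover parsimony: forced to the
shared allele when the nearest typed flanking markers agree, free inside
an attested breakpoint gap, and forced to the outermost typed allele
beyond the ends (no unattested breakpoints are posited). Untyped markers
are skipped, conservatively widening breakpoint gaps. The interval call
is the intersection over recombinants of the allowed inter-marker
segments; an empty intersection raises an error naming the offending
recombinants (phenotyping error or two-locus architecture). Genotype
vectors needing ≥ 2 breakpoints are flagged as double recombinants.
Intervals are 0-based half-open bp on the recipient-species assembly
(the same cloned region spans 13.5 kb in the *N. vitripennis* assembly
and 10.8 kb in *N. giraulti* due to indels; the recipient assembly is
canonical here, see `mapping.WS1_REGION_SPAN_BP`). A flank left
unconstrained by the panel is reported as an open (None) bound. The
implementation is verified against an independent oracle that enumerates
single-crossover haplotypes directly.

Map distances carry Wilson score confidence intervals (reported only,
never used in interval logic; the underlying counts are the inference).

## Wing morphometrics

Relative tables divide each genotype's mean *and SD* by the reference
genotype's mean, so the reference row reads `1.00 ± cv`. Display rounds
to two decimals (integer percent for derived percentages); full precision
is retained internally. The percent of the interspecies difference
attributable to an introgression is `100·(rel_intro − 1)/(rel_species − 1)`.

Genotype contrasts use Tukey HSD on a nested design. The error stratum is
family-within-genotype: each family contributes its mean and the HSD runs
on family means, treating families as the experimental units. This is the
natural reading of "family nested in genotype" for a between-family
comparison; a `residual` option runs on individuals instead, and a
genotype with a single family forces that fallback with a logged warning.
Pairwise p-values are Bonferroni-multiplied by the number of tests in the
analysis (a configuration value — 8 for a four-measurement × two-sex
analysis, 3 for a three-measurement one — never hard-coded) and capped at
1; compact letters are assigned by insert-and-absorb so genotypes sharing
a letter are not significantly different.

**Seta estimators.** Cell size is estimated from the seta pattern as the
mean over setae of `π·(nnd4_i/2)²`, with `nnd4_i` the mean Euclidean
distance to the four nearest neighbours (KD-tree; ties broken by point
index; duplicates logged). No edge correction is applied: the boundary
bias (a few percent, inflating the estimate) is shared by the two
genotypes being compared and cancels in their ratio, which is the
quantity interpreted. The estimator is exactly equivariant under
coordinate scaling (×s coordinates ⇒ ×s² area), which is what makes the
ratio form reliable. Cell number changes are estimated from seta counts;
an alternative estimator, region-area ratio divided by size ratio, is
reported alongside because the two need not agree on real wings (uneven
density, region-outline differences). On noise-free rescaled pairs
`(1+size)(1+number) = (1+area)` holds exactly.

Cells-per-seta ratios (nuclei and setae counted in a 30 µm-radius circle
of the pupal wing) are compared by a two-sided Mann–Whitney U test, exact
for ≤ 20 observations per group without ties, tie-corrected normal
approximation otherwise; all-tied inputs return p = 1 by convention.

## qPCR quantification

Each biological replicate contributes four (genotype × gene) cells run in
triplicate; the per-cell summary is the triplicate *median*, making the
ratio robust to one aberrant well per cell. The expression ratio is
`2^−((ctA_t − ctA_c) − (ctB_t − ctB_c))` with amplification efficiency
fixed at 2 per cycle (no efficiency correction; ratios are approximate in
the same sense as the assay). The ratio is exactly invariant to adding a
constant to every Ct and exactly antisymmetric under genotype swap
(ratio → 1/ratio).

Minus-RT wells are "no amplification" sentinels (missing Ct, never 0). A
replicate is rejected when any −RT well amplifies within 5 cycles of its
+RT cell median: 5 cycles corresponds to ≈ 2⁻⁵ ≈ 3% potential genomic
contribution, a conservative contamination margin chosen here since the
assay convention fixes no threshold.

Replicate sets are summarised by median and IQR using
linear-interpolation quartiles (convention pinned in configuration, since
published IQRs are not re-derivable from summaries). The location test of
ratios against 1 is a sign-flip permutation test on log ratios (exact for
n ≤ 16, seeded Monte Carlo above) — analysis plumbing for synthetic
summaries, chosen for exactness at n = 3–7.

## Synthetic data: what it emulates, and what not

The generators reproduce the *statistical* structure the estimators
assume: binomially recombining gametes at stated cM distances, lethal
viability filtering, nested family structure with published means and
total SDs, over-dispersed (jittered-lattice) seta fields at published
densities, and Ct triplicates consistent with a stated true ratio.

Deliberate simplifications, hence limits on what passing tests show about
real data:

- **Family variance split.** Only total per-genotype SDs are published;
  the generator assigns 30% of variance between families and 70% within
  (configurable). Real intraclass correlations are unknown.
- **Independent measurements.** Length, width, area and head width are
  generated independently per individual; real wing measurements are
  strongly correlated. Contrast letters are unaffected (per-measurement
  analyses), but joint analyses should not be read into the defaults.
- **Seta fields** are homogeneous jittered square lattices in a square
  region; real distal-wing fields have boundary structure, vein shadows
  and density gradients. A `uniform_random` mode exists for estimator-bias
  studies. With jitter ≤ 25% of spacing, coincident points are
  geometrically impossible; the generator nevertheless verifies
  uniqueness and would regenerate.
- **Ct noise** is i.i.d. Gaussian per well (default SD 0.2 cycles, a
  typical SYBR triplicate scatter); real wells share plate and pipetting
  effects.
- **No images, sequences or reads** are synthesised; patterns arrive as
  coordinates, genotypes as labels.

Two published cell-number figures (the +45% increase quoted alongside
Table-2-style ratios of 1.49 for counts and 1.73 for area, where
1.21 × 1.45 ≈ 1.75) cannot both be derived from one estimator; the
package therefore reports both the count-based and the area/size-quotient
estimators side by side rather than reconciling them.

## Determinism and problem sizes

Every stochastic function takes a seed or Generator; the pipeline spawns
per-stage child seeds from one global seed via `SeedSequence`, and equal
seeds give byte-identical outputs (asserted in tests). Default analysis
sizes — 10⁶-offspring enrichment screens, 15 594-survivor conditioned
screens, 100-replicate wing recoveries, 1000-replicate HSD null
calibrations, 120 random panels against the interval oracle — were chosen
so the full suite and the reproduction script each run in well under a
minute on one core while keeping Monte-Carlo error far inside the
tolerances tested.
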