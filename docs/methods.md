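# Methods

## The contributor-count model

A DNA mixture profile is, per locus, the *set* of distinct alleles
detected; read depths are deliberately not weighted (a discrete,
presence-based model, not a continuous peak-height model). For a proposed
number of diploid contributors `x`, the locus likelihood is the
probability that `2x` gene copies drawn i.i.d. from the population allele
frequencies produce exactly the observed set: every observed allele at
least once and nothing outside the set. The masked-allele enumeration and
its inclusion–exclusion identity (see README) are two routes to the same
number; the multi-locus estimate maximises the product over loci on a
candidate grid, by default x = 1…100.

Assumptions worth keeping in mind:

* contributors are unrelated members of one panmictic population in HWE;
* loci are independent (no linkage);
* the population frequency table is correct — observed alleles without a
  population frequency are dropped before evaluation (their count is
  reported), so an incomplete reference biases x̂ downward;
* detection is what the filtering made it: dropout of true alleles pushes
  x̂ down, artifact alleles that survive filtering and coincide with real
  population alleles push it up. The threshold experiments quantify
  exactly this trade-off.

### Numerics

Three evaluators cross-check each other:

* `likelihood_bruteforce` — enumeration of masked-allele allocations
  (compositions of `2x` into `n` positive parts), with an enumeration cap
  and an exact-rational mode; the test oracle.
* `likelihood_efficient` — the inclusion–exclusion subset sum, computed
  with exact compensated summation (`math.fsum`). The alternating series
  loses precision as `x·n` grows: results escaping `[−tol, 1+tol]`
  (tol = 1e−9) raise a numerical-instability error naming the locus and
  x rather than returning a silently wrong value; values inside the
  tolerance band are clipped to [0, 1].
* `locus_loglik_curve` — the default engine behind profile estimation.
  `L(2x)` is `(2x)!` times the `z^{2x}` coefficient of
  `Π_i (exp(p_i z) − 1)`, so one pass of length-`2x_max` convolutions
  (one per allele) yields the entire log-likelihood curve with **all
  positive terms** — no cancellation at any `x` or `n`, and `O(n·x_max²)`
  instead of `O(2^n · x_max)`. Coefficients are scaled by `m^c` with
  `m = 2x_max/e` to keep them inside double range; results are reported
  in log space. Equality with the other two forms to 1e−9 relative is
  asserted in the test suite.

Ties in the argmax resolve to the smallest x (the conservative abundance
claim). Because the full-set likelihood saturates numerically at 1, a
"boundary" flag is defined as *top-of-grid log-likelihood within 1e−9 of
the maximum* — i.e., the data do not bound x from above — rather than by
the argmax index, which would be tie-resolution luck. A locus whose
observed allele count exceeds `2·max(x_grid)` (zero likelihood
everywhere) aborts with a diagnostic instead of being silently dropped.

## Read processing

Demultiplexed, adapter-free paired FASTQ goes through: (i) 3′
sliding-window quality trimming (window 4, mean Phred ≥ 20; reads shorter
than the longest forward primer afterwards are discarded — trimming
rather than wholesale discarding preserves the amplicon structure);
(ii) pair merging at the longest overlap ≥ 20 bp with mismatch rate
strictly < 0.05, disagreements resolved by base quality; (iii) locus
assignment by exact forward-primer prefix (a mismatch allowance is
exposed for noisy data; ambiguous matches are dropped and counted);
(iv) exact-identity collapsing, with the contig sequence itself as the
allele identifier so identity is stable across samples by construction;
(v) a reference filter requiring ≥ 90% ungapped identity over the first
40 bases against the locus reference (built from the most common allele)
— boundary semantics are: exactly 90% passes, mismatch rate exactly 0.05
fails. Per-sample attrition counts partition the input exactly
(`input = quality + merge + unassigned + reference + counted`), which the
tests assert as an identity, not a tolerance.

## Genotyping and locus QC

Tissue genotypes: top allele by read count; a second allele is accepted
iff it carries ≥ 20% of the individual's reads at the locus (fraction of
*total* locus reads, the natural reading of the rule) and ≥ 10 reads;
an individual is missing where the top allele has < 10 reads. Exact
top-count ties break lexicographically by allele id and are logged.

Locus QC tests genotype counts against HWE expectations with a chi-square
goodness of fit (`G − k` degrees of freedom for `G` possible genotypes
over `k` alleles; an optional Monte-Carlo permutation p-value shuffles
gene copies among individuals). A locus is flagged for exclusion only on
the *conjunction* of significance and heterozygote excess — the
co-amplifying-paralogue signature; a heterozygote deficit (the dropout
signature) is reported but not auto-excluded. No multiplicity correction
is applied across loci by default; both alpha and the permutation count
are configurable.

## eDNA allele frequencies

The pipeline order is fixed and deliberate: per-sample 10-read minimum →
scale each (sample, locus) to 100 reads → per-sample 1% frequency filter
→ pool replicate samples per unit → read-frequency allele frequencies
(or a sensitivity threshold, then mixture profiles). Scaled counts stay
fractional: rounding at 100 reads would erase sub-1% alleles before the
frequency filter could see them. The 1% filter removes rows without
renormalising; frequencies are recomputed from surviving counts at
estimation time. Applying the 1% rule per sample (before pooling) is the
default since it is a per-sample noise filter; a pooled-first order is a
one-line change in the caller.

The sensitivity thresholds are a fixed cutoff t ∈ {0.001, 0.01, 0.1} or a
richness-variable cutoff interpolating **log-linearly** from 0.1 at 2
alleles/locus to 0.001 at 21 alleles/locus (clamped outside). Only the
endpoints are externally specified; log-linear interpolation is this
package's choice because it passes through the middle fixed cutoff (0.01)
at the richness midpoint and spans the three fixed thresholds smoothly.
Richness defaults to the tissue-genotyped reference panel's per-locus
allele counts, falling back to observed eDNA richness without a panel.

## The simulator

The generator emulates the statistical structure the analysis assumes,
with defaults matching the emulated study design: 28 tetranucleotide
loci; per-locus allele counts drawn as `2 + Binomial(19, 0.3895)` (range
2–21, mean 9.4); symmetric Dirichlet(1) allele frequencies; 58 + 15
individuals in HWE; twelve mesocosms (3×1, 3×3, 3×5, 2×10 and one
mis-stocked 11-fish tank); duplicate water samples per tank and
triplicate field samples; total depths 45,534 (tissue), 37,151 (mesocosm
eDNA) and 4,305 (field eDNA) distributed over loci with mild
Dirichlet(50) amplification share variation.

Error model, applied to count tables in this order:

* **shedding inequality** — per-individual contribution weights
  ~ Dirichlet(concentration 1.0 by default; lower = more unequal). The
  real shedding distribution is unknown; the concentration is an exposed
  parameter, not an assertion.
* **dropout** — each allele's reads in a water sample are zeroed with
  probability `min(0.9, 0.05 / rel)` where `rel` is the best carrier's
  weight relative to the equal-share baseline: alleles carried only by
  low-shedding fish drop out more, reproducing the loss of rare alleles
  at low depth.
* **stutter** — 5% of a true allele's reads move to the allele one
  repeat unit shorter (single-step loss only, the dominant
  tetranucleotide artifact). When the one-shorter allele is a real
  population allele this creates exactly the dangerous kind of false
  positive that lax thresholds admit.
* **substitution** — 0.5% of reads move onto a small set of recurrent
  single-base variants of their parent allele (three per allele),
  mimicking how PCR/sequencing errors concentrate on hotspots; unlike
  fully random errors these can pass the 10-read floor.

Tissue reads split between a heterozygote's alleles as
`Binomial(depth, b)`, `b ~ Beta(30, 30)` (mild amplification bias);
dropout is not applied to tissue (high template). Allele sequences are
`primer + flank + k·motif + flank + primer̄`, with a flank SNP haplotype
added when richness exceeds the repeat-count range; panel generation
self-checks that every catalogued sequence round-trips through an
error-free merge and redraws flanks otherwise, which is what makes the
zero-error FASTQ round trip exact rather than merely very likely.

What the simulator does **not** model: multi-step stutter, chimeras,
index hopping, PCR-cycle-explicit amplification, eDNA transport and
degradation, inhibition, or contamination. Passing tests therefore show
the pipeline's statistical behaviour under the modelled artifact classes,
not robustness to every failure mode of real field data.

## Experiment and validation sizes

The experiment drivers and validation suite use sizes chosen to keep any
single run in the seconds-to-minutes range on one CPU while leaving
Monte-Carlo error small against the margins under test: bootstrap mixture
runs default to 200 replicates (1,000 via `--n-reps`); the
threshold-bias experiment aggregates 24 independently simulated studies
(72 tanks per density); contributor recovery uses 200 replicates per
density with a fresh panel every 20; HWE calibration uses 1,000 biallelic
loci of 100 individuals with allele frequency ~ Uniform(0.3, 0.7), keeping
the rarest expected genotype count ≥ 9 (chi-square validity). The
recovery check supplies the exact generating frequencies ("perfect
information"), isolating the estimator's own error; the mesocosm
experiment instead estimates frequencies from the 58 genotyped
individuals, so both frequency regimes are exercised.

## Known limitations

* The contributor model ignores relatedness and population structure;
  related contributors share alleles and push x̂ down.
* Allele identity is exact sequence identity; a single uncorrected
  sequencing error makes a new allele. Denoising is out of scope and the
  filters are the only defence.
* The likelihood treats detection as deterministic given the filters; no
  explicit dropout probability enters the model (it enters the
  experiments through the data instead).
* `x_grid` caps the estimate; boundary estimates are flagged, not
  resolved.
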