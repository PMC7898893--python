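# ednamix

Population allele frequencies and absolute-abundance estimates from
**microsatellite eDNA amplicon sequencing**.

Environmental DNA sampled from water contains nuclear DNA shed by every
individual present, so a multiallelic microsatellite panel amplified from a
water sample is a *DNA mixture*: per locus, a set of detected alleles with
no individual-level genotypes. This package implements the full analysis
chain for such data — for molecular ecologists working on eDNA-based
population assessment and for anyone estimating the number of contributors
to a mixed DNA sample:

* paired-end amplicon read processing (quality trimming, pair merging,
  locus assignment by forward primer, exact-identity collapsing, a
  reference-prefix artifact filter);
* diploid genotype calling from tissue read counts with Hardy–Weinberg
  locus QC, and tissue-based population allele frequencies;
* eDNA read filtering, depth scaling, replicate pooling and read-frequency
  allele-frequency estimation, with fixed and allelic-richness-variable
  low-frequency filters;
* maximum-likelihood estimation of the number of diploid contributors;
* a ground-truthed simulator of the whole study design (mesocosms stocked
  at known densities, duplicate water samples, PCR stutter, substitution
  false alleles, allelic dropout, unequal per-individual shedding).

## The mixture model

At locus *j*, suppose *x* diploid individuals contributed to the sample and
the set *A* = {a₁, …, aₙ} of alleles was detected, with population
frequencies *p* = (p₁, …, pₙ). The 2*x* gene copies carry *d* = 2*x* − *n*
"masked" copies hidden behind alleles already seen. Summing over every
allocation of masked copies (gᵢ ≥ 1 copies of allele aᵢ, Σgᵢ = 2x):

```
L_j(x | A, p) = Σ_{g: gᵢ≥1, Σgᵢ=2x}  (2x)! / Π gᵢ!  ·  Π pᵢ^gᵢ
              = Σ_{B ⊆ A} (−1)^{|A|−|B|} ( Σ_{a∈B} p_a )^{2x}
```

The second (inclusion–exclusion) form is the classical efficient identity;
the package additionally evaluates the whole likelihood *curve* over
x = 1…100 with an all-positive generating-function convolution that avoids
the alternating-series cancellation entirely. The estimate is

```
x̂ = argmax_x  Π_j L_j(x | A_j, p)
```

with ties resolved to the smallest x and a flag raised when the likelihood
has not dropped off by the top of the grid.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 0 --outdir results/study
python analysis/03_edna_frequencies.py --seed 0
python analysis/04_mesocosm_contributors.py --seed 0
```

prints, for the default study (28 loci, 58 fish in 12 mesocosms):

```
eDNA vs tissue allele frequencies: overall Pearson r = 0.948 (per locus 0.78-1.00)
mean within-mesocosm eDNA-tissue PC distance 13.08 vs overall mean 23.42

tissue-derived profiles: max |bias| = 2 contributors
eDNA profiles, fixed_0.001  mean bias by density: {1: 1.0, 3: 2.0, 5: 1.33, 10: 2.0, 11: 1.0}
eDNA profiles, fixed_0.1    mean bias by density: {1: 0.0, 3: -0.67, 5: -2.33, 10: -7.0, 11: -8.0}
eDNA profiles, variable     mean bias by density: {1: 1.0, 3: 1.0, 5: 0.0, 10: -2.5, 11: -2.0}
```

Read: eDNA read frequencies track the tissue-based allele frequencies
closely (r ≈ 0.95) and water samples ordinate next to their own tank's
fish. Contributor estimates from pooled tissue genotypes land within ±2 of
the stocked density. For eDNA-derived allele sets the filtering threshold
controls the sign of the error — lax thresholds keep artifact alleles and
overestimate, the strict 10% threshold deletes true low-frequency alleles
and underestimates dense tanks, and the richness-variable threshold sits
between the extremes. `analysis/05_bootstrap_mixtures.py` extends this to
random combinations of tanks (up to 58 fish) and
`analysis/06_field_trial.py` to low-depth open-water replicates.

The same machinery is scriptable (`ednamix --help`) and importable:

```python
from ednamix import estimate_contributors, MixtureProfile

profile = MixtureProfile({"L01": frozenset({"L01_a02", "L01_a05"})})
pop = {"L01": {"L01_a02": 0.45, "L01_a05": 0.22, "L01_a07": 0.33}}
est = estimate_contributors(profile, pop, range(1, 101))
print(est.x_hat, est.boundary)
```

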