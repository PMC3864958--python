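# Methods

This note records the statistical models, default parameters, and
numerical choices implemented in `poolgsi`, together with what the test
suite does and does not establish.

## 1. Synthetic data generator (F-model)

Population allele frequencies follow the Balding–Nichols F-model. For
each biallelic locus *l* an ancestral B-allele frequency
*p<sub>l</sub>* ~ Uniform(0.05, 0.95) is drawn, and each population *j*
draws

p<sub>lj</sub> ~ Beta(p<sub>l</sub>·s, (1−p<sub>l</sub>)·s),  s = (1−F)/F,

which has mean *p<sub>l</sub>* and variance
*p<sub>l</sub>*(1−*p<sub>l</sub>*)·F. Divergence *F* may vary per
population. A chosen fraction of loci (default 5%, exactly
round(fraction·L) loci) are flagged as outliers and use F multiplied by
a factor (default 8), mimicking divergent selection; an effective F ≥ 1
is rejected with an error. Multiallelic (microsatellite-like) loci use
the Dirichlet analogue with concentration (1−F)/F.

The pooled-array observation model: each population is measured as
*r* technical replicates (default 4) of theta, where theta is the
frequency passed through the inverse cluster mapping (below) plus
Gaussian noise (default SD 0.01) truncated to [0, 1]. Genotype cluster
references per locus are drawn around 0.05 / 0.50 / 0.95 with jitter
0.02, redrawn until strictly ordered.

**Scope.** Generator defaults (20 populations, 1000 SNPs, F = 0.05, 5%
outliers × 8, pools of 50 diploids, 4 replicates, noise SD 0.01) define
the study conditions used by the acceptance script and end-to-end tests.
The generator assumes Hardy–Weinberg and linkage equilibrium,
independent loci, no null alleles, no pool-construction (unequal
individual contribution) error, and symmetric Gaussian theta noise.
Passing tests therefore demonstrate internal consistency of the
estimators under this model — not robustness to array artefacts,
related individuals, or unequal pooling, none of which are simulated.

## 2. Allelotyping

Theta is converted to B-allele frequency by piecewise-linear
interpolation against the locus's cluster means: frequency 0 at the AA
mean, 0.5 at the AB mean, 1 at the BB mean, clipped outside. The
mapping and its inverse are exact on [0, 1], which the tests exploit
(zero-noise pools round-trip to machine precision).

Quality control is panel-wide: a locus is retained only if the sample
SD of theta across its replicates is ≤ 0.02 in *every* population.
Each replicate is converted to a frequency first and replicates are then
averaged (conversion before averaging), so the nonlinearity of the
piecewise mapping never mixes replicates on the theta scale.

## 3. Population-genetic statistics

- **Expected heterozygosity**: 2p(1−p) per locus/population; per-
  population mean and median reported.
- **F<sub>ST</sub>**: Weir & Cockerham (1984) variance components
  a, b, c computed from frequencies with nominal diploid sample sizes
  (heterozygosity taken as its HWE expectation, since pools provide no
  observed heterozygosity). Per-locus estimates a/(a+b+c); global and
  pairwise variants; negative estimates are retained in means rather
  than truncated; loci monomorphic everywhere are NaN. A
  ratio-of-sums estimator is also reported for the global case.
- **Delta**: mean over population pairs of |p<sub>i</sub> −
  p<sub>j</sub>|.
- **Nei's D<sub>A</sub>**: 1 − (1/L) Σ<sub>l</sub> Σ<sub>alleles</sub>
  √(p<sub>i</sub>p<sub>j</sub>), defined for biallelic and multiallelic
  tables.
- **Trees**: neighbour-joining on D<sub>A</sub> (negative branch
  lengths truncated to 0); bootstrap over loci with a majority-rule
  consensus carrying percentage support. NJ and consensus are delegated
  to dendropy; the test suite verifies NJ recovers additive metrics
  exactly.

## 4. Outlier scan

A Bayesian F-model scan in the BayeScan style. Locus/population-specific
differentiation is θ<sub>lj</sub> = exp(−(α<sub>l</sub> + β<sub>j</sub>))
(so logit F<sub>ST</sub> decomposes as α + β), and the B-allele count is
beta-binomial: a<sub>lj</sub> ~ BetaBin(n<sub>lj</sub>,
p̄<sub>l</sub>·m<sub>lj</sub>, (1−p̄<sub>l</sub>)·m<sub>lj</sub>) with
m<sub>lj</sub> = θ<sub>lj</sub>/(1−θ<sub>lj</sub>)·(scale form in code).
Priors: α<sub>l</sub> ~ N(0, 1) when included, β<sub>j</sub> ~ N(−1, 1),
p̄<sub>l</sub> ~ Uniform(0, 1). Reversible-jump MCMC toggles each
α<sub>l</sub> in or out, using the prior as the birth proposal (proposal
and prior densities cancel, leaving the likelihood ratio and the prior
inclusion odds); prior odds for neutrality default to 10. All loci
update in parallel via vectorised numpy; random-walk scales adapt
during burn-in only.

Reported per locus: posterior inclusion probability, log<sub>10</sub>
posterior odds (capped at the Monte-Carlo resolution of half a retained
sample), and a Bayesian q-value (cumulative mean exclusion probability
in decreasing order of posterior odds, ties sharing the last value).
Selection flag: log<sub>10</sub> PO > 1 and q < 0.05.

**MCMC schedule.** Defaults are burn-in 2000 sweeps, 1200 retained
samples at thinning 3 (7600 sweeps total). These are the package's own
runtime-conscious defaults; the validation tests show that at this
schedule a neutral 20 × 1000 panel yields few selections (posterior
inclusion near the prior 1/11) while planted outliers (F × 8) are
recovered with mean recall ≥ 0.7 and precision ≥ 0.8 across seeds.
Longer chains can be requested through `McmcSettings`.

## 5. Genetic stock identification

Assignment likelihoods follow Rannala & Mountain: with a Dirichlet(½, ½)
prior on baseline frequencies, the posterior-predictive genotype
probabilities given baseline B-counts x<sub>B</sub> of n gene copies are

P(BB) = (x<sub>B</sub>+½)(x<sub>B</sub>+1½) / ((n+1)(n+2)), P(AB) =
2(x<sub>A</sub>+½)(x<sub>B</sub>+½) / ((n+1)(n+2)),

and symmetrically for AA (verified in tests against Polya-urn
enumeration). Mixture composition is estimated by EM on the mixture
individuals' likelihood matrix (monotone log-likelihood, tolerance
1e-6); assignment uses the EM proportions as prior by default (uniform
optional) and takes the maximum-posterior population.

Accuracy curves simulate disjoint baseline (100/population) and mixture
(500/population) genotype sets under HWE/LE from the frequency table,
for nested top-K panels of a ranking (or seeded random subsets). The
x-axis is independent alleles, Σ(k−1) over loci — equal to the SNP
count for biallelic panels, allowing mixed SNP/microsatellite
comparisons.

The accuracy–panel-size relationship is summarised by
y = exp(a + b/x), fit by least squares of ln y on 1/x. The markers
required for target t are ceil(b/(ln t − a)); if ln t ≥ a the target
exceeds the asymptote e<sup>a</sup> and is unattainable (None). A
non-negative b (flat or saturated curve, tolerance 1e-12) falls back to
the smallest observed panel size already meeting the target, with a
warning.

## 6. Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; sub-streams derive from tuples (seed, tag) so results
  are reproducible and independent across stages.
- Pseudo-counts for the outlier scan are round(2np) of 2n gene copies —
  pool frequencies carry no genotype-level counts, so nominal sample
  sizes stand in.
- Ranking ties break lexicographically on locus id via a stable sort;
  NaN scores sink to the bottom; random rankings require a seed.
- Linkage pruning is greedy best-first with a minimum within-chromosome
  distance (default 1 cM); unmapped loci are never pruned.
- Genepop export codes alleles 01/02 (0101/0102/0202 for dosage
  0/1/2); missing genotypes (0000) and third alleles are rejected on
  import.
- TSV writers embed provenance as `#key=value` header comments;
  floats use `%.8g`.

## 7. Limitations

- Pool frequencies are treated as known when building GSI baselines via
  pseudo-counts; allelotyping measurement error is propagated only
  through the simulated pipeline, not modelled in the likelihood.
- The outlier scan assumes the island F-model; hierarchical structure
  can inflate false positives (not simulated or tested).
- Accuracy curves and marker requirements are estimates under HWE/LE
  simulation from the supplied frequencies; real panels with linked
  loci will need the independent-allele correction plus pruning.
- The exponential curve is an empirical summary; its extrapolation
  beyond observed panel sizes should be read with caution, especially
  near saturation where the fit is weakly identified.
- No empirical claims are made beyond the quantities computed by the
  test suite and `scripts/acceptance.py`.
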