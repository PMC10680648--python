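# Methods

## Phenotype model

A biallelic locus has alleles A1 and A2 (A2 focal); `g` counts copies of
A2 in a child. The phenotype of child `i` in family `f` is

    Y_i = Y* + (alpha + alpha_f + alpha_i) g_i + eps_f + eps_i,

with `alpha` the mean per-allele effect, `alpha_f` and `alpha_i` mean-zero
family- and individual-level deviations of the *effect* (gene-by-
environment interaction), and `eps_f`, `eps_i` mean-zero environmental
deviations of the *trait*. The multi-locus version sums
`(alpha_l + alpha_lf + alpha_il) g_il` over causal loci `L`; a polygenic
score sums `beta_hat_l g_il` over a genotyped subset `Lambda ⊆ L`. All
loci are unlinked and in linkage equilibrium within populations, by
construction of the generator.

The mean-zero convention for the deviations is enforced: population-level
offsets must average to zero under the family sampling weights, and extra
family/individual deviations are drawn from centered Gaussians. A config
that violates this is rejected rather than silently recentered.

## The generator

- **Parents.** Genotypes are i.i.d. Hardy–Weinberg draws at the
  population's allele frequency; an optional inbreeding coefficient F
  deforms the parental genotype frequencies to
  (q²+Fpq, 2pq(1−F), p²+Fpq). Mating is monogamous and random within
  population; one child per family by default, two for sibling designs.
- **Segregation.** Each parent transmits a gamete carrying the focal
  allele with probability g/2. The segregation deviation
  `ς = g_child − (g_m+g_f)/2` is recorded per locus; it takes values in
  {−1, −½, 0, ½, 1}, is zero when both parents are homozygous, and has
  conditional variance (h_m + h_f)/4 with h the parental heterozygosity
  indicator.
- **Two-locus haplotypes.** Parents are pairs of haplotypes over
  {MA, Ma, mA, ma}; a gamete takes its marker allele from a uniformly
  chosen parental haplotype and its causal allele from the same haplotype
  with probability 1−r. The causal allele A adds `causal_alpha` to the
  trait with no G×E; only the marker is treated as genotyped downstream.
- **Drift.** Wright–Fisher binomial resampling of 2N allele copies per
  generation, run independently in the two populations from a shared p0.
  Defaults (N = 500, 50 generations, p0 = 0.5) give mean F_ST ≈ 0.05 and
  a broad spread across replicates; both knobs are exposed. F_ST is Nei's
  G_ST with equal population weights, 1 − H_S/H_T.
- **Randomness.** A single top-level seed feeds a `SeedSequence`; each
  population and stage gets a spawned child stream, so cohorts are
  reproducible and runs with equal configs are byte-identical on disk.

## Estimators

All estimators are OLS with heteroskedasticity-robust (HC1) standard
errors — heterogeneity makes the residual variance genotype-dependent by
construction. Designs:

| design | regression | expectation |
|---|---|---|
| population | Y ~ 1 + g | Cov(Y,g)/Var(g) |
| trio | Y ~ 1 + g + g_m + g_f | alpha + E[alpha_f &#124; het parent] |
| sibling | ΔY ~ Δg (no intercept) | same as trio |
| segregation | Y ~ 1 + ς | same as trio |
| family PGS | Y ~ 1 + PGS + (PGS_m+PGS_f) | Σ H β̂ (α + E[α_lf&#124;h_l]) / Σ H β̂² |
| population PGS | Y ~ 1 + PGS | between term + (V_ς/V_PGS)·δ_fam |

For single loci the trio design controls mother and father separately by
default (also absorbing parent-of-origin frequency differences); a `sum`
flag reproduces the parental-sum parameterization used for the PGS, and
the two agree asymptotically. With the segregation deviation taken as the
*empirical* residual of the child score on the parental controls, the
segregation regression reproduces the trio/PGS child coefficient exactly
on any finite sample (Frisch–Waugh–Lovell); the *structural* deviation
(child minus midparent, computable from observed parental genotypes) gives
the same expectation and is the default for real data.

Monomorphic loci, zero segregation variance, and collinear PGS controls
raise explicit degenerate-input errors naming the structural cause; they
are never silently skipped.

## Closed-form oracles

`theory` computes each design's expectation without noise. The population
slope is enumerated exactly over (mating type, environment, segregation
outcome) with rational transmission weights (¼, ½), standing in for the
fully written-out weighted sum. The enumeration also returns the
between/within split: the within-family term equals
(1−F)/(2(1+F)) × the trio expectation whenever the parental and offspring
generations share p and F. That stationarity holds when F is generated by
population structure (HWE within populations; Wahlund effect pooled) but
not when parental genotypes are themselves inbred within a population —
one round of random mating removes within-population inbreeding. The
result object therefore carries the exact enumerated within-term, the
single-F split, and a `consistent` flag; configurations where the two
disagree are flagged rather than forced.

Counterfactual allele-flip effects weight the per-genotype conditional
deviations by the gamete origin probabilities; the allele-frequency-
weighted average of the two flip directions equals `alpha` identically,
which the property suite checks to machine precision on 1000 random
joints.

For a marker tagging a causal locus, the trio expectation is
(1−2r)(p'_{A|M,Mm} − p'_{A|m,Mm})·alpha with the heterozygote-conditional
haplotype proportions taken in the parental generation; an
`approx_offspring` flag reproduces the tight-linkage approximation using
offspring-generation conditionals. At r = 0 the estimate decomposes
exactly into the pooled haplotype-flip effect plus an LD-heterogeneity
bias term. The population slope at the marker equals the haplotype-flip
effect computed on the *offspring gamete pool* (gamete LD (1−r)D) within a
homogeneous population; across structured samples the between-population
covariance enters the slope with a different weight than it enters the
pooled flip, so the verification matrix checks that relation only on the
single-population configuration.

Under the multiplicative G×E model (alpha_lf = C_f·alpha_l, β̂ = B·alpha),
each family has a well-defined slope (1+C_f)/B and the within-family
regression recovers the average weighted by each family's PGS segregation
variance Σ β̂²(h_m+h_f)/4 — not the unweighted average. The designed
contrast (one family class heterozygous at three times as many equal-
heterozygosity loci as the other, C = ±0.5) separates the weighted
prediction (1.25) from the unweighted one (1.0); 15,000 families per class
make that 0.25 gap decisive at 3 Monte Carlo SEs, since the heterogeneous
slopes themselves inflate the regression's residual variance.

## Variance decomposition and segregation averaging

V_PGS = Var(midparent PGS) + V_ς up to the (mean-zero) sampling covariance
between midparent score and segregation deviation. Under random mating and
linkage equilibrium V_ς = V_PGS/2. The share of phenotypic variance that
within-family PGS variation explains without extrapolation is
δ̂²_fam·V_ς/V_P; the conventional δ̂²_fam·V_PGS/V_P additionally
extrapolates the within-family slope to the between-family variance.

`segregation_averaging` performs the corresponding manipulation on
simulation truth: each child's phenotype is replaced by its conditional
mean over segregation at the scored loci (subtracting
Σ_(l∈Λ) (alpha_l + alpha_lf + alpha_il)·ς_l), and the realized variance
reduction is compared with δ̂²_fam·V_ς. Equality is asserted only in the
homogeneous regime (β̂ = α, no G×E, no individual deviations); under
heterogeneous slopes the exact expected reduction is the variance of the
realized segregation contribution, which the report returns alongside the
prediction rather than asserting equality (Jensen-gap caveat).

## Numerical and testing choices

- Exact identities (flip average, population-slope split, FWL,
  marker-estimate decomposition at r = 0, allele-relabeling symmetry) are
  tested at 1e-10–1e-12; simulation-versus-theory comparisons at 3 Monte
  Carlo SEs, with variance-ratio SEs from a per-child delta method.
- The verification matrix (`famhet verify`, `verify_all`) runs the full
  configuration bank — no G×E, two-environment G×E with and without
  frequency differentiation, Wahlund structure at F = 0.2, single- and
  two-population LD-heterogeneity, homogeneous / heterogeneous /
  multiplicative PGS, and segregation averaging — at 5×10⁴ families by
  default and exits nonzero on any failing row.
- The drift experiment summarizes the family-estimate sign concordance
  both raw and restricted to informative replicates (predicted deviation
  0.1·(H_red−H_blue)/(H_red+H_blue) above twice the Monte Carlo SE),
  because near-equal heterozygosities make the raw sign a coin flip.

## What the generator does and does not emulate

The simulator reproduces the statistical structure the derivations assume:
unconfounded genotypes, independent unlinked loci, random mating within
populations, environment-linked effect deviations that are constant within
a population. It does not model assortative mating or signed long-range
LD (which move V_ς/V_PGS away from ½), selection or participation bias,
indirect genetic effects of relatives, sex chromosomes, or missing
genotypes in simulated output (missingness is exercised through the file
layer). Passing tests therefore validate the analytical claims under
those idealized conditions, not the magnitude of the biases in any real
cohort.
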