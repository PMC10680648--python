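# famhet

Family- and population-based GWAS under heterogeneous allelic effects:
a simulator, an estimator suite, and closed-form predictions for what each
study design actually estimates.

## The problem

Family-based association studies (trio and sibling designs) are widely
treated as randomized experiments: Mendelian segregation randomizes which
allele a child inherits, so the within-family regression slope is read as
the average causal effect of an allele or polygenic score (PGS). But
segregation only randomizes alleles in the children of *heterozygous*
parents. If an allele's effect differs across family environments
(gene-by-environment interaction) or if linkage disequilibrium between a
genotyped marker and the causal variant differs across families, the
children of heterozygotes are not a random slice of the sample — and the
family-based estimate is a *local* average treatment effect (LATE) for
them, not the sample-average effect.

`famhet` makes every piece of that argument checkable. For the
single-locus phenotype model

    Y = Y* + (α + α_f + α_i)·g + ε_f + ε_i,

with g ∈ {0,1,2} the focal-allele count and α_f, α_i mean-zero family- and
individual-level effect deviations, the package provides:

- **simulate** — structured populations with drifted allele frequencies,
  Mendelian trios and sib pairs, two-locus haplotypes with recombination
  fraction r and population-specific LD, and multi-locus PGS cohorts
  (PGS = Σ_l β̂_l g_l).
- **estimate** — OLS designs with HC1 robust errors: population
  (Y ~ g), trio (Y ~ g controlling for both parental genotypes), sibling
  difference, segregation-deviation regression (Y ~ ς with
  ς = g − (g_m+g_f)/2), and the PGS analogues controlling for the
  parental PGS sum, plus the within/between-family PGS variance
  decomposition V_PGS = Var(midparent PGS) + V_ς.
- **theory** — noise-free counterparts: counterfactual allele-flip
  effects, the trio expectation α + E[α_f | heterozygous parent], the
  population slope by exact enumeration with its between/within split
  (the within term is (1−F)/(2(1+F)) times the trio slope), marker-locus
  predictions under LD heterogeneity, and the heterozygosity-weighted PGS
  slopes δ_rand = Σ H_l β̂_l α_l / Σ H_l β̂_l² and its family-based
  counterpart with E[α_lf | h_l] added per locus.
- **experiments** — the two-population drift experiment, a
  simulation-versus-theory verification matrix, and the
  segregation-averaging manipulation behind the claim that only the
  within-family share δ̂²_fam·V_ς/V_P of PGS-attributed variance is
  estimated without extrapolation.

## Worked example

Two populations, each in its own environment: the focal allele adds 1.1
per copy in the "red" environment and 0.9 in the "blue" one (average
effect 1). The allele is at frequency 0.5 in the red population and absent
in the blue one, so every heterozygous parent lives in the red
environment:

```python
from famhet import estimate, simulate, theory
from famhet.experiments import fig1_effect_model, fig1_specs

cohort = simulate.simulate_cohort(
    fig1_specs(p_red=0.5, p_blue=0.0, n_families=25_000),
    fig1_effect_model(),    # alpha=1, environment noise SD 0.5
    seed=1,
)
pop = estimate.population_gwas(cohort)
fam = estimate.family_gwas(cohort)
print(f"population slope {pop.slope:.3f} +/- {pop.stderr:.3f}")
print(f"trio slope       {fam.slope:.3f} +/- {fam.stderr:.3f}")

joint = theory.DiscreteJoint.from_populations(
    [("red", 0.5, 0.5, +0.1), ("blue", 0.5, 0.0, -0.1)]
)
print("predicted trio slope", theory.predicted_family_estimate(joint, alpha=1.0))
```

Output:

```
population slope 1.099 +/- 0.004
trio slope       1.096 +/- 0.009
predicted trio slope 1.1
```

Both designs recover ≈1.1 — the red-environment effect — rather than the
population-average effect of 1, because all the usable genotype variance
(between families for the population design, within families for the trio
design) sits in the red environment. The trio slope is the LATE for the
children of heterozygous parents.

The same machinery is scriptable from the shell:

```sh
famhet simulate --config cfg.json --out run --seed 1   # PED-style files
famhet gwas --fam run.fam --geno run.geno --design trio
famhet predict --config cfg.json                       # closed forms
famhet figure1 --out fig1/                             # drift experiment
famhet verify --report report.tsv                      # sim-vs-theory matrix
```

File formats are a minimal whitespace PED dialect: a `.fam` file
(`family_id individual_id father_id mother_id sex phenotype`) and a
`.geno` file (`family_id individual_id` then two allele columns per locus,
alleles coded 1/2, 0 missing), plus a `.truth.tsv` sidecar carrying
simulation-only truth (population label, realized α_f).

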