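"""Generator-level checks: Mendelian segregation, HWE, drift, F_ST,
recombination, and the structural invariants of simulated cohorts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famhet.errors import ConfigError
from famhet.simulate import (
    HAPLOTYPES,
    LocusEffectModel,
    PGSModel,
    PopulationSpec,
    assign_phenotype,
    compute_fst,
    draw_gametes,
    draw_parent_genotypes,
    pgs_cohort_from_parents,
    segregate,
    simulate_cohort,
    simulate_drift,
    simulate_pgs_cohort,
)


# ----------------------------------------------------------------------
# parental draws
# ----------------------------------------------------------------------
@pytest.mark.parametrize("p,expected", [(0.0, 0), (1.0, 2)])
def test_fixed_allele_gives_constant_genotypes(p, expected):
    g = draw_parent_genotypes(p, 5, seed=0)
    assert np.all(g == expected)


def test_hwe_proportions_at_half():
    g = draw_parent_genotypes(0.5, 100_000, seed=1)
    het = np.mean(g == 1)
    se = np.sqrt(0.5 * 0.5 / 100_000)
    assert abs(het - 0.5) < 3 * se


def test_inbreeding_deforms_genotype_frequencies():
    n = 200_000
    g = draw_parent_genotypes(0.4, n, seed=2, inbreeding_F=0.3)
    expected_het = 2 * 0.4 * 0.6 * 0.7
    se = np.sqrt(expected_het * (1 - expected_het) / n)
    assert abs(np.mean(g == 1) - expected_het) < 3 * se


def test_invalid_frequency_rejected():
    with pytest.raises(ConfigError):
        draw_parent_genotypes(1.5, 10)


# ----------------------------------------------------------------------
# segregation
# ----------------------------------------------------------------------
@pytest.mark.parametrize("gm,gf,child", [(0, 0, 0), (2, 2, 2), (0, 2, 1)])
def test_homozygous_parents_transmit_deterministically(gm, gf, child):
    g = segregate(np.full(50, gm), np.full(50, gf), seed=3)
    assert np.all(g == child)


def test_double_heterozygote_child_distribution():
    n = 40_000
    g = segregate(np.ones(n, dtype=int), np.ones(n, dtype=int), seed=4)
    observed = np.bincount(g, minlength=3)
    chi2 = stats.chisquare(observed, n * np.array([0.25, 0.5, 0.25]))
    assert chi2.pvalue > 0.01


@given(gm=st.integers(0, 2), gf=st.integers(0, 2), seed=st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_segregation_deviation_is_bounded_and_half_integer(gm, gf, seed):
    child = int(segregate(gm, gf, seed=seed))
    dev = child - (gm + gf) / 2.0
    assert dev in (-1.0, -0.5, 0.0, 0.5, 1.0)
    if gm != 1 and gf != 1:
        assert dev == 0.0


def test_seg_variance_matches_parental_heterozygosity():
    # Var(seg_dev | parents) = (h_m + h_f) / 4 with h the het indicator
    rng_seed = 5
    n = 60_000
    for gm, gf in [(1, 0), (1, 1), (1, 2), (0, 2)]:
        g = segregate(np.full(n, gm), np.full(n, gf), seed=rng_seed)
        dev = g - (gm + gf) / 2.0
        expected = ((gm == 1) + (gf == 1)) / 4.0
        assert np.var(dev) == pytest.approx(expected, abs=0.01)
        assert np.mean(dev) == pytest.approx(0.0, abs=0.01)


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
def test_phenotype_plugin_values():
    noiseless = LocusEffectModel(intercept=0.0, alpha=1.0)
    # effect 1.1 in the red environment, two focal alleles
    draw = assign_phenotype(2, noiseless, env_effect_dev=0.1, seed=0)
    assert draw.phenotype[0] == pytest.approx(2.2)
    # genotype zero contributes nothing beyond intercept + noise
    draw = assign_phenotype(0, LocusEffectModel(intercept=3.0, alpha=5.0), seed=0)
    assert draw.phenotype[0] == pytest.approx(3.0)
    shifted = LocusEffectModel(intercept=5.0, alpha=1.0)
    assert assign_phenotype(1, shifted, seed=0).phenotype[0] == pytest.approx(6.0)


# ----------------------------------------------------------------------
# drift and F_ST
# ----------------------------------------------------------------------
def test_drift_zero_generations_is_identity():
    assert simulate_drift(0.5, 100, 0, seed=0) == (0.5, 0.5)


def test_drift_one_generation_large_population():
    p_red, p_blue = simulate_drift(0.5, 10**6, 1, seed=1)
    se = np.sqrt(0.25 / (2 * 10**6))
    assert abs(p_red - 0.5) < 3 * se
    assert abs(p_blue - 0.5) < 3 * se


def test_long_drift_fixes_small_population():
    p_red, p_blue = simulate_drift(0.5, 50, 10_000, seed=2)
    assert p_red in (0.0, 1.0)
    assert p_blue in (0.0, 1.0)


def test_fst_hand_values():
    assert compute_fst(0.4, 0.4) == 0.0
    assert compute_fst(0.0, 1.0) == pytest.approx(1.0)
    assert compute_fst(0.3, 0.7) == pytest.approx(0.16)
    assert compute_fst(0.0, 0.0) == 0.0  # monomorphic pooled locus


@given(
    p1=st.floats(0.0, 1.0, allow_nan=False),
    p2=st.floats(0.0, 1.0, allow_nan=False),
)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_fst_is_symmetric_and_bounded(p1, p2):
    f = compute_fst(p1, p2)
    assert 0.0 <= f <= 1.0 + 1e-12
    assert f == pytest.approx(compute_fst(p2, p1))


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------
def test_cohort_conservation_and_hwe():
    specs = [PopulationSpec("pop", 0.3, 0.0, 30_000)]
    model = LocusEffectModel(alpha=1.0, sd_env_indiv=0.5)
    cohort = simulate_cohort(specs, model, seed=6)
    # exact per-child conservation: g = midparent + seg_dev
    mid = (cohort.g_mother + cohort.g_father) / 2.0
    assert np.array_equal(cohort.g_child, mid + cohort.seg_dev)
    assert set(np.unique(cohort.seg_dev)) <= {-1.0, -0.5, 0.0, 0.5, 1.0}
    both_hom = (cohort.g_mother != 1) & (cohort.g_father != 1)
    assert np.all(cohort.seg_dev[both_hom] == 0.0)
    # offspring genotype frequencies match HWE under panmixia
    for geno, freq in [(0, 0.49), (1, 0.42), (2, 0.09)]:
        obs = np.mean(cohort.g_child[:, 0] == geno)
        se = np.sqrt(freq * (1 - freq) / cohort.n_children)
        assert abs(obs - freq) < 3.5 * se


def test_mean_zero_offsets_enforced():
    specs = [
        PopulationSpec("a", 0.5, 0.2, 100),
        PopulationSpec("b", 0.5, 0.1, 100),
    ]
    with pytest.raises(ConfigError):
        simulate_cohort(specs, LocusEffectModel(), seed=0)


def test_same_seed_reproduces_cohort():
    specs = [PopulationSpec("pop", 0.4, 0.0, 500)]
    model = LocusEffectModel(alpha=1.0, sd_env_family=0.3, sd_env_indiv=0.3)
    a = simulate_cohort(specs, model, seed=42)
    b = simulate_cohort(specs, model, seed=42)
    assert np.array_equal(a.g_child, b.g_child)
    assert np.allclose(a.phenotype, b.phenotype)


# ----------------------------------------------------------------------
# two-locus transmission
# ----------------------------------------------------------------------
def test_gamete_distribution_with_recombination():
    # MA/ma parent, r = 0.2: gametes {MA: 0.4, ma: 0.4, Ma: 0.1, mA: 0.1}
    n = 20_000
    diplo = np.tile([HAPLOTYPES.index("MA"), HAPLOTYPES.index("ma")], (n, 1))
    gametes = draw_gametes(diplo, 0.2, seed=7)
    observed = np.bincount(gametes, minlength=4)
    expected = n * np.array([0.4, 0.1, 0.1, 0.4])  # order MA, Ma, mA, ma
    assert stats.chisquare(observed, expected).pvalue > 0.01


def test_no_recombination_transmits_parental_haplotypes():
    rng = np.random.default_rng(8)
    diplo = rng.integers(0, 4, size=(5_000, 2))
    gametes = draw_gametes(diplo, 0.0, seed=9)
    assert np.all((gametes == diplo[:, 0]) | (gametes == diplo[:, 1]))


def test_free_recombination_decouples_loci():
    # MA/ma parent at r = 0.5: all four gametes equally likely
    n = 20_000
    diplo = np.tile([0, 3], (n, 1))
    gametes = draw_gametes(diplo, 0.5, seed=10)
    observed = np.bincount(gametes, minlength=4)
    assert stats.chisquare(observed, np.full(4, n / 4)).pvalue > 0.01


# ----------------------------------------------------------------------
# polygenic cohorts
# ----------------------------------------------------------------------
def test_single_locus_pgs_is_the_genotype():
    model = PGSModel(p=[0.5], alpha=[1.0], beta_hat=[1.0], sd_env_indiv=0.1)
    cohort = simulate_pgs_cohort(model, [PopulationSpec("pop", None, 0.0, 2_000)], seed=11)
    child, mother, father = cohort.pgs(model.beta_hat, model.pgs_loci)
    assert np.array_equal(child, cohort.g_child[:, 0])
    seg = child - (mother + father) / 2.0
    assert np.array_equal(seg, cohort.seg_dev[:, 0])


def test_homozygous_parents_give_zero_pgs_segregation():
    model = PGSModel(p=np.full(5, 0.5), alpha=np.ones(5), beta_hat=np.ones(5))
    gm = np.full((100, 5), 2, dtype=np.int8)
    gf = np.zeros((100, 5), dtype=np.int8)
    cohort = pgs_cohort_from_parents(model, gm, gf, ["e"] * 100, seed=12)
    child, mother, father = cohort.pgs(model.beta_hat, model.pgs_loci)
    assert np.all(child - (mother + father) / 2.0 == 0.0)


def test_pgs_segregation_deviation_is_mean_zero():
    L, n = 200, 20_000
    model = PGSModel(p=np.full(L, 0.5), alpha=np.full(L, 0.1), beta_hat=np.full(L, 0.1))
    cohort = simulate_pgs_cohort(model, [PopulationSpec("pop", None, 0.0, n)], seed=13)
    child, mother, father = cohort.pgs(model.beta_hat, model.pgs_loci)
    seg = child - (mother + father) / 2.0
    assert abs(seg.mean()) < 3 * seg.std(ddof=1) / np.sqrt(n)


def test_pgs_loci_must_be_subset_of_causal():
    with pytest.raises(ConfigError):
        PGSModel(p=[0.5, 0.5], alpha=[1.0, 1.0], beta_hat=[1.0], pgs_loci=[5])


def test_pgs_population_devs_must_be_mean_zero():
    model = PGSModel(
        p=[0.5], alpha=[1.0], beta_hat=[1.0],
        population_dev={"a": [0.2], "b": [0.1]},
    )
    specs = [PopulationSpec("a", None, 0.0, 10), PopulationSpec("b", None, 0.0, 10)]
    with pytest.raises(ConfigError):
        simulate_pgs_cohort(model, specs, seed=0)
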