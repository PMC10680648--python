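"""Closed-form predictions: allele-flip identities, the population-slope
enumeration and its two-term split, marker-locus LD predictions, and the
polygenic-score slope formulas."""

import numpy as np
import pytest

from famhet.errors import ConfigError, DegenerateInputError
from famhet.simulate import LocusEffectModel, PGSModel, PopulationSpec, TwoLocusModel
from famhet import theory
from famhet.theory import (
    DiscreteJoint,
    flip_effects,
    hap_flip_effect,
    het_conditional_devs,
    multiplicative_family_slopes,
    pgs_randomization_effect,
    predicted_family_estimate,
    predicted_marker_family_estimate,
    predicted_pgs_family_estimate,
    predicted_population_estimate,
)

FIG1_JOINT = DiscreteJoint.from_populations(
    [("red", 0.5, 0.5, 0.1), ("blue", 0.5, 0.0, -0.1)]
)


# ----------------------------------------------------------------------
# allele flips
# ----------------------------------------------------------------------
def test_flip_effects_without_heterogeneity():
    joint = DiscreteJoint.from_populations([("pop", 1.0, 0.3, 0.0)])
    eff = flip_effects(joint, alpha=2.0)
    assert eff.flip_1to2 == pytest.approx(2.0)
    assert eff.flip_2to1 == pytest.approx(-2.0)
    assert eff.averaged == pytest.approx(2.0)


def test_flip_effects_fig1_brute_force():
    """The A1->A2 flip effect equals alpha plus the average deviation over
    A1-bearing parental gametes, enumerated independently here."""
    eff = flip_effects(FIG1_JOINT, alpha=1.0)
    # brute force over the 6 (genotype, population) cells
    cells = []  # (prob of parent, n A1 gametes per parent, alpha_f)
    for w, p, a in [(0.5, 0.5, 0.1), (0.5, 0.0, -0.1)]:
        q = 1 - p
        for geno, gp in [(0, q * q), (1, 2 * p * q), (2, p * p)]:
            cells.append((w * gp, 2 - geno, a))
    total_a1 = sum(prob * n for prob, n, _ in cells)
    e_dev = sum(prob * n * a for prob, n, a in cells) / total_a1
    assert eff.flip_1to2 == pytest.approx(1.0 + e_dev)
    assert eff.averaged == pytest.approx(1.0)


def test_flip_average_identity_on_random_joints(random_joint):
    """The allele-frequency-weighted average of the two flip effects equals
    alpha to machine precision, whatever the joint."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        joint = random_joint(rng)
        alpha = float(rng.normal(0, 1))
        eff = flip_effects(joint, alpha)
        assert abs(eff.averaged - alpha) < 1e-12
        # the weighted-average identity is definitional
        p = joint.p
        assert eff.averaged == pytest.approx(
            (1 - p) * eff.flip_1to2 + p * (-eff.flip_2to1), abs=1e-12
        )


def test_flip_undefined_at_fixed_locus():
    joint = DiscreteJoint.from_populations([("pop", 1.0, 1.0, 0.0)])
    with pytest.raises(DegenerateInputError):
        flip_effects(joint, 1.0)


def test_joint_requires_mean_zero_devs():
    with pytest.raises(ConfigError):
        DiscreteJoint.from_populations([("a", 0.5, 0.5, 0.2), ("b", 0.5, 0.5, 0.0)])


# ----------------------------------------------------------------------
# family and population predictions
# ----------------------------------------------------------------------
def test_family_prediction_is_late_of_heterozygous_parents():
    joint = DiscreteJoint.from_populations([("pop", 1.0, 0.3, 0.0)])
    assert predicted_family_estimate(joint, 1.0) == pytest.approx(1.0)
    # heterozygosity confined to the red environment -> effect 1.1
    assert predicted_family_estimate(FIG1_JOINT, 1.0) == pytest.approx(1.1)
    mirror = DiscreteJoint.from_populations(
        [("red", 0.5, 1.0, 0.1), ("blue", 0.5, 0.5, -0.1)]
    )
    assert predicted_family_estimate(mirror, 1.0) == pytest.approx(0.9)


def test_family_prediction_requires_heterozygous_parents():
    joint = DiscreteJoint.from_populations([("a", 0.5, 0.0, 0.1), ("b", 0.5, 1.0, -0.1)])
    with pytest.raises(DegenerateInputError):
        predicted_family_estimate(joint, 1.0)


def test_population_prediction_trivial_cases():
    model = LocusEffectModel(alpha=1.5)
    joint = DiscreteJoint.from_populations([("pop", 1.0, 0.3, 0.0)])
    pred = predicted_population_estimate(joint, model)
    assert pred.slope == pytest.approx(1.5)
    # equal frequencies in the two environments: slope is the average effect
    equal = DiscreteJoint.from_populations(
        [("red", 0.5, 0.5, 0.1), ("blue", 0.5, 0.5, -0.1)]
    )
    assert predicted_population_estimate(equal, LocusEffectModel(alpha=1.0)).slope == pytest.approx(1.0)


def test_population_split_identity_on_random_joints(random_joint):
    """Enumerated slope minus the between-family term equals
    (1-F)/(2(1+F)) times the family prediction, exactly, whenever the two
    generations share F (HWE within cells)."""
    rng = np.random.default_rng(7)
    model = LocusEffectModel(alpha=1.0)
    for _ in range(200):
        joint = random_joint(rng)
        pred = predicted_population_estimate(joint, model)
        assert 0.0 <= pred.inbreeding_F < 1.0
        assert pred.within_term == pytest.approx(pred.within_term_split, abs=1e-12)
        assert pred.consistent


def test_population_split_flags_parental_inbreeding(random_joint):
    """Within-cell parental inbreeding breaks the cross-generation
    stationarity the two-term split assumes; the enumeration flags it."""
    rng = np.random.default_rng(8)
    joint = random_joint(rng, n_cells=2, cell_inbreeding=True)
    pred = predicted_population_estimate(joint, LocusEffectModel(alpha=1.0))
    assert not pred.consistent


# ----------------------------------------------------------------------
# marker locus tagging a causal locus
# ----------------------------------------------------------------------
def test_hap_flip_hand_values():
    model = TwoLocusModel(causal_alpha=1.0)
    perfect = [0.5, 0.0, 0.0, 0.5]  # p(A|M)=1, p(A|m)=0
    assert hap_flip_effect(model, perfect) == pytest.approx(1.0)
    le = [0.25, 0.25, 0.25, 0.25]
    assert hap_flip_effect(model, le) == pytest.approx(0.0)
    # p(A|M)=0.8, p(A|m)=0.3 at p_M=0.5
    freqs = [0.4, 0.1, 0.15, 0.35]
    assert hap_flip_effect(model, freqs) == pytest.approx(0.5)


def test_marker_family_free_recombination_is_null():
    model = TwoLocusModel(recomb_fraction=0.5, causal_alpha=1.0)
    pred = predicted_marker_family_estimate(model, {"pop": [0.4, 0.1, 0.1, 0.4]})
    assert pred["estimate"] == pytest.approx(0.0)


def test_marker_family_single_population_r0_equals_flip():
    model = TwoLocusModel(recomb_fraction=0.0, causal_alpha=1.0)
    freqs = [0.4, 0.1, 0.15, 0.35]
    pred = predicted_marker_family_estimate(model, {"pop": freqs})
    assert pred["estimate"] == pytest.approx(hap_flip_effect(model, freqs), abs=1e-12)
    assert pred["ld_bias"] == pytest.approx(0.0, abs=1e-12)


def test_marker_family_decomposition_identity_at_r0():
    """Family estimate = pooled haplotype-flip effect + LD-heterogeneity
    bias, to machine precision, for random two-population configurations."""
    rng = np.random.default_rng(9)
    model = TwoLocusModel(recomb_fraction=0.0, causal_alpha=1.0)
    for _ in range(300):
        f1 = rng.dirichlet(np.ones(4))
        f2 = rng.dirichlet(np.ones(4))
        w = float(rng.uniform(0.2, 0.8))
        pred = predicted_marker_family_estimate(model, [(w, f1), (1 - w, f2)])
        assert pred["estimate"] == pytest.approx(
            pred["hap_flip"] + pred["ld_bias"], abs=1e-12
        )


# ----------------------------------------------------------------------
# polygenic scores
# ----------------------------------------------------------------------
def test_randomization_effect_values():
    model = PGSModel(p=[0.3, 0.7], alpha=[0.5, -0.2], beta_hat=[0.5, -0.2])
    assert pgs_randomization_effect(model) == pytest.approx(1.0)
    single = PGSModel(p=[0.4], alpha=[0.8], beta_hat=[2.0])
    assert pgs_randomization_effect(single) == pytest.approx(0.4)
    # two loci at p=0.5, weights (1, 2), effects (1, 1)
    two = PGSModel(p=[0.5, 0.5], alpha=[1.0, 1.0], beta_hat=[1.0, 2.0])
    assert pgs_randomization_effect(two) == pytest.approx(0.6)


def test_pgs_family_prediction_reduces_to_randomization():
    model = PGSModel(p=[0.3, 0.6], alpha=[1.0, -0.4], beta_hat=[0.9, -0.5])
    assert predicted_pgs_family_estimate(model, [0.0, 0.0]) == pytest.approx(
        pgs_randomization_effect(model)
    )


def test_single_locus_pgs_prediction_matches_single_locus_late():
    """With one scored locus, the PGS-level prediction is the single-locus
    family prediction divided by the PGS weight."""
    beta = 2.0
    model = PGSModel(
        p=[0.5], alpha=[1.0], beta_hat=[beta],
        population_dev={"red": [0.1], "blue": [-0.1]},
    )
    specs = [
        PopulationSpec("red", 0.5, 0.0, 100),
        PopulationSpec("blue", np.array([0.0]), 0.0, 100),
    ]
    devs = het_conditional_devs(model, specs)
    joint = DiscreteJoint.from_populations(
        [("red", 0.5, 0.5, 0.1), ("blue", 0.5, 0.0, -0.1)]
    )
    assert predicted_pgs_family_estimate(model, devs) == pytest.approx(
        predicted_family_estimate(joint, 1.0) / beta
    )


def test_multiplicative_slopes_weighting():
    model = PGSModel(p=np.full(4, 0.5), alpha=np.ones(4), beta_hat=np.ones(4))
    flat = multiplicative_family_slopes(model, {"a": 0.0, "b": 0.0}, B=1.0)
    assert flat.delta_fam_pred == pytest.approx(1.0)
    assert all(v == pytest.approx(1.0) for v in flat.family_slopes.values())
    # family 1 heterozygous at 3x as many equal-H loci: weights 3:1
    pred = multiplicative_family_slopes(
        model, {"f1": 0.5, "f2": -0.5}, B=1.0,
        family_seg_var={"f1": 3.0, "f2": 1.0},
    )
    assert pred.delta_fam_pred == pytest.approx(1.25)
    assert pred.delta_fam_pred != pytest.approx(
        np.mean(list(pred.family_slopes.values()))
    )


def test_multiplicative_requires_signal():
    model = PGSModel(p=[0.5], alpha=[1.0], beta_hat=[1.0])
    with pytest.raises(ConfigError):
        multiplicative_family_slopes(model, {"a": 0.0}, B=0.0)


def test_het_conditional_devs_analytic_vs_empirical():
    """The analytic het-parent-conditional deviations agree with the
    empirical truth-weighted average from a simulated cohort."""
    from famhet.simulate import simulate_pgs_cohort

    rng = np.random.default_rng(10)
    L = 12
    p_a = rng.uniform(0.2, 0.8, L)
    p_b = rng.uniform(0.2, 0.8, L)
    dev = rng.normal(0, 0.2, L)
    model = PGSModel(
        p=p_a, alpha=np.ones(L) / L, beta_hat=np.ones(L) / L,
        population_dev={"a": dev, "b": -dev},
    )
    specs = [
        PopulationSpec("a", p_a, 0.0, 15_000),
        PopulationSpec("b", p_b, 0.0, 15_000),
    ]
    cohort = simulate_pgs_cohort(model, specs, seed=11)
    analytic = het_conditional_devs(model, specs)
    empirical = theory.het_conditional_devs_empirical(cohort, model)
    assert np.allclose(analytic, empirical, atol=0.02)
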