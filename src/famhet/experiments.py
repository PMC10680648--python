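"""Scripted experiments: the two-population drift illustration, the
simulation-versus-theory verification matrix, and the segregation-averaging
variance manipulation.

The drift illustration draws a sample equally from two populations ("red"
and "blue") occupying different environments: the focal allele adds 1.1
per copy to the trait in the red environment and 0.9 in the blue one
(population-average effect 1). Allele frequencies drift independently in
the two populations, so across replicates the population- and
family-based estimates fan out with F_ST: the population estimate is
pulled toward the environment where the allele drifted to higher
frequency, while the family estimate is pulled toward the environment
with higher heterozygosity (where more parents are 'compliers').
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from . import estimate, theory
from .cohort import TrioCohort
from .errors import DegenerateInputError
from .simulate import (
    LocusEffectModel,
    PGSModel,
    PopulationSpec,
    TwoLocusModel,
    compute_fst,
    pgs_cohort_from_parents,
    simulate_cohort,
    simulate_drift,
    simulate_pgs_cohort,
    simulate_two_locus_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RED_DEV",
    "BLUE_DEV",
    "fig1_effect_model",
    "fig1_specs",
    "run_figure1",
    "verify_all",
    "segregation_averaging",
    "plot_figure1",
]

#: per-allele effect deviations in the two environments (effects 1.1 / 0.9
#: around a population-average effect of 1)
RED_DEV = 0.1
BLUE_DEV = -0.1


def fig1_effect_model(noise_sd: float = 0.5) -> LocusEffectModel:
    """Mean effect 1 with environmental noise; the G×E enters through the
    population offsets, not through extra family/individual deviations."""
    return LocusEffectModel(
        intercept=0.0,
        alpha=1.0,
        sd_env_family=noise_sd,
        sd_env_indiv=noise_sd,
    )


def fig1_specs(p_red: float, p_blue: float, n_families: int) -> list[PopulationSpec]:
    """Equal samples from the red (+0.1) and blue (-0.1) environments;
    ``n_families`` is the count per population."""
    return [
        PopulationSpec("red", p_red, RED_DEV, n_families),
        PopulationSpec("blue", p_blue, BLUE_DEV, n_families),
    ]


# ----------------------------------------------------------------------
def run_figure1(
    replicates: int = 200,
    n_families: int = 50_000,
    p0: float = 0.5,
    pop_size: int = 500,
    generations: int = 50,
    noise_sd: float = 0.5,
    seed=None,
) -> tuple[pd.DataFrame, dict]:
    """Drift followed by paired association studies, one row per replicate.

    Each replicate drifts the allele frequency independently in the two
    populations, simulates ``n_families`` families per population, and runs
    the population and trio estimators. Replicates where the locus is
    monomorphic among children (fixed for the same allele in both
    populations) are skipped with a log entry; the family estimate is NaN
    when no parent is heterozygous.
    """
    model = fig1_effect_model(noise_sd)
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, stream in enumerate(root.spawn(replicates)):
        child = stream.spawn(2)
        rng = np.random.default_rng(child[0])
        p_red, p_blue = simulate_drift(p0, pop_size, generations, rng)
        if p_red in (0.0, 1.0) and p_blue == p_red:
            logger.info("replicate %d: locus fixed in both populations, skipped", rep)
            continue
        cohort = simulate_cohort(fig1_specs(p_red, p_blue, n_families), model,
                                 seed=child[1])
        est_pop = estimate.population_gwas(cohort)
        try:
            est_fam = estimate.family_gwas(cohort)
            fam_slope, fam_se = est_fam.slope, est_fam.stderr
        except DegenerateInputError:
            fam_slope, fam_se = np.nan, np.nan
        rows.append(
            {
                "replicate": rep,
                "fst": compute_fst(p_red, p_blue),
                "p_red": p_red,
                "p_blue": p_blue,
                "est_pop": est_pop.slope,
                "se_pop": est_pop.stderr,
                "est_fam": fam_slope,
                "se_fam": fam_se,
                "higher_freq_pop": "red" if p_red > p_blue else ("blue" if p_blue > p_red else "tie"),
                "higher_het_pop": "red"
                if abs(p_red - 0.5) < abs(p_blue - 0.5)
                else ("blue" if abs(p_blue - 0.5) < abs(p_red - 0.5) else "tie"),
            }
        )
    df = pd.DataFrame(rows)
    return df, summarize_figure1(df)


def summarize_figure1(df: pd.DataFrame) -> dict:
    """Headline statistics of a drift-experiment table."""
    low = df[df["fst"] < 0.01]
    high = df[df["fst"] > 0.05]
    summary = {
        "n_replicates": int(len(df)),
        "n_low_fst": int(len(low)),
        "mean_est_pop_low_fst": float(low["est_pop"].mean()) if len(low) else np.nan,
        "se_mean_est_pop_low_fst": float(
            np.sqrt((low["se_pop"] ** 2).sum()) / len(low)
        )
        if len(low)
        else np.nan,
    }
    if len(high):
        pop_sign = np.sign(high["est_pop"] - 1.0)
        freq_sign = np.sign(high["p_red"] - high["p_blue"])
        summary["n_high_fst"] = int(len(high))
        summary["pop_sign_concordance_high_fst"] = float(
            np.mean(pop_sign == freq_sign)
        )
    fam = df.dropna(subset=["est_fam"])
    fam = fam[fam["higher_het_pop"] != "tie"]
    if len(fam):
        fam_sign = np.sign(fam["est_fam"] - 1.0)
        het_sign = np.where(fam["higher_het_pop"] == "red", 1.0, -1.0)
        summary["fam_sign_concordance"] = float(np.mean(fam_sign == het_sign))
        # restrict to replicates whose predicted deviation
        # |E[alpha_f | het parent]| clears the Monte Carlo noise
        h_red = 2 * fam["p_red"] * (1 - fam["p_red"])
        h_blue = 2 * fam["p_blue"] * (1 - fam["p_blue"])
        pred_dev = RED_DEV * (h_red - h_blue) / (h_red + h_blue)
        informative = np.abs(pred_dev) > 2.0 * fam["se_fam"]
        if informative.any():
            summary["n_fam_informative"] = int(informative.sum())
            summary["fam_sign_concordance_informative"] = float(
                np.mean(fam_sign[informative] == het_sign[informative])
            )
    both = df.dropna(subset=["est_fam"])
    both = both[(both["fst"] > 0.05) & (both["higher_het_pop"] != "tie")]
    if len(both):
        diff = both["est_fam"] - both["est_pop"]
        summary["mean_abs_fam_pop_gap_high_fst"] = float(diff.abs().mean())
        summary["se_abs_fam_pop_gap_high_fst"] = float(
            diff.abs().std(ddof=1) / np.sqrt(len(both))
        )
    return summary


def plot_figure1(df: pd.DataFrame, path) -> None:
    """Optional scatter rendering (estimates against F_ST); the numeric
    table is the artifact of record."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4), sharex=True)
    colors = np.where(df["higher_freq_pop"] == "red", "tab:red", "tab:blue")
    axes[0].scatter(df["fst"], df["est_pop"], c=colors, s=12)
    axes[0].axhline(1.0, color="k", lw=0.8)
    axes[0].set_ylabel("population estimate")
    het_colors = np.where(df["higher_het_pop"] == "red", "tab:red", "tab:blue")
    axes[1].scatter(df["fst"], df["est_fam"], c=het_colors, s=12)
    axes[1].axhline(1.0, color="k", lw=0.8)
    axes[1].set_ylabel("family estimate")
    axes[2].scatter(df["fst"], df["est_fam"] - df["est_pop"], c=het_colors, s=12)
    axes[2].axhline(0.0, color="k", lw=0.8)
    axes[2].set_ylabel("family - population")
    for ax in axes:
        ax.set_xlabel("F_ST")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ----------------------------------------------------------------------
# verification matrix
# ----------------------------------------------------------------------
def _row(config, quantity, theory_value, est, se, tolerance_sigma):
    z = (est - theory_value) / se if se > 0 else np.inf
    return {
        "config": config,
        "quantity": quantity,
        "theory": theory_value,
        "estimate": est,
        "mc_se": se,
        "z": z,
        "passed": bool(abs(z) <= tolerance_sigma),
    }


def _ratio_se(num: np.ndarray, den: np.ndarray) -> float:
    """Delta-method SE of Var(num)/Var(den) over i.i.d. children."""
    r = np.var(num) / np.var(den)
    d = (num - num.mean()) ** 2 - r * (den - den.mean()) ** 2
    return float(np.std(d, ddof=1) / (np.var(den) * np.sqrt(len(num))))


def designed_multiplicative_cohort(
    n_families_per_class: int = 15_000,
    n_loci_class1: int = 30,
    n_loci_class2: int = 10,
    C: tuple[float, float] = (0.5, -0.5),
    noise_sd: float = 0.2,
    seed=None,
) -> tuple[TrioCohort, PGSModel, theory.PGSTheory]:
    """Two family classes with designed parental heterozygosity patterns.

    Class ``hi`` parents are heterozygous at the first block of loci
    (``n_loci_class1`` of them) and homozygous elsewhere; class ``lo``
    parents are heterozygous only at the complementary block. All loci have
    unit effects and unit PGS weights (B = 1), and class G×E multipliers
    ``C``; the within-family slope therefore targets the
    segregation-variance-weighted average of (1 + C_f), not the unweighted
    one.
    """
    rng = np.random.default_rng(seed)
    L = n_loci_class1 + n_loci_class2
    n = n_families_per_class
    model = PGSModel(
        p=np.full(L, 0.5),
        alpha=np.ones(L),
        beta_hat=np.ones(L),
        multiplicative_C={"hi": C[0], "lo": C[1]},
        sd_env_indiv=noise_sd,
    )

    def parents(het_block: slice) -> tuple[np.ndarray, np.ndarray]:
        gm = rng.choice([0, 2], size=(n, L)).astype(np.int8)
        gf = rng.choice([0, 2], size=(n, L)).astype(np.int8)
        gm[:, het_block] = 1
        gf[:, het_block] = 1
        return gm, gf

    gm1, gf1 = parents(slice(0, n_loci_class1))
    gm2, gf2 = parents(slice(n_loci_class1, L))
    cohort = pgs_cohort_from_parents(
        model,
        np.vstack([gm1, gm2]),
        np.vstack([gf1, gf2]),
        ["hi"] * n + ["lo"] * n,
        seed=rng,
    )
    seg_var = {
        "hi": float(n_loci_class1 * 0.5),  # sum over het loci of (1+1)/4
        "lo": float(n_loci_class2 * 0.5),
    }
    pred = theory.multiplicative_family_slopes(
        model, {"hi": C[0], "lo": C[1]}, B=1.0, family_seg_var=seg_var
    )
    return cohort, model, pred


def verify_all(
    n_families: int = 50_000,
    tolerance_sigma: float = 3.0,
    seed=None,
    checks: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run the simulation-versus-theory verification matrix.

    Each row compares one estimator on one simulated configuration with its
    closed-form/enumeration prediction, reporting the Monte Carlo z-score
    and a pass flag at ``tolerance_sigma``. The configuration bank spans:
    no G×E, two-environment G×E (with and without allele-frequency
    differentiation), population structure with Wahlund inbreeding, LD
    heterogeneity at a tagging marker, and homogeneous / heterogeneous /
    multiplicative polygenic scores.
    """
    root = np.random.SeedSequence(seed)
    streams = iter(root.spawn(32))
    rows: list[dict] = []

    def want(name: str) -> bool:
        return checks is None or name in checks

    n_half = n_families // 2

    # -- single locus, no G×E ------------------------------------------
    if want("no_gxe"):
        model = LocusEffectModel(alpha=1.0, sd_env_family=0.5, sd_env_indiv=0.5)
        specs = [PopulationSpec("pop", 0.3, 0.0, n_families)]
        cohort = simulate_cohort(specs, model, seed=next(streams))
        joint = theory.DiscreteJoint.from_populations([("pop", 1.0, 0.3, 0.0)])
        pred = theory.predicted_population_estimate(joint, model)
        est = estimate.population_gwas(cohort)
        rows.append(_row("no_gxe", "population_slope", pred.slope, est.slope,
                         est.stderr, tolerance_sigma))
        fam = estimate.family_gwas(cohort)
        rows.append(_row("no_gxe", "family_slope",
                         theory.predicted_family_estimate(joint, model.alpha),
                         fam.slope, fam.stderr, tolerance_sigma))
        sib_cohort = simulate_cohort(specs, model, children_per_family=2,
                                     seed=next(streams))
        sib = estimate.sib_difference(sib_cohort)
        rows.append(_row("no_gxe", "sib_slope",
                         theory.predicted_family_estimate(joint, model.alpha),
                         sib.slope, sib.stderr, tolerance_sigma))

    # -- two environments, effects 1.1 / 0.9 ----------------------------
    if want("fig1"):
        model = fig1_effect_model()
        # equal frequencies: no differentiation, population slope is 1
        cohort = simulate_cohort(fig1_specs(0.5, 0.5, n_half), model,
                                 seed=next(streams))
        joint = theory.DiscreteJoint.from_populations(
            [("red", 0.5, 0.5, RED_DEV), ("blue", 0.5, 0.5, BLUE_DEV)]
        )
        pred = theory.predicted_population_estimate(joint, model)
        est = estimate.population_gwas(cohort)
        rows.append(_row("fig1_fst0", "population_slope", pred.slope, est.slope,
                         est.stderr, tolerance_sigma))
        # heterozygosity confined to the red environment
        cohort = simulate_cohort(fig1_specs(0.5, 0.0, n_half), model,
                                 seed=next(streams))
        joint = theory.DiscreteJoint.from_populations(
            [("red", 0.5, 0.5, RED_DEV), ("blue", 0.5, 0.0, BLUE_DEV)]
        )
        fam = estimate.family_gwas(cohort)
        rows.append(_row("fig1_red_het", "family_slope",
                         theory.predicted_family_estimate(joint, model.alpha),
                         fam.slope, fam.stderr, tolerance_sigma))
        pop = estimate.population_gwas(cohort)
        pred = theory.predicted_population_estimate(joint, model)
        rows.append(_row("fig1_red_het", "population_slope", pred.slope,
                         pop.slope, pop.stderr, tolerance_sigma))

    # -- population structure, Wahlund F = 0.2 --------------------------
    if want("structure"):
        model = fig1_effect_model()
        d = np.sqrt(0.05)
        p_hi, p_lo = 0.5 + d, 0.5 - d
        cohort = simulate_cohort(fig1_specs(p_hi, p_lo, n_half), model,
                                 seed=next(streams))
        joint = theory.DiscreteJoint.from_populations(
            [("red", 0.5, p_hi, RED_DEV), ("blue", 0.5, p_lo, BLUE_DEV)]
        )
        pred = theory.predicted_population_estimate(joint, model)
        est = estimate.population_gwas(cohort)
        rows.append(_row("structure_F0.2", "population_slope", pred.slope,
                         est.slope, est.stderr, tolerance_sigma))
        fam = estimate.family_gwas(cohort)
        # within-family share of the population slope: the two-term split
        g = cohort.g_child[:, 0].astype(float)
        mid = (cohort.g_mother[:, 0] + cohort.g_father[:, 0]) / 2.0
        between = float(np.cov(cohort.phenotype, mid, ddof=0)[0, 1] / np.var(g))
        F = pred.inbreeding_F
        split = (1 - F) / (2 * (1 + F)) * fam.slope
        se = float(np.hypot(est.stderr, (1 - F) / (2 * (1 + F)) * fam.stderr))
        rows.append(_row("structure_F0.2", "pop_minus_between_vs_split",
                         split, est.slope - between, se, tolerance_sigma))

    # -- marker tagging a causal locus, LD heterogeneity ----------------
    if want("two_locus"):
        # one homogeneous population first: population slope matches the
        # haplotype-flip effect in the offspring gamete pool
        freqs_a = np.array([0.4, 0.1, 0.1, 0.4])  # strong positive LD
        tl = TwoLocusModel(hap_freqs={"pop": freqs_a}, recomb_fraction=0.1,
                           causal_alpha=1.0, sd_env_indiv=0.5)
        cohort = simulate_two_locus_cohort(
            tl, [PopulationSpec("pop", None, 0.0, n_families)], seed=next(streams)
        )
        pred1 = theory.predicted_marker_family_estimate(
            tl, {"pop": freqs_a}, approx_offspring=True
        )
        est = estimate.population_gwas(cohort, locus="marker")
        # offspring gamete-pool flip effect
        p_M, p_A = freqs_a[0] + freqs_a[1], freqs_a[0] + freqs_a[2]
        r = tl.recomb_fraction
        gamete = (1 - r) * freqs_a + r * np.array(
            [p_M * p_A, p_M * (1 - p_A), (1 - p_M) * p_A, (1 - p_M) * (1 - p_A)]
        )
        rows.append(_row("two_locus_single_pop", "population_slope",
                         theory.hap_flip_effect(tl, gamete), est.slope,
                         est.stderr, tolerance_sigma))
        fam = estimate.family_gwas(cohort, locus="marker")
        pred = theory.predicted_marker_family_estimate(tl, {"pop": freqs_a})
        rows.append(_row("two_locus_single_pop", "family_slope",
                         pred["estimate"], fam.slope, fam.stderr, tolerance_sigma))
        # two populations with different LD and marker frequencies
        freqs_b = np.array([0.08, 0.12, 0.48, 0.32])
        tl2 = TwoLocusModel(hap_freqs={"popA": freqs_a, "popB": freqs_b},
                            recomb_fraction=0.1, causal_alpha=1.0, sd_env_indiv=0.5)
        cohort = simulate_two_locus_cohort(
            tl2,
            [PopulationSpec("popA", None, 0.0, n_half),
             PopulationSpec("popB", None, 0.0, n_half)],
            seed=next(streams),
        )
        fam = estimate.family_gwas(cohort, locus="marker")
        pred = theory.predicted_marker_family_estimate(
            tl2, {"popA": freqs_a, "popB": freqs_b}
        )
        rows.append(_row("two_locus_ld_heterogeneity", "family_slope",
                         pred["estimate"], fam.slope, fam.stderr, tolerance_sigma))

    # -- polygenic scores ----------------------------------------------
    n_pgs = max(n_families // 2, 2_000)
    if want("pgs_homogeneous"):
        L = 50
        p = np.linspace(0.15, 0.85, L)
        alpha = np.where(np.arange(L) % 2 == 0, 1.0, -0.6) / np.sqrt(L)
        model = PGSModel(p=p, alpha=alpha, beta_hat=alpha,
                         sd_env_family=0.5, sd_env_indiv=0.5)
        cohort = simulate_pgs_cohort(
            model, [PopulationSpec("pop", None, 0.0, n_pgs)], seed=next(streams)
        )
        fam = estimate.family_pgs(cohort, model)
        rows.append(_row("pgs_homogeneous", "family_pgs_slope",
                         theory.pgs_randomization_effect(model),
                         fam.slope, fam.stderr, tolerance_sigma))
        pop = estimate.population_pgs(cohort, model)
        rows.append(_row("pgs_homogeneous", "population_pgs_slope",
                         theory.pgs_randomization_effect(model),
                         pop.slope, pop.stderr, tolerance_sigma))
        child, mother, father = cohort.pgs(model.beta_hat, model.pgs_loci)
        seg = child - (mother + father) / 2.0
        rows.append(_row("pgs_homogeneous", "v_seg_over_v_pgs", 0.5,
                         float(np.var(seg) / np.var(child)),
                         _ratio_se(seg, child), tolerance_sigma))

    if want("pgs_heterogeneous"):
        L = 40
        rng = np.random.default_rng(next(streams))
        p_a = np.clip(rng.uniform(0.1, 0.9, L), 0.05, 0.95)
        p_b = np.clip(p_a + rng.uniform(-0.25, 0.25, L), 0.05, 0.95)
        alpha = rng.normal(0.0, 1.0, L) / np.sqrt(L)
        dev = rng.normal(0.0, 0.4, L) * np.abs(alpha)
        model = PGSModel(
            p=p_a, alpha=alpha, beta_hat=alpha,
            population_dev={"envA": dev, "envB": -dev},
            sd_env_family=0.3, sd_env_indiv=0.3,
        )
        specs = [
            PopulationSpec("envA", p_a, 0.0, n_pgs // 2),
            PopulationSpec("envB", p_b, 0.0, n_pgs // 2),
        ]
        cohort = simulate_pgs_cohort(model, specs, seed=next(streams))
        fam = estimate.family_pgs(cohort, model)
        devs = theory.het_conditional_devs(model, specs)
        rows.append(_row("pgs_heterogeneous", "family_pgs_slope",
                         theory.predicted_pgs_family_estimate(model, devs),
                         fam.slope, fam.stderr, tolerance_sigma))
        pop = estimate.population_pgs(cohort, model)
        rows.append(_row("pgs_heterogeneous", "population_pgs_two_term_sum",
                         pop.extras["between_term"] + pop.extras["within_term"],
                         pop.slope, pop.stderr, tolerance_sigma))

    if want("pgs_multiplicative"):
        # the designed contrast needs enough families for the weighted and
        # unweighted averages (0.25 apart) to separate decisively
        cohort, model, pred = designed_multiplicative_cohort(
            n_families_per_class=max(n_pgs // 2, 15_000), seed=next(streams)
        )
        fam = estimate.family_pgs(cohort, model)
        rows.append(_row("pgs_multiplicative", "family_pgs_slope_weighted",
                         pred.delta_fam_pred, fam.slope, fam.stderr,
                         tolerance_sigma))
        unweighted = float(np.mean(list(pred.family_slopes.values())))
        rows.append({
            "config": "pgs_multiplicative",
            "quantity": "weighted_vs_unweighted_separation",
            "theory": pred.delta_fam_pred,
            "estimate": fam.slope,
            "mc_se": fam.stderr,
            "z": (fam.slope - unweighted) / fam.stderr,
            "passed": bool(abs(fam.slope - unweighted) > tolerance_sigma * fam.stderr),
        })

    if want("segregation_averaging"):
        L = 50
        p = np.linspace(0.2, 0.8, L)
        alpha = np.full(L, 1.0 / np.sqrt(L))
        model = PGSModel(p=p, alpha=alpha, beta_hat=alpha,
                         sd_env_family=0.5, sd_env_indiv=0.5)
        cohort = simulate_pgs_cohort(
            model, [PopulationSpec("pop", None, 0.0, n_pgs)], seed=next(streams)
        )
        report = segregation_averaging(cohort, model)
        rows.append(_row("segregation_averaging", "variance_reduction",
                         report["predicted_reduction"], report["reduction"],
                         report["reduction_se"], tolerance_sigma))

    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def segregation_averaging(cohort: TrioCohort, pgs: PGSModel) -> dict:
    """Replace each child's phenotype by its conditional mean over Mendelian
    segregation at the scored loci (parents, environment and all other
    genotype contributions held fixed) and report the variance reduction.

    The reduction is predicted by delta_fam^2 * V_seg; the prediction is an
    identity in the homogeneous regime (PGS weights equal to the causal
    effects, no G×E, no individual-level deviations). Under heterogeneous
    effects the exact expected reduction is the truth-based
    ``reduction_truth`` (per-family slopes weight their own segregation
    variances), which can exceed the delta_fam^2 * V_seg prediction.
    """
    if cohort.locus_dev_child is None:
        raise DegenerateInputError(
            "segregation averaging requires simulation truth (per-locus "
            "realized effect deviations)"
        )
    y = cohort.phenotype
    v_p = float(np.var(y))
    idx = pgs.pgs_loci
    if idx.size == 0:
        return {
            "v_pheno": v_p, "v_pheno_after": v_p, "reduction": 0.0,
            "predicted_reduction": 0.0, "reduction_truth": 0.0,
            "reduction_se": 0.0, "v_seg": 0.0, "delta_fam": np.nan,
        }
    effects = pgs.alpha[idx][None, :] + cohort.locus_dev_child[:, idx]
    seg_contrib = np.einsum("il,il->i", effects, cohort.seg_dev[:, idx])
    y_after = y - seg_contrib
    v_after = float(np.var(y_after))

    fam = estimate.family_pgs(cohort, pgs)
    child, mother, father = cohort.pgs(pgs.beta_hat, idx)
    seg = child - (mother + father) / 2.0
    v_seg = float(np.var(seg))
    predicted = fam.slope**2 * v_seg
    reduction = v_p - v_after
    # per-child delta-method SE of (V_P - V_P_after) - delta^2 V_seg
    d = (
        (y - y.mean()) ** 2
        - (y_after - y_after.mean()) ** 2
        - fam.slope**2 * (seg - seg.mean()) ** 2
    )
    se = float(np.std(d, ddof=1) / np.sqrt(len(d)))
    return {
        "v_pheno": v_p,
        "v_pheno_after": v_after,
        "reduction": reduction,
        "predicted_reduction": predicted,
        "reduction_truth": float(np.var(seg_contrib)),
        "reduction_se": se,
        "v_seg": v_seg,
        "delta_fam": fam.slope,
    }
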