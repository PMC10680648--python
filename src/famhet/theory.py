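"""Closed-form and exact-enumeration predictions for the estimators.

Every estimator in :mod:`famhet.estimate` has a noise-free counterpart
here, computed either in closed form or by exact enumeration over
(parental mating type, environment, segregation outcome) with rational
segregation weights. These predictions double as the verification
oracles for the simulator: a simulated estimate must agree with its
prediction within Monte Carlo error.

Key quantities, for a biallelic locus with focal allele A2 at parental
frequency p and mean effect alpha:

* allele-flip effects: the expected phenotype change from flipping the
  allele carried by a randomly chosen parental gamete (A1->A2 or
  A2->A1). These depend on the environments in which each allele is
  found. Their allele-frequency-weighted average is exactly alpha.
* trio prediction: alpha + E[alpha_f | parent heterozygous] -- a local
  average treatment effect in the children of heterozygous parents.
* population prediction: Cov(Y, g)/Var(g) by enumeration, which splits
  into a between-family covariance term and a within-family
  (segregation) term equal to (1-F)/(2(1+F)) times the trio prediction.
* two-locus marker predictions for a genotyped marker tagging an
  ungenotyped causal locus, under population-specific LD.
* polygenic-score slopes under randomization and under within-family
  estimation, with heterozygosity-weighted per-locus contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, DegenerateInputError
from .simulate import LocusEffectModel, PGSModel, PopulationSpec, TwoLocusModel

__all__ = [
    "DiscreteJoint",
    "FlipEffects",
    "PopulationPrediction",
    "PGSTheory",
    "flip_effects",
    "predicted_family_estimate",
    "predicted_population_estimate",
    "hap_flip_effect",
    "predicted_marker_family_estimate",
    "pgs_randomization_effect",
    "predicted_pgs_family_estimate",
    "het_conditional_devs",
    "het_conditional_devs_empirical",
    "multiplicative_family_slopes",
]

_TRANSMIT = {
    # P(gamete carries focal allele | parent genotype)
    0: 0.0,
    1: 0.5,
    2: 1.0,
}


@dataclass
class DiscreteJoint:
    """Exact joint distribution of (parental genotype, environment).

    Each cell is one environment (population) with a family weight, its
    parental genotype frequencies (P(g=0), P(g=1), P(g=2)) and the
    alpha_f value shared by families in that environment. Mothers and
    fathers are i.i.d. within a cell. Family weights must make alpha_f
    mean zero, matching the generative model's convention.
    """

    labels: list[str]
    weights: np.ndarray
    geno_freqs: np.ndarray  # (n_cells, 3)
    alpha_f: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.geno_freqs = np.asarray(self.geno_freqs, dtype=float)
        self.alpha_f = np.asarray(self.alpha_f, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ConfigError("cell weights must sum to 1")
        if np.any(self.geno_freqs < -1e-12) or not np.allclose(
            self.geno_freqs.sum(axis=1), 1.0
        ):
            raise ConfigError("each cell's genotype frequencies must sum to 1")
        if abs(float(self.weights @ self.alpha_f)) > 1e-8:
            raise ConfigError(
                "alpha_f must be mean zero under the family weights "
                f"(got {float(self.weights @ self.alpha_f)})"
            )

    @classmethod
    def from_populations(
        cls, cells: Sequence[tuple[str, float, float, float] | tuple[str, float, float, float, float]]
    ) -> "DiscreteJoint":
        """Build from (label, weight, allele_freq, alpha_f[, inbreeding_F])
        tuples; parental genotypes are HWE within each cell, deformed by F
        when given."""
        labels, weights, freqs, devs = [], [], [], []
        for cell in cells:
            label, w, p, a, *rest = cell
            F = rest[0] if rest else 0.0
            q = 1.0 - p
            labels.append(label)
            weights.append(w)
            freqs.append([q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q])
            devs.append(a)
        return cls(labels, np.asarray(weights), np.asarray(freqs), np.asarray(devs))

    # pooled parental quantities -------------------------------------
    @property
    def genotype_freqs(self) -> np.ndarray:
        return self.weights @ self.geno_freqs

    @property
    def p(self) -> float:
        p11, p12, p22 = self.genotype_freqs
        return float(p12 / 2.0 + p22)

    @property
    def inbreeding_F(self) -> float:
        """Pooled parental inbreeding coefficient F = 1 - p12 / (2 p q);
        population structure contributes through the Wahlund effect."""
        p = self.p
        if p in (0.0, 1.0):
            return 0.0
        return float(1.0 - self.genotype_freqs[1] / (2.0 * p * (1.0 - p)))

    def e_alpha_f_given(self, genotype: int) -> float:
        """E[alpha_f | a random parent has the given genotype]."""
        cell_probs = self.weights * self.geno_freqs[:, genotype]
        total = cell_probs.sum()
        if total == 0:
            raise DegenerateInputError(
                f"no parents with genotype {genotype} exist under this joint"
            )
        return float(cell_probs @ self.alpha_f / total)


@dataclass
class FlipEffects:
    """Counterfactual allele-flip effects at a single locus."""

    flip_1to2: float
    flip_2to1: float
    averaged: float
    hap_flip: float | None = None


@dataclass
class PopulationPrediction:
    """Exact-enumeration population slope and its two-term split."""

    slope: float
    between_term: float
    within_term: float  # exact: Cov(Y, sigma) / Var(g)
    within_term_split: float  # (1-F)/(2(1+F)) * family prediction
    family_estimate: float
    inbreeding_F: float
    consistent: bool  # enumeration agrees with the two-term split


@dataclass
class PGSTheory:
    """Family-specific PGS slopes under the multiplicative G×E model."""

    delta_rand: float
    delta_fam_pred: float
    family_slopes: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)
    B: float = 1.0


# ----------------------------------------------------------------------
# single locus
# ----------------------------------------------------------------------
def flip_effects(joint: DiscreteJoint, alpha: float) -> FlipEffects:
    """Expected phenotype changes from flipping the allele carried by a
    randomly chosen parental gamete, in each direction, and their
    allele-frequency-weighted average (which equals alpha exactly)."""
    p = joint.p
    if p in (0.0, 1.0):
        raise DegenerateInputError("allele flips are undefined at a fixed locus")
    p11, p12, p22 = joint.genotype_freqs
    q = 1.0 - p
    flip_12 = alpha
    if p11 > 0:
        flip_12 += p11 / q * joint.e_alpha_f_given(0)
    if p12 > 0:
        flip_12 += p12 / (2 * q) * joint.e_alpha_f_given(1)
    flip_21 = -alpha
    if p22 > 0:
        flip_21 -= p22 / p * joint.e_alpha_f_given(2)
    if p12 > 0:
        flip_21 -= p12 / (2 * p) * joint.e_alpha_f_given(1)
    averaged = q * flip_12 + p * (-flip_21)
    return FlipEffects(flip_1to2=flip_12, flip_2to1=flip_21, averaged=averaged)


def predicted_family_estimate(joint: DiscreteJoint, alpha: float) -> float:
    """Expected trio (and sibling) slope: alpha + E[alpha_f | heterozygous
    parent] -- the LATE in children of heterozygous parents."""
    if joint.genotype_freqs[1] <= 0:
        raise DegenerateInputError(
            "no heterozygous parents under this joint; the within-family "
            "design has no compliers"
        )
    return alpha + joint.e_alpha_f_given(1)


def predicted_population_estimate(
    joint: DiscreteJoint, model: LocusEffectModel
) -> PopulationPrediction:
    """Expected population slope Cov(Y, g)/Var(g) by exact enumeration over
    (mating type, environment, segregation outcome).

    The slope splits into a between-family covariance term and a
    within-family term; the latter equals (1-F)/(2(1+F)) times the trio
    prediction when the inbreeding coefficient F and allele frequency are
    shared across the parental and offspring generations (HWE within each
    cell). Cells with parental inbreeding break that stationarity, in
    which case ``consistent`` is False and the exact ``within_term``
    should be trusted over ``within_term_split``.
    """
    alpha = model.alpha
    # accumulate exact moments over cells x mating types x segregation outcomes
    s1 = s2 = sm1 = a1 = a2 = a3 = 0.0
    for w, freqs, dev in zip(joint.weights, joint.geno_freqs, joint.alpha_f):
        eff = alpha + dev
        for gm in range(3):
            for gf in range(3):
                prob_mating = w * freqs[gm] * freqs[gf]
                if prob_mating == 0.0:
                    continue
                mid = (gm + gf) / 2.0
                tm, tf = _TRANSMIT[gm], _TRANSMIT[gf]
                # child genotype = Bernoulli(tm) + Bernoulli(tf)
                for cm in (0, 1):
                    for cf in (0, 1):
                        pm = tm if cm else 1 - tm
                        pf = tf if cf else 1 - tf
                        prob = prob_mating * pm * pf
                        if prob == 0.0:
                            continue
                        g = cm + cf
                        s1 += prob * g
                        s2 += prob * g * g
                        sm1 += prob * mid
                        a1 += prob * eff * g
                        a2 += prob * eff * g * g
                        a3 += prob * eff * g * mid
    var_g = s2 - s1 * s1
    if var_g <= 0:
        raise DegenerateInputError("Var(g) = 0 under this joint")
    cov_yg = a2 - a1 * s1
    cov_ym = a3 - a1 * sm1
    slope = cov_yg / var_g
    between = cov_ym / var_g
    within_exact = slope - between
    F = joint.inbreeding_F
    fam = predicted_family_estimate(joint, alpha)
    within_split = (1.0 - F) / (2.0 * (1.0 + F)) * fam
    return PopulationPrediction(
        slope=slope,
        between_term=between,
        within_term=within_exact,
        within_term_split=within_split,
        family_estimate=fam,
        inbreeding_F=F,
        consistent=bool(abs(within_exact - within_split) < 1e-9 * max(1.0, abs(fam))),
    )


# ----------------------------------------------------------------------
# two loci
# ----------------------------------------------------------------------
def _hap_conditionals(freqs: np.ndarray) -> tuple[float, float, float, float]:
    """(p_M, p_m, p_{A|M}, p_{A|m}) from (MA, Ma, mA, ma) frequencies."""
    f_ma_, f_mb, f_am, f_ab = freqs  # MA, Ma, mA, ma
    p_M = f_ma_ + f_mb
    p_m = f_am + f_ab
    pa_M = f_ma_ / p_M if p_M > 0 else np.nan
    pa_m = f_am / p_m if p_m > 0 else np.nan
    return p_M, p_m, pa_M, pa_m


def hap_flip_effect(model: TwoLocusModel, pooled_hap_freqs) -> float:
    """Expected effect of flipping the haplotype around the marker in a
    randomly chosen gamete, assuming the flipped segment spans the causal
    locus: (p_{A|M} - p_{A|m}) * alpha."""
    freqs = np.asarray(pooled_hap_freqs, dtype=float)
    p_M, p_m, pa_M, pa_m = _hap_conditionals(freqs)
    if p_M in (0.0, 1.0):
        raise DegenerateInputError("marker is monomorphic; haplotype flip undefined")
    return (pa_M - pa_m) * model.causal_alpha


def predicted_marker_family_estimate(
    model: TwoLocusModel,
    parental_hap_freqs: Mapping[str, Sequence[float]] | Sequence[tuple[float, Sequence[float]]],
    weights: Sequence[float] | None = None,
    approx_offspring: bool = False,
) -> dict:
    """Expected trio slope at the marker locus.

    The exact form is (1 - 2r) * (p'_{A|M,Mm} - p'_{A|m,Mm}) * alpha, with
    the haplotype conditionals taken among *heterozygous parents* in the
    parental generation. ``parental_hap_freqs`` maps population label ->
    (MA, Ma, mA, ma) frequencies (with ``weights`` per population, equal by
    default), or is a sequence of (weight, freqs) pairs.

    With ``approx_offspring=True`` the heterozygote-conditional proportions
    are instead computed among offspring, reproducing the approximation
    valid for tight linkage and stationary genotype frequencies.

    Returns a dict with the estimate, the pooled haplotype-flip effect and
    the LD-heterogeneity bias term; at r=0, estimate = flip + bias exactly.
    """
    if isinstance(parental_hap_freqs, Mapping):
        items = list(parental_hap_freqs.values())
        w = np.ones(len(items)) if weights is None else np.asarray(weights, float)
    else:
        w = np.array([x[0] for x in parental_hap_freqs], dtype=float)
        items = [x[1] for x in parental_hap_freqs]
    w = w / w.sum()
    freqs = np.asarray(items, dtype=float)  # (n_pops, 4)
    r = model.recomb_fraction
    alpha = model.causal_alpha

    if approx_offspring:
        # gamete-pool haplotype frequencies after one round of recombination
        out = np.empty_like(freqs)
        for k, f in enumerate(freqs):
            p_M = f[0] + f[1]
            p_A = f[0] + f[2]
            out[k] = (1 - r) * f + r * np.array(
                [p_M * p_A, p_M * (1 - p_A), (1 - p_M) * p_A, (1 - p_M) * (1 - p_A)]
            )
        cond_freqs = out
        linkage_factor = 1.0
    else:
        cond_freqs = freqs
        linkage_factor = 1.0 - 2.0 * r

    # weight populations by their share of Mm heterozygous parents
    p_M_k = cond_freqs[:, 0] + cond_freqs[:, 1]
    p_m_k = cond_freqs[:, 2] + cond_freqs[:, 3]
    het_w = w * p_M_k * p_m_k
    if het_w.sum() <= 0:
        raise DegenerateInputError("no Mm heterozygous parents in any population")
    het_w = het_w / het_w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        pa_M_k = np.where(p_M_k > 0, cond_freqs[:, 0] / p_M_k, 0.0)
        pa_m_k = np.where(p_m_k > 0, cond_freqs[:, 2] / p_m_k, 0.0)
    pa_M_het = float(het_w @ pa_M_k)
    pa_m_het = float(het_w @ pa_m_k)
    estimate = linkage_factor * (pa_M_het - pa_m_het) * alpha

    pooled = w @ freqs
    flip = hap_flip_effect(model, pooled)
    _, _, pa_M, pa_m = _hap_conditionals(np.asarray(pooled))
    bias = ((pa_M_het - pa_M) - (pa_m_het - pa_m)) * alpha
    return {
        "estimate": estimate,
        "hap_flip": flip,
        "ld_bias": bias,
        "pa_M_het": pa_M_het,
        "pa_m_het": pa_m_het,
    }


# ----------------------------------------------------------------------
# polygenic scores
# ----------------------------------------------------------------------
def _pgs_weights(pgs: PGSModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = pgs.pgs_loci
    H = pgs.heterozygosity[idx]
    beta = pgs.beta_hat
    denom = float(np.sum(H * beta**2))
    if denom <= 0:
        raise DegenerateInputError("the PGS has zero genic variance")
    return idx, H, beta


def pgs_randomization_effect(pgs: PGSModel) -> float:
    """Expected PGS slope when genotypes at the scored loci are randomly
    reassigned across environments:
    sum_l H_l beta_l alpha_l / sum_l H_l beta_l^2."""
    idx, H, beta = _pgs_weights(pgs)
    return float(np.sum(H * beta * pgs.alpha[idx]) / np.sum(H * beta**2))


def predicted_pgs_family_estimate(pgs: PGSModel, het_conditional_devs) -> float:
    """Expected within-family PGS slope:
    sum_l H_l beta_l (alpha_l + E[alpha_lf | het parent at l]) /
    sum_l H_l beta_l^2, over the scored loci."""
    idx, H, beta = _pgs_weights(pgs)
    devs = np.asarray(het_conditional_devs, dtype=float)
    if devs.shape == (pgs.n_loci,):
        devs = devs[idx]
    if devs.shape != idx.shape:
        raise ConfigError("one het-conditional deviation per scored locus is required")
    return float(np.sum(H * beta * (pgs.alpha[idx] + devs)) / np.sum(H * beta**2))


def het_conditional_devs(
    pgs: PGSModel, specs: Sequence[PopulationSpec]
) -> np.ndarray:
    """Analytic E[alpha_lf | a parent is heterozygous at l] per causal
    locus, for a cohort drawn from the given populations: populations are
    weighted by family count times their heterozygosity at l."""
    weights = np.array([s.n_families for s in specs], dtype=float)
    devs = np.stack([pgs.family_dev(s.label) for s in specs])  # (K, L)
    het = np.stack(
        [2.0 * pgs.freqs_for(s) * (1.0 - pgs.freqs_for(s)) for s in specs]
    )  # (K, L)
    num = (weights[:, None] * het * devs).sum(axis=0)
    den = (weights[:, None] * het).sum(axis=0)
    out = np.zeros(pgs.n_loci)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def het_conditional_devs_empirical(cohort, pgs: PGSModel) -> np.ndarray:
    """Empirical E[alpha_lf | het parent at l] from simulation truth: the
    realized per-child locus deviations averaged with weight equal to the
    number of heterozygous parents. Individual-level deviations average
    out because they are independent of parental heterozygosity."""
    if cohort.locus_dev_child is None:
        raise DegenerateInputError("cohort carries no simulation truth")
    het_count = (cohort.g_mother == 1).astype(float) + (cohort.g_father == 1)
    den = het_count.sum(axis=0)
    num = (het_count * cohort.locus_dev_child).sum(axis=0)
    out = np.zeros(cohort.n_loci)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def multiplicative_family_slopes(
    pgs: PGSModel,
    C: Mapping[str, float],
    B: float,
    family_seg_var: Mapping[str, float] | None = None,
) -> PGSTheory:
    """Family-specific PGS slopes delta_f = (1 + C_f)/B under the
    multiplicative G×E model alpha_lf = C_f alpha_l with PGS weights
    beta_l = B alpha_l.

    The within-family regression recovers the average of the delta_f
    weighted by each family's PGS segregation variance (families whose
    parents are heterozygous at more scored loci count for more), not the
    unweighted average. ``family_seg_var`` supplies those variances (per
    family or family-class label); when omitted, every family gets the
    expected segregation variance under HWE and the weights are equal.
    """
    if B == 0:
        raise ConfigError("B = 0 leaves the PGS with no signal")
    slopes = {f: (1.0 + c) / B for f, c in C.items()}
    if family_seg_var is None:
        weights = {f: 1.0 / len(slopes) for f in slopes}
    else:
        total = float(sum(family_seg_var[f] for f in slopes))
        if total <= 0:
            raise DegenerateInputError("total segregation variance is zero")
        weights = {f: family_seg_var[f] / total for f in slopes}
    delta_fam = float(sum(weights[f] * slopes[f] for f in slopes))
    return PGSTheory(
        delta_rand=pgs_randomization_effect(pgs),
        delta_fam_pred=delta_fam,
        family_slopes=slopes,
        weights=weights,
        B=B,
    )
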