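"""Generation of family cohorts with heterogeneous allelic effects.

The single-locus generative model for the phenotype of child ``i`` in
family ``f`` is

    Y_i = Y* + (alpha + alpha_f + alpha_i) * g_i + eps_f + eps_i,

where ``g_i`` counts copies of the focal allele, ``alpha`` is the mean
per-allele effect, ``alpha_f``/``alpha_i`` are family- and
individual-level effect deviations (gene-by-environment interaction),
and ``eps_f``/``eps_i`` are environmental trait deviations. Families
live in populations; each population occupies one environment and
contributes a fixed component of ``alpha_f`` to all of its families.
All deviations are mean zero over the sampled families, which the
constructors enforce.

Parents are drawn from Hardy-Weinberg proportions (optionally deformed
by an inbreeding coefficient), mate monogamously at random within their
population, and transmit alleles by Mendelian segregation. The child's
segregation deviation sigma = g_child - midparent is recorded per locus
and is the quantity on which all within-family designs rely.

Multi-locus (polygenic-score) cohorts and two-locus marker/causal
haplotype cohorts follow the same conventions; see
:func:`simulate_pgs_cohort` and :func:`simulate_two_locus_cohort`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import TrioCohort
from .errors import ConfigError

__all__ = [
    "PopulationSpec",
    "LocusEffectModel",
    "TwoLocusModel",
    "PGSModel",
    "HAPLOTYPES",
    "draw_parent_genotypes",
    "segregate",
    "assign_phenotype",
    "simulate_drift",
    "compute_fst",
    "simulate_cohort",
    "simulate_two_locus_cohort",
    "simulate_pgs_cohort",
    "pgs_cohort_from_parents",
    "draw_gametes",
]

#: two-locus haplotype alphabet: marker allele first (M/m), causal second (A/a)
HAPLOTYPES = ("MA", "Ma", "mA", "ma")


# ----------------------------------------------------------------------
# configuration types
# ----------------------------------------------------------------------
@dataclass
class PopulationSpec:
    """One population, inhabiting one environment.

    ``allele_freq`` is the focal-allele frequency for single-locus runs, a
    length-4 haplotype frequency vector (order :data:`HAPLOTYPES`) for
    two-locus runs, or a per-locus array for polygenic runs (``None`` falls
    back to the loci's default frequencies). ``env_effect_dev`` is the
    alpha_f component shared by every family in this population.
    ``inbreeding_F`` deforms the parental genotype frequencies to
    p^2+Fpq / 2pq(1-F) / q^2+Fpq.
    """

    label: str
    allele_freq: float | Sequence[float] | None
    env_effect_dev: float = 0.0
    n_families: int = 1
    inbreeding_F: float = 0.0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ConfigError(f"population {self.label!r}: n_families must be >= 1")
        if not 0.0 <= self.inbreeding_F <= 1.0:
            raise ConfigError(f"population {self.label!r}: F must lie in [0, 1]")
        if self.allele_freq is None:
            return
        freq = np.atleast_1d(np.asarray(self.allele_freq, dtype=float))
        if np.any(freq < 0) or np.any(freq > 1):
            raise ConfigError(f"population {self.label!r}: frequencies must lie in [0, 1]")
        if freq.size == 4 and not np.isclose(freq.sum(), 1.0):
            raise ConfigError(
                f"population {self.label!r}: haplotype frequencies must sum to 1"
            )

    @property
    def hap_freqs(self) -> np.ndarray:
        freq = np.atleast_1d(np.asarray(self.allele_freq, dtype=float))
        if freq.size != 4:
            raise ConfigError(
                f"population {self.label!r} does not carry haplotype frequencies"
            )
        return freq


@dataclass
class LocusEffectModel:
    """Distributional parameters of the single-locus phenotype model."""

    intercept: float = 0.0
    alpha: float = 1.0
    sd_family_dev: float = 0.0  # extra alpha_f noise beyond the population offset
    sd_indiv_dev: float = 0.0  # alpha_i
    sd_env_family: float = 0.0  # eps_f
    sd_env_indiv: float = 0.0  # eps_i

    def __post_init__(self) -> None:
        for name in ("sd_family_dev", "sd_indiv_dev", "sd_env_family", "sd_env_indiv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


@dataclass
class TwoLocusModel:
    """A genotyped marker locus (alleles M/m) tagging an ungenotyped causal
    locus (alleles A/a) at recombination fraction ``recomb_fraction``.

    ``hap_freqs`` maps population label -> frequencies of (MA, Ma, mA, ma);
    a :class:`PopulationSpec` carrying its own 4-vector overrides the map.
    The causal allele A adds ``causal_alpha`` to the trait with no G×E.
    """

    hap_freqs: Mapping[str, Sequence[float]] = field(default_factory=dict)
    recomb_fraction: float = 0.0
    causal_alpha: float = 1.0
    intercept: float = 0.0
    sd_env_indiv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.recomb_fraction <= 0.5:
            raise ConfigError("recombination fraction must lie in [0, 0.5]")
        for label, freqs in self.hap_freqs.items():
            arr = np.asarray(freqs, dtype=float)
            if arr.shape != (4,) or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0):
                raise ConfigError(
                    f"haplotype frequencies for {label!r} must be 4 nonnegative "
                    "numbers summing to 1"
                )

    def freqs_for(self, spec: PopulationSpec) -> np.ndarray:
        if spec.allele_freq is not None:
            return spec.hap_freqs
        if spec.label not in self.hap_freqs:
            raise ConfigError(f"no haplotype frequencies for population {spec.label!r}")
        return np.asarray(self.hap_freqs[spec.label], dtype=float)


@dataclass
class PGSModel:
    """Loci underlying a polygenic score and the trait it predicts.

    The causal set L is indexed 0..n_loci-1 with per-locus mean effects
    ``alpha`` and default allele frequencies ``p``. The scored (genotyped)
    subset Lambda is given by ``pgs_loci`` with weights ``beta_hat``.
    Family-level effect deviations alpha_lf come either from explicit
    per-population offset vectors (``population_dev``) or from a
    multiplicative amplification factor per population
    (``multiplicative_C``, giving alpha_lf = C_f * alpha_l); at most one
    mechanism may be active. ``indiv_dev_sd`` is the SD of the
    individual-level deviation alpha_il, per locus.

    Loci are mutually unlinked and in linkage equilibrium by construction.
    """

    p: np.ndarray
    alpha: np.ndarray
    beta_hat: np.ndarray
    pgs_loci: np.ndarray | None = None
    population_dev: Mapping[str, Sequence[float]] | None = None
    multiplicative_C: Mapping[str, float] | None = None
    indiv_dev_sd: float | np.ndarray = 0.0
    intercept: float = 0.0
    sd_env_family: float = 0.0
    sd_env_indiv: float = 0.0

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        if self.p.shape != self.alpha.shape:
            raise ConfigError("p and alpha must have one entry per causal locus")
        if np.any(self.p < 0) or np.any(self.p > 1):
            raise ConfigError("allele frequencies must lie in [0, 1]")
        if self.pgs_loci is None:
            self.pgs_loci = np.arange(self.n_loci)
        self.pgs_loci = np.asarray(self.pgs_loci, dtype=int)
        if self.beta_hat.shape != self.pgs_loci.shape:
            raise ConfigError("beta_hat must have one entry per scored locus")
        if np.any(self.pgs_loci < 0) or np.any(self.pgs_loci >= self.n_loci):
            raise ConfigError("scored loci must form a subset of the causal loci")
        if len(set(self.pgs_loci.tolist())) != len(self.pgs_loci):
            raise ConfigError("scored loci must be distinct")
        if self.population_dev is not None and self.multiplicative_C is not None:
            raise ConfigError(
                "choose either per-population offsets or a multiplicative factor, not both"
            )
        self.indiv_dev_sd = np.broadcast_to(
            np.asarray(self.indiv_dev_sd, dtype=float), (self.n_loci,)
        ).copy()
        if np.any(self.indiv_dev_sd < 0):
            raise ConfigError("indiv_dev_sd must be nonnegative")

    @property
    def n_loci(self) -> int:
        return self.p.size

    @property
    def heterozygosity(self) -> np.ndarray:
        """HWE heterozygosity 2 p (1 - p) per causal locus."""
        return 2.0 * self.p * (1.0 - self.p)

    def family_dev(self, label: str) -> np.ndarray:
        """Realized alpha_lf vector for a family in population ``label``."""
        if self.population_dev is not None:
            if label not in self.population_dev:
                raise ConfigError(f"no effect deviations for population {label!r}")
            dev = np.asarray(self.population_dev[label], dtype=float)
            if dev.shape != (self.n_loci,):
                raise ConfigError("population_dev vectors must cover every causal locus")
            return dev
        if self.multiplicative_C is not None:
            if label not in self.multiplicative_C:
                raise ConfigError(f"no multiplicative factor for population {label!r}")
            return float(self.multiplicative_C[label]) * self.alpha
        return np.zeros(self.n_loci)

    def freqs_for(self, spec: PopulationSpec) -> np.ndarray:
        if spec.allele_freq is None:
            return self.p
        freq = np.broadcast_to(
            np.atleast_1d(np.asarray(spec.allele_freq, dtype=float)), (self.n_loci,)
        )
        return np.asarray(freq, dtype=float)


def _check_mean_zero_devs(specs: Sequence[PopulationSpec], devs: np.ndarray) -> None:
    """Population-level effect deviations must average to zero over families."""
    weights = np.array([s.n_families for s in specs], dtype=float)
    weights /= weights.sum()
    devs = np.asarray(devs, dtype=float)
    if devs.ndim == 1:
        devs = devs[:, None]
    mean_dev = weights @ devs
    if np.any(np.abs(mean_dev) > 1e-9):
        raise ConfigError(
            "population effect deviations must be mean zero under the family "
            f"sampling weights (got mean {mean_dev})"
        )


# ----------------------------------------------------------------------
# elementary draws
# ----------------------------------------------------------------------
def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, np.random.Generator):
        return np.random.SeedSequence(int(seed.integers(2**63)))
    return np.random.SeedSequence(seed)


def draw_parent_genotypes(
    p: float, n: int, seed=None, inbreeding_F: float = 0.0
) -> np.ndarray:
    """I.i.d. genotypes (focal-allele counts) from HWE at frequency ``p``,
    optionally deformed by an inbreeding coefficient F."""
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"allele frequency {p} outside [0, 1]")
    if n < 1:
        raise ConfigError("n must be >= 1")
    q = 1.0 - p
    probs = np.array(
        [
            q * q + inbreeding_F * p * q,
            2.0 * p * q * (1.0 - inbreeding_F),
            p * p + inbreeding_F * p * q,
        ]
    )
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    rng = _rng(seed)
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def segregate(g_mother, g_father, seed=None) -> np.ndarray:
    """Mendelian transmission: each parent contributes one gamete, a
    heterozygous parent transmitting the focal allele with probability 1/2.

    Accepts scalars or equally shaped arrays; returns child genotypes.
    """
    g_m = np.asarray(g_mother)
    g_f = np.asarray(g_father)
    if np.any((g_m < 0) | (g_m > 2)) or np.any((g_f < 0) | (g_f > 2)):
        raise ConfigError("genotypes must lie in {0, 1, 2}")
    rng = _rng(seed)
    gamete_m = rng.binomial(1, g_m / 2.0)
    gamete_f = rng.binomial(1, g_f / 2.0)
    return np.asarray(gamete_m + gamete_f).astype(np.int8)


class PhenotypeDraw(NamedTuple):
    phenotype: np.ndarray
    alpha_f: float
    alpha_i: np.ndarray
    eps_f: float
    eps_i: np.ndarray


def assign_phenotype(
    g, model: LocusEffectModel, env_effect_dev: float = 0.0, seed=None
) -> PhenotypeDraw:
    """Phenotypes for the children of one family under the single-locus model.

    ``env_effect_dev`` is the population component of alpha_f; the model may
    add mean-zero family noise on top. Individual-level terms are drawn
    independently per child. Returns the phenotypes together with the
    realized deviations so that simulation truth can be stored.
    """
    g = np.atleast_1d(np.asarray(g, dtype=float))
    rng = _rng(seed)
    alpha_f = env_effect_dev + (
        rng.normal(0.0, model.sd_family_dev) if model.sd_family_dev > 0 else 0.0
    )
    alpha_i = rng.normal(0.0, model.sd_indiv_dev, size=g.shape)
    eps_f = rng.normal(0.0, model.sd_env_family) if model.sd_env_family > 0 else 0.0
    eps_i = rng.normal(0.0, model.sd_env_indiv, size=g.shape)
    y = model.intercept + (model.alpha + alpha_f + alpha_i) * g + eps_f + eps_i
    return PhenotypeDraw(y, alpha_f, alpha_i, eps_f, eps_i)


# ----------------------------------------------------------------------
# drift and differentiation
# ----------------------------------------------------------------------
def simulate_drift(
    p0: float, pop_size: int, generations: int, seed=None
) -> tuple[float, float]:
    """Two independent Wright-Fisher trajectories from a shared starting
    frequency; returns the two terminal frequencies (red, blue).

    Each generation resamples ``2 * pop_size`` allele copies binomially.
    """
    if not 0.0 < p0 < 1.0:
        raise ConfigError("starting frequency must lie strictly in (0, 1)")
    rng = _rng(seed)
    n_copies = 2 * pop_size
    freqs = [p0, p0]
    for k in range(2):
        p = p0
        for _ in range(generations):
            p = rng.binomial(n_copies, p) / n_copies
        freqs[k] = p
    return freqs[0], freqs[1]


def compute_fst(p_red: float, p_blue: float) -> float:
    """Nei's G_ST for two equally weighted populations:
    F_ST = 1 - H_S / H_T, with H_S the mean within-population
    heterozygosity and H_T the heterozygosity at the pooled frequency.
    Returns 0 when the pooled locus is monomorphic."""
    p_bar = 0.5 * (p_red + p_blue)
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    if h_t == 0.0:
        return 0.0
    h_s = p_red * (1.0 - p_red) + p_blue * (1.0 - p_blue)
    return 1.0 - h_s / h_t


# ----------------------------------------------------------------------
# single-locus cohorts
# ----------------------------------------------------------------------
def simulate_cohort(
    specs: Sequence[PopulationSpec],
    model: LocusEffectModel,
    children_per_family: int = 1,
    seed=None,
) -> TrioCohort:
    """Random-mating trio cohort at a single locus.

    One monogamous parent pair per family; ``children_per_family`` children
    each (two for sibling designs). Population offsets must be mean zero
    under the family sampling weights.
    """
    _check_mean_zero_devs(specs, np.array([s.env_effect_dev for s in specs]))
    root = _seedseq(seed)
    streams = root.spawn(len(specs))
    frames = []
    g_c, g_m, g_f = [], [], []
    for spec, stream in zip(specs, streams):
        rng = np.random.default_rng(stream)
        n = spec.n_families
        p = float(np.atleast_1d(spec.allele_freq)[0])
        gm = draw_parent_genotypes(p, n, rng, spec.inbreeding_F)
        gf = draw_parent_genotypes(p, n, rng, spec.inbreeding_F)
        gm = np.repeat(gm, children_per_family)
        gf = np.repeat(gf, children_per_family)
        gc = segregate(gm, gf, rng)
        n_children = n * children_per_family
        # family-level draws, broadcast to children
        alpha_f = spec.env_effect_dev + (
            rng.normal(0.0, model.sd_family_dev, size=n)
            if model.sd_family_dev > 0
            else np.zeros(n)
        )
        eps_f = (
            rng.normal(0.0, model.sd_env_family, size=n)
            if model.sd_env_family > 0
            else np.zeros(n)
        )
        alpha_f = np.repeat(alpha_f, children_per_family)
        eps_f = np.repeat(eps_f, children_per_family)
        alpha_i = rng.normal(0.0, model.sd_indiv_dev, size=n_children)
        eps_i = rng.normal(0.0, model.sd_env_indiv, size=n_children)
        y = model.intercept + (model.alpha + alpha_f + alpha_i) * gc + eps_f + eps_i
        fam_ids = np.repeat(
            [f"{spec.label}_{j}" for j in range(n)], children_per_family
        )
        frames.append(
            pd.DataFrame(
                {
                    "family_id": fam_ids,
                    "child_id": np.tile(np.arange(children_per_family), n),
                    "population": spec.label,
                    "phenotype": y,
                    "alpha_f": alpha_f,
                    "alpha_i": alpha_i,
                }
            )
        )
        g_c.append(gc)
        g_m.append(gm)
        g_f.append(gf)
    fam = pd.concat(frames, ignore_index=True)
    dev = (fam["alpha_f"] + fam["alpha_i"]).to_numpy()[:, None]
    return TrioCohort(
        fam=fam,
        g_child=np.concatenate(g_c)[:, None],
        g_mother=np.concatenate(g_m)[:, None],
        g_father=np.concatenate(g_f)[:, None],
        locus_ids=["locus0"],
        locus_dev_child=dev,
    )


# ----------------------------------------------------------------------
# two-locus cohorts
# ----------------------------------------------------------------------
def draw_gametes(diplotypes: np.ndarray, r: float, seed=None) -> np.ndarray:
    """Transmitted two-locus haplotypes from parental diplotypes.

    ``diplotypes`` has shape (n, 2) with entries indexing
    :data:`HAPLOTYPES`. The marker allele comes from a uniformly chosen
    parental haplotype; the causal allele comes from the same haplotype
    with probability 1 - r and from the homolog with probability r.
    Returns the transmitted haplotype index per parent.
    """
    if not 0.0 <= r <= 0.5:
        raise ConfigError("recombination fraction must lie in [0, 0.5]")
    diplo = np.asarray(diplotypes)
    rng = _rng(seed)
    n = diplo.shape[0]
    pick = rng.integers(0, 2, size=n)
    swap = rng.random(n) < r
    hap_marker = diplo[np.arange(n), pick]
    hap_causal = np.where(swap, diplo[np.arange(n), 1 - pick], hap_marker)
    marker_is_M = hap_marker < 2
    causal_is_A = hap_causal % 2 == 0
    return (np.where(marker_is_M, 0, 2) + np.where(causal_is_A, 0, 1)).astype(np.int8)


def simulate_two_locus_cohort(
    model: TwoLocusModel,
    specs: Sequence[PopulationSpec],
    children_per_family: int = 1,
    seed=None,
) -> TrioCohort:
    """Trio cohort at a genotyped marker tagging an ungenotyped causal locus.

    Parents are random haplotype pairs drawn per population; gametes
    recombine with probability ``model.recomb_fraction``. The phenotype is
    intercept + causal_alpha * (causal-allele count) + noise, with no G×E.
    The returned cohort has loci ("marker", "causal"); only the marker is
    treated as genotyped by downstream estimators.
    """
    p_m = np.array([model.freqs_for(s)[0] + model.freqs_for(s)[1] for s in specs])
    if np.all((p_m == 0.0) | (p_m == 1.0)):
        pooled = np.average(p_m, weights=[s.n_families for s in specs])
        if pooled in (0.0, 1.0):
            raise ConfigError("marker locus is monomorphic in every population")
        logging.getLogger(__name__).warning(
            "marker locus is monomorphic within each population; "
            "within-family designs will be degenerate"
        )

    root = _seedseq(seed)
    frames, g_c, g_m, g_f = [], [], [], []
    for spec, stream in zip(specs, root.spawn(len(specs))):
        rng = np.random.default_rng(stream)
        freqs = model.freqs_for(spec)
        n = spec.n_families
        diplo_m = rng.choice(4, size=(n, 2), p=freqs)
        diplo_f = rng.choice(4, size=(n, 2), p=freqs)
        diplo_m = np.repeat(diplo_m, children_per_family, axis=0)
        diplo_f = np.repeat(diplo_f, children_per_family, axis=0)
        gam_m = draw_gametes(diplo_m, model.recomb_fraction, rng)
        gam_f = draw_gametes(diplo_f, model.recomb_fraction, rng)

        def counts(haps: np.ndarray) -> np.ndarray:
            # (marker count, causal count) per individual given 2 haplotypes
            marker = (haps < 2).sum(axis=1)
            causal = (haps % 2 == 0).sum(axis=1)
            return np.stack([marker, causal], axis=1).astype(np.int8)

        child_haps = np.stack([gam_m, gam_f], axis=1)
        gc = counts(child_haps)
        gm = counts(diplo_m)
        gf = counts(diplo_f)
        n_children = n * children_per_family
        y = (
            model.intercept
            + model.causal_alpha * gc[:, 1]
            + (
                rng.normal(0.0, model.sd_env_indiv, size=n_children)
                if model.sd_env_indiv > 0
                else 0.0
            )
        )
        fam_ids = np.repeat([f"{spec.label}_{j}" for j in range(n)], children_per_family)
        frames.append(
            pd.DataFrame(
                {
                    "family_id": fam_ids,
                    "child_id": np.tile(np.arange(children_per_family), n),
                    "population": spec.label,
                    "phenotype": y,
                }
            )
        )
        g_c.append(gc)
        g_m.append(gm)
        g_f.append(gf)
    return TrioCohort(
        fam=pd.concat(frames, ignore_index=True),
        g_child=np.concatenate(g_c),
        g_mother=np.concatenate(g_m),
        g_father=np.concatenate(g_f),
        locus_ids=["marker", "causal"],
    )


# ----------------------------------------------------------------------
# polygenic cohorts
# ----------------------------------------------------------------------
def pgs_cohort_from_parents(
    model: PGSModel,
    g_mother: np.ndarray,
    g_father: np.ndarray,
    populations: Sequence[str],
    children_per_family: int = 1,
    seed=None,
) -> TrioCohort:
    """Children and phenotypes from fixed parental genotype matrices.

    ``g_mother``/``g_father`` have shape (n_families, n_loci);
    ``populations`` gives one environment label per family (it selects the
    family's alpha_lf vector). This is the engine behind
    :func:`simulate_pgs_cohort` and is also useful for designed parental
    heterozygosity patterns.
    """
    g_mother = np.asarray(g_mother)
    g_father = np.asarray(g_father)
    n_fam, n_loci = g_mother.shape
    if g_father.shape != (n_fam, n_loci) or n_loci != model.n_loci:
        raise ConfigError("parental genotype matrices must be (n_families, n_loci)")
    if len(populations) != n_fam:
        raise ConfigError("one population label per family is required")
    rng = _rng(seed)

    labels = pd.unique(np.asarray(populations, dtype=object))
    dev_by_label = {lab: model.family_dev(lab) for lab in labels}
    alpha_lf = np.stack([dev_by_label[lab] for lab in populations])  # (n_fam, L)

    gm = np.repeat(g_mother, children_per_family, axis=0)
    gf = np.repeat(g_father, children_per_family, axis=0)
    n_children = n_fam * children_per_family
    gc = (rng.binomial(1, gm / 2.0) + rng.binomial(1, gf / 2.0)).astype(np.int8)

    alpha_lf_children = np.repeat(alpha_lf, children_per_family, axis=0)
    if np.any(model.indiv_dev_sd > 0):
        alpha_il = rng.normal(0.0, 1.0, size=(n_children, n_loci)) * model.indiv_dev_sd
    else:
        alpha_il = np.zeros((n_children, n_loci))
    eps_f = (
        rng.normal(0.0, model.sd_env_family, size=n_fam)
        if model.sd_env_family > 0
        else np.zeros(n_fam)
    )
    eps_i = (
        rng.normal(0.0, model.sd_env_indiv, size=n_children)
        if model.sd_env_indiv > 0
        else np.zeros(n_children)
    )
    effects = model.alpha[None, :] + alpha_lf_children + alpha_il
    y = (
        model.intercept
        + np.einsum("il,il->i", effects, gc.astype(float))
        + np.repeat(eps_f, children_per_family)
        + eps_i
    )
    fam_ids = np.repeat([f"fam_{j}" for j in range(n_fam)], children_per_family)
    fam = pd.DataFrame(
        {
            "family_id": fam_ids,
            "child_id": np.tile(np.arange(children_per_family), n_fam),
            "population": np.repeat(np.asarray(populations, dtype=object), children_per_family),
            "phenotype": y,
        }
    )
    dev = alpha_lf_children + alpha_il
    return TrioCohort(
        fam=fam,
        g_child=gc,
        g_mother=gm,
        g_father=gf,
        locus_ids=[f"locus{j}" for j in range(n_loci)],
        locus_dev_child=dev if np.any(dev) else np.zeros_like(dev),
    )


def simulate_pgs_cohort(
    model: PGSModel,
    specs: Sequence[PopulationSpec],
    children_per_family: int = 1,
    seed=None,
) -> TrioCohort:
    """Random-mating multi-locus cohort; loci unlinked and in linkage
    equilibrium within each population. Per-population effect deviations
    must be mean zero under the family sampling weights."""
    devs = np.stack([model.family_dev(s.label) for s in specs])
    _check_mean_zero_devs(specs, devs)
    root = _seedseq(seed)
    pieces = []
    for spec, stream in zip(specs, root.spawn(len(specs))):
        rng = np.random.default_rng(stream)
        p = model.freqs_for(spec)
        n = spec.n_families
        gm = rng.binomial(2, p[None, :], size=(n, model.n_loci)).astype(np.int8)
        gf = rng.binomial(2, p[None, :], size=(n, model.n_loci)).astype(np.int8)
        pieces.append(
            pgs_cohort_from_parents(
                model, gm, gf, [spec.label] * n, children_per_family, rng
            )
        )
    fam = pd.concat([c.fam for c in pieces], ignore_index=True)
    # re-key family ids so they stay unique across populations
    fam["family_id"] = (
        fam["population"].astype(str) + "_" + fam["family_id"].astype(str)
    )
    return TrioCohort(
        fam=fam,
        g_child=np.concatenate([c.g_child for c in pieces]),
        g_mother=np.concatenate([c.g_mother for c in pieces]),
        g_father=np.concatenate([c.g_father for c in pieces]),
        locus_ids=pieces[0].locus_ids,
        locus_dev_child=np.concatenate([c.locus_dev_child for c in pieces]),
    )
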