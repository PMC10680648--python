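"""OLS association estimators for trio, sibling and population designs.

All estimators are ordinary least squares with heteroskedasticity-robust
(HC1) standard errors, since effect heterogeneity makes the phenotype
residual variance depend on genotype by construction.

Design summary (Y is the child phenotype, g the child genotype, sigma the
segregation deviation g - midparent):

* population:     Y ~ 1 + g                      -> alpha_hat_pop
* trio (family):  Y ~ 1 + g + g_m + g_f          -> alpha_hat_fam
* sibling:        (Y1 - Y2) ~ (g1 - g2)          -> alpha_hat_fam (same
  expectation as the trio design)
* segregation:    Y ~ 1 + sigma                  -> same expectation as the
  trio design; with sigma taken as the empirical residual of g (or the
  PGS) on the parental controls, the slope equals the trio/PGS child
  coefficient exactly on any finite sample (Frisch-Waugh-Lovell).

Polygenic-score designs replace g by PGS = sum_l beta_hat_l g_l and control
for the parental PGS sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .cohort import TrioCohort
from .errors import DegenerateInputError, RankDeficiencyError
from .simulate import PGSModel

logger = logging.getLogger(__name__)

__all__ = [
    "EstimateResult",
    "VarianceDecomposition",
    "population_gwas",
    "family_gwas",
    "sib_difference",
    "seg_regression",
    "family_pgs",
    "population_pgs",
    "pgs_variance_decomposition",
]


@dataclass
class EstimateResult:
    """A fitted association slope with its provenance."""

    estimator: str
    slope: float
    intercept: float
    stderr: float
    n_used: int
    parental_coef: float | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("standard error cannot be negative")


@dataclass
class VarianceDecomposition:
    """Within/between family decomposition of PGS and phenotype variance.

    ``seg_explained`` is the share of phenotypic variance attributable to
    Mendelian segregation at the scored loci, slope^2 * V_seg / V_pheno;
    ``full_extrapolated`` is the conventional slope^2 * V_PGS / V_pheno,
    which additionally extrapolates the within-family slope to the
    between-family PGS variance.
    """

    v_pgs: float
    v_between: float
    v_seg: float
    v_pheno: float
    seg_explained: float
    full_extrapolated: float
    cov_mid_seg: float = 0.0


# ----------------------------------------------------------------------
def _fit(y: np.ndarray, X: np.ndarray, estimator: str, cov_type: str = "HC1"):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            f"{estimator}: design matrix is rank deficient "
            "(no independent within- or between-family genotype variation)"
        )
    return sm.OLS(y, X).fit(cov_type=cov_type)


def _column(cohort: TrioCohort, which: str, locus) -> np.ndarray:
    j = cohort.locus_index(locus)
    return getattr(cohort, which)[:, j].astype(float)


def _locus_data(cohort: TrioCohort, locus, need_parents: bool):
    """Per-locus vectors with trios carrying missing genotypes dropped."""
    g = _column(cohort, "g_child", locus)
    g_m = _column(cohort, "g_mother", locus)
    g_f = _column(cohort, "g_father", locus)
    keep = g >= 0
    if need_parents:
        keep &= (g_m >= 0) & (g_f >= 0)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("locus %r: dropped %d trios with missing genotypes", locus, dropped)
    return cohort.phenotype[keep], g[keep], g_m[keep], g_f[keep]


def population_gwas(cohort: TrioCohort, locus=0) -> EstimateResult:
    """Population-based association: OLS of child phenotype on child
    genotype, no parental controls."""
    y, g, _, _ = _locus_data(cohort, locus, need_parents=False)
    if np.var(g) == 0:
        raise DegenerateInputError(
            f"locus {locus!r} is monomorphic among children; "
            "the population regression is undefined"
        )
    res = _fit(y, sm.add_constant(g), "population")
    return EstimateResult(
        estimator="population",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        n_used=len(y),
    )


def family_gwas(
    cohort: TrioCohort, locus=0, parental_control: str = "separate"
) -> EstimateResult:
    """Trio design: phenotype on child genotype controlling for parental
    genotypes; returns the child-genotype coefficient.

    ``parental_control`` is ``"separate"`` (mother and father entered as two
    regressors; the default for single loci, which also absorbs
    parent-of-origin frequency differences) or ``"sum"`` (a single
    mother+father regressor). The two are asymptotically equivalent.
    """
    y, g, g_m, g_f = _locus_data(cohort, locus, need_parents=True)
    if not np.any((g_m == 1) | (g_f == 1)):
        raise RankDeficiencyError(
            "family_gwas: no heterozygous parents at this locus, so there is "
            "no within-family genotype variance to exploit"
        )
    if parental_control == "separate":
        X = np.column_stack([np.ones_like(g), g, g_m, g_f])
    elif parental_control == "sum":
        X = np.column_stack([np.ones_like(g), g, g_m + g_f])
    else:
        raise ValueError("parental_control must be 'separate' or 'sum'")
    res = _fit(y, X, "trio_family")
    parental = float(res.params[2]) if parental_control == "sum" else None
    return EstimateResult(
        estimator="trio_family",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        n_used=len(y),
        parental_coef=parental,
    )


def sib_difference(cohort: TrioCohort, locus=0) -> EstimateResult:
    """Sibling design: OLS of the phenotype difference between two full
    siblings on their genotype difference, through the origin."""
    first, second = cohort.sibling_pairs()
    g = _column(cohort, "g_child", locus)
    y = cohort.phenotype
    keep = (g[first] >= 0) & (g[second] >= 0)
    first, second = first[keep], second[keep]
    dg = g[first] - g[second]
    dy = y[first] - y[second]
    if np.all(dg == 0):
        raise DegenerateInputError(
            "sib_difference: every sibling pair is genotypically identical "
            "at this locus"
        )
    res = _fit(dy, dg[:, None], "sib_difference")
    return EstimateResult(
        estimator="sib_difference",
        slope=float(res.params[0]),
        intercept=0.0,
        stderr=float(res.bse[0]),
        n_used=len(first),
    )


def _pgs_triplet(cohort: TrioCohort, pgs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(pgs, PGSModel):
        return cohort.pgs(pgs.beta_hat, pgs.pgs_loci)
    beta, loci = pgs if isinstance(pgs, tuple) else (np.asarray(pgs), None)
    return cohort.pgs(beta, loci)


def seg_regression(
    cohort: TrioCohort, locus=None, pgs=None, mode: str = "structural"
) -> EstimateResult:
    """Regression of the phenotype on the segregation deviation.

    The deviation is either *structural* (child minus midparent, computable
    from observed parental genotypes) or the *empirical residual* of the
    child score on the parental-sum control, in which case the slope
    reproduces the trio/PGS child coefficient exactly on the same finite
    sample (Frisch-Waugh-Lovell).
    """
    if (locus is None) == (pgs is None):
        raise ValueError("pass exactly one of locus= or pgs=")
    if pgs is not None:
        child, mother, father = _pgs_triplet(cohort, pgs)
        y = cohort.phenotype
    else:
        y, child, mother, father = _locus_data(cohort, locus, need_parents=True)
    if mode == "structural":
        dev = child - (mother + father) / 2.0
    elif mode == "residual":
        controls = sm.add_constant(mother + father)
        dev = child - controls @ np.linalg.lstsq(controls, child, rcond=None)[0]
    else:
        raise ValueError("mode must be 'structural' or 'residual'")
    if np.allclose(dev, 0.0):
        raise DegenerateInputError(
            "seg_regression: segregation deviations are identically zero "
            "(no heterozygous parents)"
        )
    res = _fit(y, sm.add_constant(dev), "seg_regression")
    return EstimateResult(
        estimator="seg_regression",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        n_used=len(y),
    )


def family_pgs(cohort: TrioCohort, pgs) -> EstimateResult:
    """Within-family PGS design: phenotype on the child PGS controlling for
    the parental PGS sum; returns the child coefficient (slope) and the
    parental coefficient (``parental_coef``)."""
    child, mother, father = _pgs_triplet(cohort, pgs)
    controls = mother + father
    resid = child - np.polyval(np.polyfit(controls, child, 1), controls) if np.var(
        controls
    ) > 0 else child - child.mean()
    if np.allclose(resid, 0.0):
        raise RankDeficiencyError(
            "family_pgs: the child PGS is collinear with the parental PGS "
            "(no segregation variance at the scored loci)"
        )
    X = np.column_stack([np.ones_like(child), child, controls])
    res = _fit(cohort.phenotype, X, "family_pgs")
    return EstimateResult(
        estimator="trio_family",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        n_used=cohort.n_children,
        parental_coef=float(res.params[2]),
    )


def population_pgs(cohort: TrioCohort, pgs) -> EstimateResult:
    """Population PGS design: phenotype on the child PGS alone.

    The returned ``extras`` decompose the slope into the between-family
    covariance term Cov(Y, midparent PGS)/V_PGS and the within-family term
    (V_seg / V_PGS) * delta_fam, whose sum matches the population slope up
    to sampling error.
    """
    child, mother, father = _pgs_triplet(cohort, pgs)
    if np.var(child) == 0:
        raise DegenerateInputError("population_pgs: the PGS has zero variance")
    y = cohort.phenotype
    res = _fit(y, sm.add_constant(child), "population_pgs")
    mid = (mother + father) / 2.0
    seg = child - mid
    v_pgs = float(np.var(child))
    between_term = float(np.cov(y, mid, ddof=0)[0, 1] / v_pgs)
    delta_fam = family_pgs(cohort, pgs).slope
    within_term = float(np.var(seg) / v_pgs * delta_fam)
    return EstimateResult(
        estimator="population",
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr=float(res.bse[1]),
        n_used=cohort.n_children,
        extras={
            "between_term": between_term,
            "within_term": within_term,
            "delta_fam": delta_fam,
            "v_pgs": v_pgs,
            "v_seg": float(np.var(seg)),
        },
    )


def pgs_variance_decomposition(
    cohort: TrioCohort, pgs, family_slope: float
) -> VarianceDecomposition:
    """Sample-moment decomposition of PGS and phenotype variance.

    ``family_slope`` is the within-family PGS coefficient (from
    :func:`family_pgs`). ``seg_explained`` = slope^2 V_seg / V_P is the
    internally valid share of phenotypic variance due to Mendelian
    segregation at the scored loci; ``full_extrapolated`` = slope^2 V_PGS /
    V_P extrapolates the within-family slope to the full PGS variance.
    """
    child, mother, father = _pgs_triplet(cohort, pgs)
    y = cohort.phenotype
    v_pheno = float(np.var(y))
    if v_pheno == 0:
        raise DegenerateInputError("phenotype variance is zero")
    mid = (mother + father) / 2.0
    seg = child - mid
    v_pgs = float(np.var(child))
    v_between = float(np.var(mid))
    v_seg = float(np.var(seg))
    return VarianceDecomposition(
        v_pgs=v_pgs,
        v_between=v_between,
        v_seg=v_seg,
        v_pheno=v_pheno,
        seg_explained=family_slope**2 * v_seg / v_pheno,
        full_extrapolated=family_slope**2 * v_pgs / v_pheno,
        cov_mid_seg=float(np.cov(mid, seg, ddof=0)[0, 1]),
    )
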