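import numpy as np
import pandas as pd
import pytest

from famhet.cohort import TrioCohort
from famhet.theory import DiscreteJoint


@pytest.fixture
def toy_cohort():
    """Build a minimal TrioCohort from explicit per-child vectors."""

    def build(g_child, g_mother, g_father, phenotype, population=None, family_id=None):
        g_child = np.atleast_2d(np.asarray(g_child)).T if np.ndim(g_child) == 1 else np.asarray(g_child)
        g_mother = np.atleast_2d(np.asarray(g_mother)).T if np.ndim(g_mother) == 1 else np.asarray(g_mother)
        g_father = np.atleast_2d(np.asarray(g_father)).T if np.ndim(g_father) == 1 else np.asarray(g_father)
        n = g_child.shape[0]
        fam = pd.DataFrame(
            {
                "family_id": [f"f{i}" for i in range(n)] if family_id is None else family_id,
                "child_id": 0 if family_id is None else pd.Series(family_id).groupby(family_id).cumcount(),
                "population": "pop" if population is None else population,
                "phenotype": np.asarray(phenotype, dtype=float),
            }
        )
        return TrioCohort(
            fam=fam,
            g_child=g_child,
            g_mother=g_mother,
            g_father=g_father,
            locus_ids=[f"locus{j}" for j in range(g_child.shape[1])],
        )

    return build


@pytest.fixture
def random_joint():
    """Random multi-population joint with mean-zero environment deviations.

    Cells are Hardy-Weinberg within populations so the parental and
    offspring generations share allele frequency and (Wahlund) inbreeding
    coefficient; ``cell_inbreeding=True`` adds within-cell parental
    inbreeding, which breaks that stationarity.
    """

    def build(rng, n_cells=None, cell_inbreeding=False):
        k = int(rng.integers(2, 5)) if n_cells is None else n_cells
        w = rng.dirichlet(np.ones(k))
        p = rng.uniform(0.05, 0.95, size=k)
        a = rng.normal(0.0, 0.3, size=k)
        a = a - w @ a  # mean zero under the family weights
        F = rng.uniform(0.0, 0.5, size=k) if cell_inbreeding else np.zeros(k)
        return DiscreteJoint.from_populations(
            [(f"pop{i}", w[i], p[i], a[i], F[i]) for i in range(k)]
        )

    return build
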