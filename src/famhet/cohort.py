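"""Trio cohort container shared by the simulator, the estimators and the
pedigree I/O layer.

A cohort is a set of children with known parental genotypes. Genotypes are
coded as counts of the focal allele (0/1/2), one column per locus, and the
segregation deviation of child ``i`` at locus ``l`` is

    seg_dev[i, l] = g_child[i, l] - (g_mother[i, l] + g_father[i, l]) / 2,

which is nonzero only when a parent is heterozygous at ``l``. Simulated
cohorts may carry "truth" columns (realized family/individual effect
deviations) that real data would not have; estimators never read them
except where an operation explicitly requires simulation truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError

#: columns every cohort frame must carry, one row per child
FAM_COLUMNS = ("family_id", "child_id", "population", "phenotype")


@dataclass
class TrioRecord:
    """One child with its parental genotypes at a single locus."""

    family_id: str
    population: str
    g_mother: int
    g_father: int
    g_child: int
    phenotype: float
    seg_dev: float = field(init=False)
    alpha_f_realized: float = np.nan
    alpha_i_realized: float = np.nan

    def __post_init__(self) -> None:
        self.seg_dev = self.g_child - (self.g_mother + self.g_father) / 2.0
        if abs(self.seg_dev) > 1.0:
            raise ConfigError(
                f"child genotype {self.g_child} incompatible with parents "
                f"({self.g_mother}, {self.g_father})"
            )


@dataclass
class TrioCohort:
    """Children with parental genotypes at one or more unlinked loci.

    Parameters
    ----------
    fam
        One row per child with at least :data:`FAM_COLUMNS`. Simulated
        cohorts additionally carry ``alpha_f``, ``alpha_i`` (single-locus
        truth) where applicable.
    g_child, g_mother, g_father
        Integer genotype matrices of shape ``(n_children, n_loci)``.
    locus_ids
        Locus labels, one per genotype column.
    locus_dev_child
        Optional truth matrix of realized per-child, per-locus effect
        deviations (family + individual G×E terms); ``None`` when the
        generating model had none.
    """

    fam: pd.DataFrame
    g_child: np.ndarray
    g_mother: np.ndarray
    g_father: np.ndarray
    locus_ids: list[str]
    locus_dev_child: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("g_child", "g_mother", "g_father"):
            arr = np.atleast_2d(np.asarray(getattr(self, name)))
            if arr.shape != (len(self.fam), len(self.locus_ids)):
                raise ConfigError(
                    f"{name} has shape {arr.shape}, expected "
                    f"({len(self.fam)}, {len(self.locus_ids)})"
                )
            setattr(self, name, arr)
        missing = [c for c in FAM_COLUMNS if c not in self.fam.columns]
        if missing:
            raise ConfigError(f"cohort frame lacks columns {missing}")
        # missing genotypes (negative sentinel) are exempt from the
        # Mendelian-consistency check
        observed = (self.g_child >= 0) & (self.g_mother >= 0) & (self.g_father >= 0)
        midparent = (self.g_mother + self.g_father) / 2.0
        dev = np.where(observed, np.abs(self.g_child - midparent), 0.0)
        if dev.max(initial=0.0) > 1.0:
            raise ConfigError("a child genotype is incompatible with its parents")

    # ------------------------------------------------------------------
    @property
    def n_children(self) -> int:
        return len(self.fam)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def phenotype(self) -> np.ndarray:
        return self.fam["phenotype"].to_numpy(dtype=float)

    @property
    def seg_dev(self) -> np.ndarray:
        """Per-locus segregation deviations, shape (n_children, n_loci)."""
        return self.g_child - (self.g_mother + self.g_father) / 2.0

    def locus_index(self, locus: int | str) -> int:
        if isinstance(locus, str):
            try:
                return self.locus_ids.index(locus)
            except ValueError:
                raise KeyError(f"unknown locus {locus!r}") from None
        if not 0 <= locus < self.n_loci:
            raise KeyError(f"locus index {locus} out of range")
        return int(locus)

    def pgs(self, beta: np.ndarray, loci: np.ndarray | None = None):
        """Polygenic scores sum(beta_l * g_l) for child, mother and father.

        ``loci`` selects the scored (genotyped) columns; by default all
        loci are scored.
        """
        beta = np.asarray(beta, dtype=float)
        idx = np.arange(self.n_loci) if loci is None else np.asarray(loci)
        if beta.shape != idx.shape:
            raise ConfigError("one weight per scored locus is required")
        return (
            self.g_child[:, idx] @ beta,
            self.g_mother[:, idx] @ beta,
            self.g_father[:, idx] @ beta,
        )

    def record(self, i: int, locus: int | str = 0) -> TrioRecord:
        """Single-locus record view of child ``i`` (mostly for inspection)."""
        j = self.locus_index(locus)
        row = self.fam.iloc[i]
        return TrioRecord(
            family_id=str(row["family_id"]),
            population=str(row["population"]),
            g_mother=int(self.g_mother[i, j]),
            g_father=int(self.g_father[i, j]),
            g_child=int(self.g_child[i, j]),
            phenotype=float(row["phenotype"]),
            alpha_f_realized=float(row.get("alpha_f", np.nan)),
            alpha_i_realized=float(row.get("alpha_i", np.nan)),
        )

    def sibling_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index pairs (first child, second child) for two-child families."""
        order = self.fam.groupby("family_id", sort=False).cumcount().to_numpy()
        fam_ids = self.fam["family_id"].to_numpy()
        first = np.flatnonzero(order == 0)
        second = np.flatnonzero(order == 1)
        if len(first) != len(second) or (order > 1).any():
            raise ConfigError("sibling designs require exactly two children per family")
        if not np.array_equal(fam_ids[first], fam_ids[second]):
            raise ConfigError("cohort rows are not grouped by family")
        return first, second
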