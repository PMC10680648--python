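"""Whitespace-delimited pedigree + genotype files (a minimal PED dialect).

Two files describe a cohort:

* ``<prefix>.fam`` -- one row per individual:
  ``family_id individual_id father_id mother_id sex phenotype``
  with ``0`` for unknown parents, sex always ``0`` and ``-9`` for a
  missing phenotype. Parents precede their children within a family.
* ``<prefix>.geno`` -- one row per individual:
  ``family_id individual_id`` followed by two allele columns per locus,
  alleles coded ``1``/``2`` (``2`` the focal allele by default) and ``0``
  for a missing allele.

A simulated cohort additionally writes ``<prefix>.truth.tsv`` with the
population label and realized effect deviations per child -- simulation
truth that real data would not have; it is read back only when explicitly
supplied.

Trios are assembled by parent-ID linkage: a child row is any individual
whose two parent IDs both resolve to genotyped individuals. Children with
missing parents are excluded (and counted in the log). A missing genotype
is stored as -1 in the cohort matrices; estimators drop those rows for
the locus they analyse.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import TrioCohort
from .errors import PedFormatError

logger = logging.getLogger(__name__)

__all__ = ["write_ped", "read_ped", "MISSING"]

#: sentinel for a missing genotype in cohort matrices
MISSING = -1

_FLOAT_FMT = "%.10g"


def _individual_ids(fam: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    child = (
        fam["family_id"].astype(str) + "_c" + fam["child_id"].astype(str)
    ).to_numpy()
    mother = (fam["family_id"].astype(str) + "_m").to_numpy()
    father = (fam["family_id"].astype(str) + "_f").to_numpy()
    return child, mother, father


def _geno_fields(g: int) -> str:
    if g == MISSING:
        return "0 0"
    return ("1 1", "1 2", "2 2")[int(g)]


def write_ped(cohort: TrioCohort, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.fam`` and ``<prefix>.geno`` (plus
    ``<prefix>.truth.tsv`` when the cohort carries simulation truth).
    Output is deterministic: equal cohorts produce byte-identical files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fam = cohort.fam
    child_ids, mother_ids, father_ids = _individual_ids(fam)

    fam_path = prefix.with_suffix(".fam")
    geno_path = prefix.with_suffix(".geno")
    seen_parents: set[str] = set()
    with fam_path.open("w") as fh_fam, geno_path.open("w") as fh_geno:
        for i in range(cohort.n_children):
            famid = str(fam["family_id"].iloc[i])
            for pid, genos in (
                (mother_ids[i], cohort.g_mother[i]),
                (father_ids[i], cohort.g_father[i]),
            ):
                if pid in seen_parents:
                    continue
                seen_parents.add(pid)
                fh_fam.write(f"{famid} {pid} 0 0 0 -9\n")
                fh_geno.write(
                    f"{famid} {pid} " + " ".join(_geno_fields(g) for g in genos) + "\n"
                )
            pheno = _FLOAT_FMT % fam["phenotype"].iloc[i]
            fh_fam.write(
                f"{famid} {child_ids[i]} {father_ids[i]} {mother_ids[i]} 0 {pheno}\n"
            )
            fh_geno.write(
                f"{famid} {child_ids[i]} "
                + " ".join(_geno_fields(g) for g in cohort.g_child[i])
                + "\n"
            )
    written = [fam_path, geno_path]

    truth_cols = [c for c in ("population", "alpha_f", "alpha_i") if c in fam.columns]
    if "population" in truth_cols:
        truth = fam[["family_id"]].copy()
        truth["individual_id"] = child_ids
        for c in truth_cols:
            truth[c] = fam[c]
        truth_path = prefix.with_suffix(".truth.tsv")
        truth.to_csv(truth_path, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(truth_path)
    return written


def _parse_fam(path: Path) -> pd.DataFrame:
    rows = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise PedFormatError(
                    f"{path}:{lineno}: expected 6 columns, found {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"],
    )
    df["phenotype"] = pd.to_numeric(df["phenotype"], errors="coerce")
    return df


def _parse_geno(
    path: Path, effect_allele: Sequence[str] | str
) -> tuple[dict[str, np.ndarray], int]:
    genotypes: dict[str, np.ndarray] = {}
    n_loci = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 4 or (len(fields) - 2) % 2 != 0:
                raise PedFormatError(
                    f"{path}:{lineno}: expected 2 id columns plus allele pairs"
                )
            alleles = fields[2:]
            loci = len(alleles) // 2
            if n_loci is None:
                n_loci = loci
                eff = (
                    [str(effect_allele)] * loci
                    if isinstance(effect_allele, str)
                    else [str(a) for a in effect_allele]
                )
                if len(eff) != loci:
                    raise PedFormatError(
                        f"{path}: {loci} loci but {len(eff)} effect alleles declared"
                    )
            elif loci != n_loci:
                raise PedFormatError(
                    f"{path}:{lineno}: {loci} loci, expected {n_loci}"
                )
            g = np.empty(loci, dtype=np.int8)
            for j in range(loci):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    g[j] = MISSING
                else:
                    g[j] = (a1 == eff[j]) + (a2 == eff[j])
            genotypes[fields[1]] = g
    if n_loci is None:
        raise PedFormatError(f"{path}: no genotype rows")
    return genotypes, n_loci


def read_ped(
    fam_path: str | Path,
    geno_path: str | Path,
    effect_allele: Sequence[str] | str = "2",
    truth_path: str | Path | None = None,
) -> TrioCohort:
    """Assemble a trio cohort from pedigree and genotype files.

    ``effect_allele`` declares, per locus (or one code for all loci), which
    allele is counted; flipping the declaration maps g to 2 - g and negates
    every association slope. Children lacking a genotyped mother or father
    are excluded, with the count logged. ``truth_path`` optionally restores
    population labels and realized deviations written by :func:`write_ped`.
    """
    fam = _parse_fam(Path(fam_path))
    genotypes, n_loci = _parse_geno(Path(geno_path), effect_allele)

    children = fam[(fam["father_id"] != "0") & (fam["mother_id"] != "0")]
    rows, g_c, g_m, g_f = [], [], [], []
    excluded = 0
    child_counter: dict[str, int] = {}
    for _, row in children.iterrows():
        cid, mid, fid = row["individual_id"], row["mother_id"], row["father_id"]
        if cid not in genotypes or mid not in genotypes or fid not in genotypes:
            excluded += 1
            logger.warning(
                "excluding child %s: parent or child genotypes missing", cid
            )
            continue
        famid = row["family_id"]
        k = child_counter.get(famid, 0)
        child_counter[famid] = k + 1
        rows.append(
            {
                "family_id": famid,
                "child_id": k,
                "individual_id": cid,
                "population": "unknown",
                "phenotype": row["phenotype"],
            }
        )
        g_c.append(genotypes[cid])
        g_m.append(genotypes[mid])
        g_f.append(genotypes[fid])
    if excluded:
        logger.info("excluded %d children without two genotyped parents", excluded)
    if not rows:
        frame = pd.DataFrame(
            columns=["family_id", "child_id", "individual_id", "population", "phenotype"]
        )
        empty = np.empty((0, n_loci), dtype=np.int8)
        return TrioCohort(frame, empty, empty.copy(), empty.copy(),
                          [f"locus{j}" for j in range(n_loci)])

    frame = pd.DataFrame(rows)
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep="\t", dtype={"family_id": str})
        frame = frame.merge(
            truth, on=["family_id", "individual_id"], how="left", validate="1:1"
        )
        if "population_y" in frame.columns:  # truth wins over the placeholder
            frame["population"] = frame.pop("population_y")
            frame = frame.drop(columns=["population_x"])
    frame = frame.drop(columns=["individual_id"])

    cohort = TrioCohort(
        fam=frame,
        g_child=np.vstack(g_c),
        g_mother=np.vstack(g_m),
        g_father=np.vstack(g_f),
        locus_ids=[f"locus{j}" for j in range(n_loci)],
    )
    missing = int(np.sum(cohort.g_child == MISSING))
    if missing:
        logger.info("%d missing child genotypes; affected trios are dropped per locus", missing)
    return cohort
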