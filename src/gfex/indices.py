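"""Per-genome gene-family-extension (GFE) measures.

For a genome whose present gene families have sizes ``s_1 .. s_{K'}``
(every ``s_j ≥ 1``; absent families are ignored), the package computes

* ``ave`` — mean family size, ``(Σ s_j) / K'``.  Singletons are included in
  the average; an option excludes them for comparison with older work that
  averaged over paralogous families only.
* ``p.i.`` — the paralog index, ``P / K'``, where ``P`` is the number of
  non-singleton families (size ≥ 2).  The fraction of a genome's families
  that have undergone any duplication.
* ``mp`` — the multi-paralog index, ``P2 / P``, where ``P2`` counts families
  with more than two copies.  Among duplicated families, the relative
  frequency of the larger ones.  Undefined when the genome has no
  non-singleton family (``P = 0``); batch output records it as missing.

These quantities summarise how far each genome's gene complement has been
extended by duplication, and are later related to genome size.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import GeneFamilyMatrix

__all__ = [
    "GFEProfile",
    "family_counts",
    "average_family_size",
    "paralog_index",
    "multi_paralog_index",
    "profile_for",
    "profile_from_histogram",
    "gfe_profile_table",
]

PROFILE_COLUMNS = ["genome_id", "K_prime", "P", "P2", "ave", "p_i", "mp"]


@dataclasses.dataclass(frozen=True)
class GFEProfile:
    """All derived family-size quantities for one genome.

    ``mp`` is ``None`` when the genome has no non-singleton family.
    """

    genome_id: str
    k_prime: int
    p: int
    p2: int
    ave: float
    p_i: float
    mp: Optional[float]

    def __post_init__(self) -> None:
        if not (0 <= self.p2 <= self.p <= self.k_prime):
            raise ValueError(
                f"{self.genome_id}: require P2 <= P <= K' "
                f"(got {self.p2}, {self.p}, {self.k_prime})"
            )


def family_counts(row: np.ndarray) -> tuple[int, int, int, int]:
    """Return ``(K', P, P2, total_copies)`` for one genome row.

    K' — families present (nonzero entries); P — families of size ≥ 2;
    P2 — families of size > 2; total_copies — sum of all entries.
    """
    sizes = row[row > 0]
    return (
        int(sizes.size),
        int((sizes >= 2).sum()),
        int((sizes > 2).sum()),
        int(sizes.sum()),
    )


def average_family_size(
    matrix: GeneFamilyMatrix, genome_id: str, include_singletons: bool = True
) -> float:
    """Mean size of the genome's present gene families.

    With ``include_singletons=False`` the average runs over paralogous
    (size ≥ 2) families only, which requires at least one such family.
    """
    row = matrix.row(genome_id)
    sizes = row[row > 0]
    if not include_singletons:
        sizes = sizes[sizes >= 2]
        if sizes.size == 0:
            raise ValueError(
                f"{genome_id}: no non-singleton family; singleton-free average undefined"
            )
    return float(sizes.sum() / sizes.size)


def paralog_index(matrix: GeneFamilyMatrix, genome_id: str) -> float:
    """Fraction of the genome's families that are non-singletons (P / K')."""
    k_prime, p, _, _ = family_counts(matrix.row(genome_id))
    return p / k_prime


def multi_paralog_index(matrix: GeneFamilyMatrix, genome_id: str) -> Optional[float]:
    """Among non-singleton families, the fraction with > 2 copies (P2 / P).

    Returns ``None`` for an all-singleton genome (P = 0), where the ratio
    is undefined.
    """
    _, p, p2, _ = family_counts(matrix.row(genome_id))
    if p == 0:
        return None
    return p2 / p


def profile_for(matrix: GeneFamilyMatrix, genome_id: str) -> GFEProfile:
    k_prime, p, p2, total = family_counts(matrix.row(genome_id))
    return GFEProfile(
        genome_id=genome_id,
        k_prime=k_prime,
        p=p,
        p2=p2,
        ave=total / k_prime,
        p_i=p / k_prime,
        mp=(p2 / p) if p > 0 else None,
    )


def profile_from_histogram(
    genome_id: str,
    n1: int,
    n2: int,
    n3: int,
    n_gt3: int,
    total_copies: Optional[int] = None,
) -> GFEProfile:
    """Build a profile from a binned family-size distribution.

    Published family-size tables often report only the counts of families of
    size 1, 2, 3 and > 3 together with the total number of COG-annotated
    proteins.  That is enough for K', P, P2, p.i. and mp exactly, and — when
    ``total_copies`` is given — for ``ave`` as total copies over total
    families.
    """
    if min(n1, n2, n3, n_gt3) < 0:
        raise ValueError("histogram bins must be nonnegative")
    k_prime = n1 + n2 + n3 + n_gt3
    if k_prime == 0:
        raise ValueError(f"{genome_id}: empty family-size histogram")
    p = n2 + n3 + n_gt3
    p2 = n3 + n_gt3
    ave = math.nan if total_copies is None else total_copies / k_prime
    return GFEProfile(
        genome_id=genome_id,
        k_prime=k_prime,
        p=p,
        p2=p2,
        ave=ave,
        p_i=p / k_prime,
        mp=(p2 / p) if p > 0 else None,
    )


def gfe_profile_table(matrix: GeneFamilyMatrix) -> pd.DataFrame:
    """One profile row per genome, in matrix order.

    Columns: genome_id, K_prime, P, P2, ave, p_i, mp.  ``mp`` is NaN where
    undefined (all-singleton genome).
    """
    records = []
    for g in matrix.genome_ids:
        pr = profile_for(matrix, g)
        records.append(
            (pr.genome_id, pr.k_prime, pr.p, pr.p2, pr.ave, pr.p_i,
             np.nan if pr.mp is None else pr.mp)
        )
    return pd.DataFrame(records, columns=PROFILE_COLUMNS)
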