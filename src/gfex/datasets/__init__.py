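"""Small packaged example tables.

* ``load_fictional_example`` — a 3-genome × 5-COG toy matrix on which the
  four GFE measures disagree about the genome order, plus a metadata table
  whose (synthetic) genome sizes realise the size order B < A < C.
* ``load_mycoplasma_family_sizes`` — published family-size distributions of
  32 Mycoplasmataceae genomes: counts of families of size 1, 2, 3 and > 3
  together with protein / ORFan / COG-annotated-protein totals.  Exact
  family sizes above 3 are not recoverable from the binned table, but K',
  P, P2, p.i. and mp are exact, and ave follows as NC / K'.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..indices import profile_from_histogram
from ..matrix import GeneFamilyMatrix, read_matrix, read_metadata

__all__ = [
    "load_fictional_example",
    "load_mycoplasma_family_sizes",
    "mycoplasma_profiles",
]


def _path(name: str):
    return resources.files(__package__) / name


def load_fictional_example() -> tuple[GeneFamilyMatrix, pd.DataFrame]:
    """The 3×5 worked-example matrix and its metadata table."""
    with resources.as_file(_path("table8_fictional.tsv")) as p:
        matrix = read_matrix(p, format="dense-tsv")
    with resources.as_file(_path("table8_metadata.tsv")) as p:
        metadata = read_metadata(p)
    return matrix, metadata


def load_mycoplasma_family_sizes() -> pd.DataFrame:
    """Binned family-size distributions of 32 Mycoplasmataceae genomes."""
    with resources.as_file(_path("table5_mycoplasma.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def mycoplasma_profiles() -> pd.DataFrame:
    """GFE profiles derived from the Mycoplasmataceae histogram table.

    Adds mp numerator/denominator columns (P2 and P) so the printed
    fractions can be checked exactly.
    """
    df = load_mycoplasma_family_sizes()
    records = []
    for r in df.itertuples(index=False):
        pr = profile_from_histogram(
            r.genome_id, r.fam1, r.fam2, r.fam3, r.fam_gt3,
            total_copies=r.n_cog_annotated,
        )
        records.append(
            {
                "genome_id": pr.genome_id,
                "K_prime": pr.k_prime,
                "P": pr.p,
                "P2": pr.p2,
                "ave": pr.ave,
                "p_i": pr.p_i,
                "mp": pr.mp,
                "mp_num": pr.p2,
                "mp_den": pr.p,
            }
        )
    return pd.DataFrame(records)
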