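"""Genome × COG gene-copy matrices and genome metadata.

The central object is a dense table of nonnegative integer counts: entry
(i, j) is the number of genes of genome *i* assigned to orthologous group
(COG) *j*, i.e. the size of that genome's gene family in the group.  A zero
means the family is absent from the genome; per-genome family statistics
ignore zeros throughout the package.

Two plain-text interchange formats are supported:

* dense TSV — header ``genome_id<TAB>cog1<TAB>cog2...``, one row per genome;
* triplet TSV — header ``genome_id<TAB>cog_id<TAB>count``, one row per
  nonzero entry (zeros are never stored).

Genome metadata (genome size in Mbp plus optional taxon labels) travels in a
separate TSV keyed by ``genome_id``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MatrixFormatError",
    "GeneFamilyMatrix",
    "read_matrix",
    "write_matrix",
    "family_size_histogram",
    "read_metadata",
    "write_metadata",
    "check_metadata_covers",
]

HISTOGRAM_BINS = ("1", "2", "3", ">3")


class MatrixFormatError(ValueError):
    """A matrix or metadata file (or in-memory table) failed validation."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = list(ids)
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise MatrixFormatError(f"duplicate {what} {x!r}")
        seen.add(x)
    return ids


@dataclasses.dataclass
class GeneFamilyMatrix:
    """Dense genome × COG gene-copy count matrix.

    Parameters
    ----------
    genome_ids
        Unique genome identifiers, one per row.
    cog_ids
        Unique COG identifiers, one per column.
    counts
        ``(n_genomes, n_cogs)`` array of nonnegative integers.  Every genome
        row must contain at least one nonzero entry: a genome without a
        single COG-annotated gene carries no family information and is
        rejected.
    """

    genome_ids: list[str]
    cog_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.genome_ids = _check_unique((str(g) for g in self.genome_ids), "genome id")
        self.cog_ids = _check_unique((str(c) for c in self.cog_ids), "COG id")
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise MatrixFormatError("counts must be a 2-D array")
        if counts.shape != (len(self.genome_ids), len(self.cog_ids)):
            raise MatrixFormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.genome_ids)} genomes × {len(self.cog_ids)} COGs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                raise MatrixFormatError("counts must be integral")
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            raise MatrixFormatError("counts must be nonnegative")
        empty = np.flatnonzero((counts > 0).sum(axis=1) == 0)
        if empty.size:
            bad = self.genome_ids[int(empty[0])]
            raise MatrixFormatError(
                f"genome {bad!r} has no nonzero COG count (all-zero row)"
            )
        self.counts = counts
        self._index = {g: i for i, g in enumerate(self.genome_ids)}

    # -- accessors ---------------------------------------------------------

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_cogs(self) -> int:
        return len(self.cog_ids)

    def genome_index(self, genome_id: str) -> int:
        try:
            return self._index[genome_id]
        except KeyError:
            raise KeyError(f"unknown genome id {genome_id!r}") from None

    def row(self, genome_id: str) -> np.ndarray:
        """Family-size vector of one genome (zeros = absent families)."""
        return self.counts[self.genome_index(genome_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.genome_ids), columns=list(self.cog_ids)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneFamilyMatrix):
            return NotImplemented
        return (
            self.genome_ids == other.genome_ids
            and self.cog_ids == other.cog_ids
            and np.array_equal(self.counts, other.counts)
        )


# -- file I/O --------------------------------------------------------------

_FORMATS = {"dense-tsv", "triplet-tsv"}


def _normalise_format(fmt: str) -> str:
    fmt = {"dense": "dense-tsv", "triplet": "triplet-tsv"}.get(fmt, fmt)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown matrix format {fmt!r}; expected one of {sorted(_FORMATS)}")
    return fmt


def read_matrix(path: str | Path, format: str = "dense-tsv") -> GeneFamilyMatrix:
    """Read and validate a gene-family matrix from a TSV file."""
    fmt = _normalise_format(format)
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    if fmt == "dense-tsv":
        return _read_dense(path, lines)
    return _read_triplet(path, lines)


def _read_dense(path, lines) -> GeneFamilyMatrix:
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2 or header[0] != "genome_id":
        raise MatrixFormatError(
            f"{path}:1: malformed header (expected 'genome_id<TAB>cog...', got {lines[0]!r})"
        )
    cog_ids = header[1:]
    genome_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise MatrixFormatError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        genome_ids.append(fields[0])
        rows.append([_parse_count(path, lineno, v) for v in fields[1:]])
    if not rows:
        raise MatrixFormatError(f"{path}: no genome rows")
    try:
        return GeneFamilyMatrix(genome_ids, cog_ids, np.array(rows, dtype=np.int64).reshape(len(rows), len(cog_ids)))
    except MatrixFormatError as e:
        raise MatrixFormatError(f"{path}: {e}") from None


def _read_triplet(path, lines) -> GeneFamilyMatrix:
    header = lines[0].rstrip("\n").split("\t")
    if header != ["genome_id", "cog_id", "count"]:
        raise MatrixFormatError(
            f"{path}:1: malformed header (expected 'genome_id\\tcog_id\\tcount')"
        )
    entries: dict[tuple[str, str], int] = {}
    gi: dict[str, int] = {}  # first-appearance order
    ci: dict[str, int] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise MatrixFormatError(f"{path}:{lineno}: expected 3 fields, got {len(fields)}")
        g, c, raw = fields
        key = (g, c)
        if key in entries:
            raise MatrixFormatError(f"{path}:{lineno}: duplicate triplet for ({g!r}, {c!r})")
        entries[key] = _parse_count(path, lineno, raw)
        gi.setdefault(g, len(gi))
        ci.setdefault(c, len(ci))
    genome_ids = list(gi)
    cog_ids = list(ci)
    if not entries:
        raise MatrixFormatError(
            f"{path}: triplet body is empty — every genome needs at least one nonzero count"
        )
    counts = np.zeros((len(genome_ids), len(cog_ids)), dtype=np.int64)
    for (g, c), v in entries.items():
        counts[gi[g], ci[c]] = v
    try:
        return GeneFamilyMatrix(genome_ids, cog_ids, counts)
    except MatrixFormatError as e:
        raise MatrixFormatError(f"{path}: {e}") from None


def _parse_count(path, lineno: int, raw: str) -> int:
    try:
        value = int(raw)
    except ValueError:
        raise MatrixFormatError(f"{path}:{lineno}: non-integer count {raw!r}") from None
    if value < 0:
        raise MatrixFormatError(f"{path}:{lineno}: negative count {raw!r}")
    return value


def write_matrix(matrix: GeneFamilyMatrix, path: str | Path, format: str = "dense-tsv") -> None:
    """Write a matrix; ``read_matrix(write_matrix(m))`` is the identity."""
    fmt = _normalise_format(format)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if fmt == "dense-tsv":
            fh.write("genome_id\t" + "\t".join(matrix.cog_ids) + "\n")
            for g, row in zip(matrix.genome_ids, matrix.counts):
                fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
        else:
            fh.write("genome_id\tcog_id\tcount\n")
            for g, row in zip(matrix.genome_ids, matrix.counts):
                for c, v in zip(matrix.cog_ids, row):
                    if v > 0:
                        fh.write(f"{g}\t{c}\t{int(v)}\n")


# -- per-genome family-size histogram --------------------------------------

def family_size_histogram(matrix: GeneFamilyMatrix, genome_id: str) -> dict[str, int]:
    """Histogram of a genome's family sizes over bins 1 / 2 / 3 / >3.

    Only present families (nonzero entries) are counted; the bin totals sum
    to K′, the number of gene families in the genome.
    """
    row = matrix.row(genome_id)
    sizes = row[row > 0]
    return {
        "1": int((sizes == 1).sum()),
        "2": int((sizes == 2).sum()),
        "3": int((sizes == 3).sum()),
        ">3": int((sizes > 3).sum()),
    }


# -- genome metadata -------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a genome metadata TSV (genome_id, size_mbp, optional taxon cols)."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    for col in ("genome_id", "size_mbp"):
        if col not in df.columns:
            raise MatrixFormatError(f"{path}: metadata is missing required column {col!r}")
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].iloc[0]
        raise MatrixFormatError(f"{path}: duplicate genome id {dup!r} in metadata")
    sizes = pd.to_numeric(df["size_mbp"], errors="coerce")
    if sizes.isna().any() or (sizes <= 0).any():
        raise MatrixFormatError(f"{path}: size_mbp must be a positive number for every genome")
    df["size_mbp"] = sizes.astype(float)
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def check_metadata_covers(matrix: GeneFamilyMatrix, metadata: pd.DataFrame) -> None:
    """Require every matrix genome to have a metadata row."""
    missing = set(matrix.genome_ids) - set(metadata["genome_id"])
    if missing:
        raise MatrixFormatError(
            f"metadata is missing {len(missing)} genome(s), e.g. {sorted(missing)[0]!r}"
        )
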