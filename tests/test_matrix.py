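"""Matrix data model, file round-trips and family-size histograms."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gfex.matrix import (
    GeneFamilyMatrix,
    MatrixFormatError,
    family_size_histogram,
    read_matrix,
    read_metadata,
    write_matrix,
)

from conftest import random_matrix


# -- validation ------------------------------------------------------------

def test_rejects_all_zero_genome_row():
    with pytest.raises(MatrixFormatError, match="all-zero"):
        GeneFamilyMatrix(["g1", "g2"], ["c1"], np.array([[1], [0]]))


def test_rejects_negative_and_non_integral_counts():
    with pytest.raises(MatrixFormatError, match="nonnegative"):
        GeneFamilyMatrix(["g1"], ["c1", "c2"], np.array([[1, -2]]))
    with pytest.raises(MatrixFormatError, match="integral"):
        GeneFamilyMatrix(["g1"], ["c1", "c2"], np.array([[1.0, 2.5]]))


def test_rejects_duplicate_ids():
    with pytest.raises(MatrixFormatError, match="duplicate genome id"):
        GeneFamilyMatrix(["g1", "g1"], ["c1"], np.array([[1], [2]]))
    with pytest.raises(MatrixFormatError, match="duplicate COG id"):
        GeneFamilyMatrix(["g1"], ["c1", "c1"], np.array([[1, 2]]))


# -- file I/O --------------------------------------------------------------

def test_dense_read_of_fictional_fixture(fictional_matrix):
    m = fictional_matrix
    assert m.genome_ids == ["A", "B", "C"]
    assert m.n_cogs == 5
    assert m.counts[m.genome_index("A"), 4] == 16
    assert list(m.row("B")) == [1, 1, 2, 2, 4]


def test_triplet_reader_minimal_case(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("genome_id\tcog_id\tcount\ng1\tc1\t2\ng1\tc2\t1\n")
    m = read_matrix(p, format="triplet-tsv")
    assert (m.n_genomes, m.n_cogs) == (1, 2)
    assert m.counts.sum() == 3


def test_triplet_duplicate_entry_reports_line(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("genome_id\tcog_id\tcount\ng1\tc1\t2\ng1\tc1\t3\n")
    with pytest.raises(MatrixFormatError, match=r":3: duplicate"):
        read_matrix(p, format="triplet-tsv")


def test_empty_triplet_body_is_an_error(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text("genome_id\tcog_id\tcount\n")
    with pytest.raises(MatrixFormatError, match="empty"):
        read_matrix(p, format="triplet-tsv")


@pytest.mark.parametrize("bad,msg", [
    ("genome\tc1\ng1\t1\n", "malformed header"),
    ("genome_id\tc1\ng1\t-1\n", "negative count"),
    ("genome_id\tc1\ng1\tx\n", "non-integer count"),
])
def test_dense_parse_errors_are_descriptive(tmp_path, bad, msg):
    p = tmp_path / "m.tsv"
    p.write_text(bad)
    with pytest.raises(MatrixFormatError, match=msg):
        read_matrix(p, format="dense-tsv")


@pytest.mark.parametrize("fmt", ["dense-tsv", "triplet-tsv"])
def test_fixture_round_trip(fictional_matrix, tmp_path, fmt):
    p = tmp_path / "m.tsv"
    write_matrix(fictional_matrix, p, format=fmt)
    assert read_matrix(p, format=fmt) == fictional_matrix


@given(seed=st.integers(0, 10_000))
def test_round_trip_identity_random_matrices(seed, tmp_path_factory):
    m = random_matrix(seed, n_genomes=7, n_cogs=11)
    tmp = tmp_path_factory.mktemp("rt")
    p = tmp / f"{seed}_dense.tsv"
    write_matrix(m, p, format="dense-tsv")
    assert read_matrix(p, format="dense-tsv") == m
    # the triplet format stores no zeros and orders axes by first appearance,
    # so the round trip is identity on the stored entries
    p2 = tmp / f"{seed}_triplet.tsv"
    write_matrix(m, p2, format="triplet-tsv")
    back = read_matrix(p2, format="triplet-tsv")
    df = back.to_frame().reindex(index=m.genome_ids, columns=m.cog_ids, fill_value=0)
    assert (df.to_numpy() == m.counts).all()


def test_sparse_round_trip_and_format_equivalence(tmp_path):
    rng = np.random.default_rng(5)
    counts = (rng.random((50, 100)) < 0.1) * rng.integers(1, 9, size=(50, 100))
    counts[counts.sum(axis=1) == 0, 0] = 1
    m = GeneFamilyMatrix([f"g{i}" for i in range(50)], [f"c{j}" for j in range(100)], counts)
    write_matrix(m, tmp_path / "d.tsv", format="dense-tsv")
    write_matrix(m, tmp_path / "t.tsv", format="triplet-tsv")
    dense = read_matrix(tmp_path / "d.tsv", format="dense-tsv")
    triplet = read_matrix(tmp_path / "t.tsv", format="triplet-tsv")
    assert dense == m
    # triplet loses columns that are zero everywhere and follows appearance
    # order, so compare entries through the dense frame
    df = triplet.to_frame().reindex(index=m.genome_ids, columns=m.cog_ids, fill_value=0)
    assert (df.to_numpy() == m.counts).all()


# -- histograms ------------------------------------------------------------

@pytest.mark.parametrize("row,expected", [
    ([1, 1, 1, 1, 16], {"1": 4, "2": 0, "3": 0, ">3": 1}),
    ([1, 1, 1], {"1": 3, "2": 0, "3": 0, ">3": 0}),
    ([2, 3, 4, 4], {"1": 0, "2": 1, "3": 1, ">3": 2}),
])
def test_family_size_histogram_bins(row, expected):
    m = GeneFamilyMatrix(["g"], [f"c{j}" for j in range(len(row))], np.array([row]))
    assert family_size_histogram(m, "g") == expected


@given(seed=st.integers(0, 10_000))
def test_histogram_bins_sum_to_k_prime(seed):
    m = random_matrix(seed, n_genomes=4, n_cogs=20)
    for g in m.genome_ids:
        hist = family_size_histogram(m, g)
        assert sum(hist.values()) == int((m.row(g) > 0).sum())


def test_histogram_unknown_genome(fictional_matrix):
    with pytest.raises(KeyError, match="unknown genome"):
        family_size_histogram(fictional_matrix, "Z")


def test_mycoplasma_fixture_reproduces_all_printed_bins(mycoplasma):
    from gfex.datasets import load_mycoplasma_family_sizes

    raw = load_mycoplasma_family_sizes()
    assert len(raw) == 32
    # spot-check a few rows against the published bin counts
    row = raw.set_index("genome_id")
    assert list(row.loc["M_fermentans_M64", ["fam1", "fam2", "fam3", "fam_gt3"]]) == [383, 35, 11, 18]
    assert list(row.loc["M_genitalium_G37", ["fam1", "fam2", "fam3", "fam_gt3"]]) == [330, 15, 4, 3]
    assert list(row.loc["U_urealyticum_serovar_10_ATCC_33699", ["fam1", "fam2", "fam3", "fam_gt3"]]) == [342, 25, 3, 2]
    # bins are internally consistent with the derived profiles
    prof = mycoplasma.set_index("genome_id")
    assert (prof["K_prime"] == raw.set_index("genome_id")[["fam1", "fam2", "fam3", "fam_gt3"]].sum(axis=1)).all()


# -- metadata --------------------------------------------------------------

def test_metadata_validation(tmp_path):
    p = tmp_path / "meta.tsv"
    p.write_text("genome_id\tsize_mbp\ng1\t2.5\ng2\t0\n")
    with pytest.raises(MatrixFormatError, match="positive"):
        read_metadata(p)
    p.write_text("genome_id\tsize_mbp\ng1\t2.5\ng1\t3.0\n")
    with pytest.raises(MatrixFormatError, match="duplicate"):
        read_metadata(p)
    p.write_text("genome_id\tsize_mbp\ttaxon\ng1\t2.5\tMollicutes\n")
    df = read_metadata(p)
    assert df.loc[0, "taxon"] == "Mollicutes"
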