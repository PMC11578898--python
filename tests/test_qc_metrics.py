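import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from autoqc import (
    AlignmentError,
    AuxiliaryCellData,
    GeneSetConfig,
    METRIC_COLUMNS,
    PopulationSpec,
    compute_qc_metrics,
    generate_sample,
)

from conftest import make_counts


def brute_force_top_n(row: np.ndarray, n: int) -> float:
    """Independent sort-and-sum oracle for percent_top50."""
    total = row.sum()
    if total == 0:
        return math.nan
    return 100.0 * np.sort(row)[::-1][:n].sum() / total


def test_two_gene_cell_closed_form():
    counts = make_counts([[90, 10]], gene_ids=["MT-CO1", "GENEB"])
    m = compute_qc_metrics(counts)
    assert m["percent_mito"].iloc[0] == pytest.approx(90.0)
    assert m["log1p_n_counts"].iloc[0] == pytest.approx(math.log(101))
    assert m["percent_top50"].iloc[0] == 100.0  # <= 50 genes expressed


def test_uniform_sixty_genes_top50():
    counts = make_counts(np.ones((1, 60), dtype=int))
    m = compute_qc_metrics(counts)
    assert m["percent_top50"].iloc[0] == pytest.approx(100 * 50 / 60)


def test_gene_permutation_leaves_metrics_unchanged():
    rng = np.random.default_rng(0)
    arr = rng.poisson(2, (30, 80))
    genes = [f"MT-{j}" if j < 5 else f"G{j}" for j in range(80)]
    m1 = compute_qc_metrics(make_counts(arr, gene_ids=genes))
    perm = rng.permutation(80)
    m2 = compute_qc_metrics(
        make_counts(arr[:, perm], gene_ids=[genes[j] for j in perm])
    )
    np.testing.assert_allclose(m1[METRIC_COLUMNS[:6]], m2[METRIC_COLUMNS[:6]])


def test_cell_permutation_permutes_rows():
    rng = np.random.default_rng(1)
    arr = rng.poisson(2, (25, 40))
    m1 = compute_qc_metrics(make_counts(arr))
    perm = rng.permutation(25)
    m2 = compute_qc_metrics(
        make_counts(arr[perm], cell_ids=[f"C{i}" for i in perm])
    )
    np.testing.assert_allclose(
        m1.iloc[perm][METRIC_COLUMNS[:6]].to_numpy(), m2[METRIC_COLUMNS[:6]].to_numpy()
    )


def test_doubling_counts_scale_invariance():
    rng = np.random.default_rng(2)
    arr = rng.poisson(3, (10, 60)) + 1
    genes = [f"MT-{j}" if j < 4 else f"G{j}" for j in range(60)]
    m1 = compute_qc_metrics(make_counts(arr, gene_ids=genes))
    m2 = compute_qc_metrics(make_counts(2 * arr, gene_ids=genes))
    for col in ["percent_mito", "percent_ribo", "percent_hb", "percent_top50"]:
        np.testing.assert_allclose(m1[col], m2[col])
    assert (m2["log1p_n_counts"] > m1["log1p_n_counts"]).all()


def test_absent_aux_metrics_are_missing_not_zero():
    m = compute_qc_metrics(make_counts([[5, 5]]))
    assert np.isnan(m["percent_soup"].iloc[0])
    assert np.isnan(m["percent_spliced"].iloc[0])


def test_spliced_and_soup_from_aux():
    aux = AuxiliaryCellData(
        spliced_total=np.array([75.0, 0.0]),
        unspliced_total=np.array([25.0, 0.0]),
        soup_fraction=np.array([0.2, 0.5]),
    )
    m = compute_qc_metrics(make_counts([[5, 5], [3, 3]]), aux)
    assert m["percent_spliced"].iloc[0] == pytest.approx(75.0)
    assert np.isnan(m["percent_spliced"].iloc[1])  # 0/0 -> missing
    np.testing.assert_allclose(m["percent_soup"], [20.0, 50.0])


def test_zero_count_cell_flagged_invalid():
    m = compute_qc_metrics(make_counts([[0, 0], [1, 1]]))
    assert not m["valid"].iloc[0] and m["valid"].iloc[1]
    assert np.isnan(m["percent_mito"].iloc[0])


def test_misaligned_aux_raises():
    with pytest.raises(AlignmentError):
        compute_qc_metrics(
            make_counts([[1, 2]]), AuxiliaryCellData(soup_fraction=np.array([0.1, 0.2]))
        )


def test_soup_fraction_out_of_range_raises():
    with pytest.raises(AlignmentError):
        compute_qc_metrics(
            make_counts([[1, 2]]), AuxiliaryCellData(soup_fraction=np.array([1.5]))
        )


def test_planted_mito_fraction_recovered():
    """200 cells with mito fractions drawn Beta(16, 24) (mean 40%): the
    realized mean percent_mito stays within 5 points of 40."""
    sample = generate_sample(
        [PopulationSpec("high_mito", 200, (7.8, 0.4), (16, 24))], seed=3
    )
    m = compute_qc_metrics(sample.counts)
    assert abs(m["percent_mito"].mean() - 40.0) < 5.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    arr=hnp.arrays(
        dtype=np.int64,
        shape=st.tuples(st.integers(1, 8), st.integers(1, 120)),
        elements=st.integers(0, 50),
    ),
    top_n=st.integers(1, 60),
)
def test_percent_top_n_matches_bruteforce_oracle(arr, top_n):
    m = compute_qc_metrics(make_counts(arr), genesets=GeneSetConfig(top_n=top_n))
    for i in range(arr.shape[0]):
        expected = brute_force_top_n(arr[i], top_n)
        got = m["percent_top50"].iloc[i]
        if math.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected)


def test_disjoint_gene_set_percentages_bounded(standard_sample):
    m = compute_qc_metrics(standard_sample.counts)
    total = m["percent_mito"] + m["percent_ribo"] + m["percent_hb"]
    assert (total <= 100 + 1e-9).all()
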