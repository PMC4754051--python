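"""RNA-seq QC filters, size factors, FPKM and the DE post-filter."""

import numpy as np
import pandas as pd
import pytest

from corticell.io_ct import CountMatrix, GeneAnnotation
from corticell.scrnaseq import (
    DEPostFilterRule,
    cell_qc,
    de_post_filter,
    detectable_genes,
    fpkm,
    mito_fraction,
    n_detected_genes,
    pooled_vs_bulk_corr,
    ranksum_de_flags,
    size_factors,
)
from corticell.simdata import simulate_counts


def _counts(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return CountMatrix(pd.DataFrame(arr, index=genes, columns=cells))


def _ann(genes, mito=None, length=1000.0):
    mito = mito or []
    return GeneAnnotation(pd.DataFrame(
        {"is_mito": [g in mito for g in genes],
         "length_bp": [length] * len(genes)},
        index=pd.Index(genes, name="gene_id"),
    ))


def test_detectable_genes_definitional():
    m = _counts([[0, 1], [2, 0], [0, 0]])
    det = detectable_genes(m)
    assert det["c0"] == frozenset({"g1"})
    assert det["c1"] == frozenset({"g0"})
    nz = (m.counts > 0).sum(axis=0)
    assert (n_detected_genes(m) == nz).all()


def test_identical_cells_all_pass():
    m = _counts(np.full((20, 10), 5))
    ann = _ann(list(m.gene_ids))
    report = cell_qc(m, ann)
    assert report["pass"].all()
    assert (report["fail_reasons"] == "").all()


def test_mito_fraction_boundary_is_strict():
    # cell with exactly 15% mito counts passes the mito filter
    arr = np.full((20, 6), 10)
    genes = [f"g{i}" for i in range(20)]
    m = _counts(arr, genes=genes)
    ann = _ann(genes, mito=["g0", "g1", "g2"])  # 3/20 = 0.15 exactly
    frac = mito_fraction(m, ann)
    assert frac.iloc[0] == pytest.approx(0.15)
    report = cell_qc(m, ann)
    assert not report["high_mito"].any()


def test_planted_high_mito_cell_flagged():
    rng = np.random.default_rng(0)
    arr = rng.poisson(10, size=(50, 12))
    genes = [f"g{i}" for i in range(50)]
    m0 = arr.copy()
    m0[:5, 0] = 200  # cell c0: mito-heavy
    m = _counts(m0, genes=genes)
    ann = _ann(genes, mito=genes[:5])
    report = cell_qc(m, ann)
    assert report.loc["c0", "high_mito"]
    assert "high_mito" in report.loc["c0", "fail_reasons"]
    assert not report.loc["c1":, "high_mito"].any()


def test_cell_qc_needs_four_cells():
    m = _counts(np.full((10, 3), 5))
    with pytest.raises(ValueError, match="4 cells"):
        cell_qc(m, _ann(list(m.gene_ids)))


def test_cell_qc_stable_under_reordering(sim_counts_outliers):
    counts, ann, _ = sim_counts_outliers
    rep = cell_qc(counts, ann)
    rev = CountMatrix(counts.counts.iloc[::-1, ::-1])
    rep2 = cell_qc(rev, ann)
    pd.testing.assert_frame_equal(rep.sort_index(), rep2.sort_index())


def test_size_factors_identical_cells_unity():
    m = _counts(np.full((30, 5), 7))
    sf = size_factors(m)
    np.testing.assert_allclose(sf, 1.0)


def test_size_factors_doubling_cell():
    base = np.arange(1, 31).reshape(-1, 1)
    m = _counts(np.hstack([base, 2 * base]))
    sf = size_factors(m)
    assert sf["c1"] / sf["c0"] == pytest.approx(2.0)


def test_size_factors_scale_equivariant():
    # factors are defined up to a global constant (the geometric means
    # rescale), so equivariance is exact on factor ratios
    counts, _, _ = simulate_counts(10, 200, seed=3)
    sf = size_factors(counts)
    scaled = counts.counts.copy()
    scaled.iloc[:, 0] *= 3
    sf2 = size_factors(CountMatrix(scaled))
    np.testing.assert_allclose(
        (sf2.iloc[0] / sf2.iloc[1:]).to_numpy(),
        3.0 * (sf.iloc[0] / sf.iloc[1:]).to_numpy(),
        rtol=1e-12,
    )


def test_size_factors_brute_force_oracle():
    rng = np.random.default_rng(4)
    arr = rng.poisson(20, size=(50, 10)) + 1  # all nonzero
    m = _counts(arr)
    sf = size_factors(m)
    # direct median-of-ratios from the definition
    geomean = np.exp(np.mean(np.log(arr), axis=1))
    expected = np.median(arr / geomean[:, None], axis=0)
    np.testing.assert_allclose(sf.to_numpy(), expected, rtol=1e-12)


def test_size_factors_error_without_common_gene():
    arr = np.array([[1, 0], [0, 1]])
    with pytest.raises(ValueError, match="pseudocount"):
        size_factors(_counts(arr))
    sf = size_factors(_counts(arr), pseudocount=1.0)
    assert (sf > 0).all()


def test_size_factors_true_three_cell_ratio():
    base = np.arange(1, 101).reshape(-1, 1)
    m = _counts(np.hstack([base, base, 2 * base]))
    sf = size_factors(m)
    np.testing.assert_allclose(sf / sf.iloc[0], [1.0, 1.0, 2.0])


def test_fpkm_unit_case_and_length_scaling():
    genes = ["a", "b"]
    m = _counts([[100, 100], [999_900, 999_900]], genes=genes)
    ann = GeneAnnotation(pd.DataFrame(
        {"is_mito": [False, False], "length_bp": [1000.0, 2000.0]},
        index=pd.Index(genes, name="gene_id"),
    ))
    out = fpkm(m, ann)
    # library = 1e6 fragments, count 100, length 1 kb -> FPKM 100
    assert out.loc["a", "c0"] == pytest.approx(100.0)
    # doubling length halves FPKM
    assert out.loc["b", "c0"] == pytest.approx(999_900 / 2, rel=1e-6)


def test_fpkm_conservation_identity():
    counts, ann, _ = simulate_counts(8, 100, seed=6)
    out = fpkm(counts, ann)
    length_kb = ann.length_bp.reindex(counts.gene_ids) / 1000.0
    totals = counts.counts.sum(axis=0)
    recon = (out.mul(length_kb, axis=0)).sum(axis=0) * totals / 1e6
    np.testing.assert_allclose(recon, totals, rtol=1e-9)


def test_fpkm_zero_total_cell_errors():
    m = _counts([[0], [0]])
    with pytest.raises(ValueError, match="zero total"):
        fpkm(m, _ann(list(m.gene_ids)))


@pytest.mark.parametrize(
    "fr_a,fr_b,mu_a,mu_b,kept",
    [
        (0.5, 0.1, 10.0, 1.0, True),    # concordant decrease
        (0.5, 0.1, 1.0, 10.0, False),   # discordant directions
        (0.05, 0.08, 0.5, 0.9, False),  # no group passes abundance gate
        (0.5, 0.5, 10.0, 1.0, False),   # zero detection change fails concordance
    ],
)
def test_de_post_filter_rules(fr_a, fr_b, mu_a, mu_b, kept):
    table = pd.DataFrame(
        {"mean_fpkm_a": [mu_a], "mean_fpkm_b": [mu_b],
         "detect_frac_a": [fr_a], "detect_frac_b": [fr_b],
         "significant": [True]},
        index=["gene"],
    )
    retained = de_post_filter(table)
    assert ("gene" in retained) is kept


def test_de_post_filter_monotone_in_fpkm_threshold():
    rng = np.random.default_rng(5)
    n = 200
    table = pd.DataFrame(
        {"mean_fpkm_a": rng.lognormal(0, 1, n),
         "mean_fpkm_b": rng.lognormal(0, 1, n),
         "detect_frac_a": rng.random(n),
         "detect_frac_b": rng.random(n),
         "significant": rng.random(n) < 0.5},
        index=[f"g{i}" for i in range(n)],
    )
    prev = None
    for thr in [0.5, 1.0, 2.0, 4.0]:
        kept = set(de_post_filter(table, DEPostFilterRule(min_mean_fpkm=thr)))
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_de_post_filter_missing_columns():
    with pytest.raises(ValueError, match="missing columns"):
        de_post_filter(pd.DataFrame({"mean_fpkm_a": [1.0]}))


def test_ranksum_flags_feed_post_filter():
    rng = np.random.default_rng(7)
    n_genes, n_cells = 60, 40
    base = rng.lognormal(1, 0.3, size=(n_genes, n_cells))
    base[:10, n_cells // 2:] *= 8  # first 10 genes up in group b ...
    drop = rng.random((10, n_cells // 2)) < 0.5
    base[:10, : n_cells // 2][drop] = 0.0  # ... and detected less in group a
    mat = pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                       columns=[f"c{j}" for j in range(n_cells)])
    groups = pd.Series(["a"] * (n_cells // 2) + ["b"] * (n_cells // 2),
                       index=mat.columns)
    de = ranksum_de_flags(mat, groups)
    kept = de_post_filter(de)
    assert set(kept) >= {f"g{i}" for i in range(5)}


def test_pooled_vs_bulk_affine_transform_r_one():
    rng = np.random.default_rng(8)
    single = pd.DataFrame(rng.lognormal(0, 1, size=(30, 6)),
                          index=[f"g{i}" for i in range(30)])
    pooled = single.mean(axis=1)
    bulk = 3.0 * pooled + 2.0
    r, p = pooled_vs_bulk_corr(single, bulk)
    assert r == pytest.approx(1.0)
    assert p < 1e-10


def test_pooled_vs_bulk_noise_recovers_target_r():
    rng = np.random.default_rng(9)
    n_genes = 90
    pooled_true = rng.normal(0, 1, n_genes)
    # noise sd chosen for correlation ~0.75: r = 1/sqrt(1+sd^2), sd ~ 0.88
    bulk = pooled_true + rng.normal(0, 0.88, n_genes)
    single = pd.DataFrame(
        {f"c{j}": pooled_true for j in range(5)},
        index=[f"g{i}" for i in range(n_genes)],
    )
    r, _ = pooled_vs_bulk_corr(single, pd.Series(bulk, index=single.index))
    assert r == pytest.approx(0.75, abs=0.1)


def test_pooled_vs_bulk_needs_shared_genes():
    single = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
    bulk = pd.Series([1.0], index=["a"])
    with pytest.raises(ValueError, match="shared"):
        pooled_vs_bulk_corr(single, bulk)
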