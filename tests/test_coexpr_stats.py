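"""Permutation co-expression tests, BH, PCA and cluster separation."""

import math

import numpy as np
import pandas as pd
import pytest

from corticell.coexpr_stats import (
    bh_adjust,
    cluster_separation_test,
    pairwise_corr,
    pca,
    perm_corr_test,
)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Step-up BH computed directly from the definition (test oracle)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return np.minimum(q, 1.0)


def test_pairwise_corr_basics():
    df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10]})
    df["neg"] = -df["x"]
    corr = pairwise_corr(df)
    assert corr.loc["x", "x"] == pytest.approx(1.0)
    assert corr.loc["x", "y"] == pytest.approx(1.0)
    assert corr.loc["x", "neg"] == pytest.approx(-1.0)


def test_pairwise_corr_zero_variance_undefined():
    df = pd.DataFrame({"x": [1.0, 2, 3], "const": [5.0, 5, 5]})
    corr = pairwise_corr(df)
    assert np.isnan(corr.loc["x", "const"])


def test_pairwise_corr_needs_three_wells():
    df = pd.DataFrame({"x": [1.0, 2], "y": [2.0, 4]})
    with pytest.raises(ValueError, match="3 wells"):
        pairwise_corr(df)


def test_exhaustive_perfect_pair_is_2_over_24():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
    res = perm_corr_test(df, [("a", "b")], mode="exhaustive")
    assert res.loc[0, "p_emp"] == pytest.approx(2 / 24)
    assert res.loc[0, "n_perm"] == math.factorial(4)


def test_sampled_determinism_and_floor():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
    r1 = perm_corr_test(df, [("a", "b")], n_perm=500, seed=42)
    r2 = perm_corr_test(df, [("a", "b")], n_perm=500, seed=42)
    pd.testing.assert_frame_equal(r1, r2)
    assert r1.loc[0, "p_emp"] >= 1 / 501


def test_zero_variance_pair_not_evaluable_excluded_from_bh():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3],
                       "const": [7.0, 7, 7, 7]})
    res = perm_corr_test(df, [("a", "b"), ("a", "const")], n_perm=100, seed=0)
    assert not res.loc[1, "evaluable"]
    assert np.isnan(res.loc[1, "q"])
    assert res.loc[0, "q"] == pytest.approx(res.loc[0, "p_emp"])  # family of 1


def test_p_emp_monotone_in_observed_correlation():
    """Stronger observed correlation never gets a larger empirical p at
    fixed n and seed."""
    n = 40
    rng = np.random.default_rng(5)
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    ps = []
    for w in [0.0, 0.3, 0.6, 0.9, 1.0]:
        y = w * x + (1 - w) * noise
        df = pd.DataFrame({"x": x, "y": y})
        res = perm_corr_test(df, [("x", "y")], n_perm=2000, seed=9)
        ps.append(res.loc[0, "p_emp"])
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


def test_sampled_matches_exhaustive_small_n():
    rng = np.random.default_rng(2)
    for n in (4, 5, 6):
        df = pd.DataFrame(rng.normal(size=(n, 2)), columns=["a", "b"])
        exact = perm_corr_test(df, [("a", "b")], mode="exhaustive")
        sampled = perm_corr_test(df, [("a", "b")], n_perm=50_000, seed=3)
        assert sampled.loc[0, "p_emp"] == pytest.approx(
            exact.loc[0, "p_emp"], abs=0.01
        )


def test_null_pairs_rejection_rate_calibrated():
    rng = np.random.default_rng(17)
    n_pairs = 300
    hits = 0
    for i in range(n_pairs):
        df = pd.DataFrame(rng.normal(size=(50, 2)), columns=["x", "y"])
        p = perm_corr_test(df, [("x", "y")], n_perm=400, seed=i).loc[0, "p_emp"]
        hits += p <= 0.05
    rate = hits / n_pairs
    # binomial 95% envelope around 0.05 at 300 draws
    assert 0.025 <= rate <= 0.08


@pytest.mark.parametrize("trial", range(5))
def test_bh_matches_brute_force(trial):
    rng = np.random.default_rng(100 + trial)
    m = int(rng.integers(1, 21))
    p = rng.random(m)
    np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


def test_pca_line_explains_everything():
    t = np.linspace(0, 1, 10)
    df = pd.DataFrame({"g1": 2 * t, "g2": -3 * t})
    res = pca(df, n_components=2)
    assert res.variance_explained[0] == pytest.approx(1.0)


def test_pca_rotation_invariant_spectrum():
    rng = np.random.default_rng(8)
    x = rng.normal(size=(40, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
    q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
    a = pca(pd.DataFrame(x), 4).variance_explained
    b = pca(pd.DataFrame(x @ q), 4).variance_explained
    np.testing.assert_allclose(a, b, atol=1e-10)


def test_pca_agrees_with_covariance_eigendecomposition():
    rng = np.random.default_rng(12)
    x = rng.normal(size=(10, 6))
    res = pca(pd.DataFrame(x), 3)
    cov = np.cov(x, rowvar=False)
    eigvals = np.sort(np.linalg.eigvalsh(cov))[::-1]
    expected = eigvals[:3] / eigvals.sum()
    np.testing.assert_allclose(res.variance_explained, expected, atol=1e-10)


def test_pca_constant_matrix_errors():
    df = pd.DataFrame(np.ones((5, 3)))
    with pytest.raises(ValueError, match="variance"):
        pca(df)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(20, 5)))
    a = pca(df, 2)
    b = pca(df.iloc[:, :], 2)
    pd.testing.assert_frame_equal(a.scores, b.scores)
    for k in ["PC1", "PC2"]:
        j = a.loadings[k].abs().idxmax()
        assert a.loadings.loc[j, k] > 0


def _two_groups(rng, sep=0.0, n=50):
    pts = np.vstack([
        rng.normal([0, 0], 1.0, size=(n, 2)),
        rng.normal([sep, 0], 1.0, size=(n, 2)),
    ])
    scores = pd.DataFrame(pts, columns=["PC1", "PC2"],
                          index=[f"c{i}" for i in range(2 * n)])
    labels = pd.Series(["a"] * n + ["b"] * n, index=scores.index)
    return scores, labels


def test_cluster_separation_detects_10sd_split():
    rng = np.random.default_rng(3)
    scores, labels = _two_groups(rng, sep=10.0)
    res = cluster_separation_test(scores, labels)
    assert res.p_value < 0.01
    assert (res.own_distance.mean() < res.pooled_distance.mean())


def test_cluster_separation_null_mostly_non_significant():
    rng = np.random.default_rng(4)
    sig = 0
    n_rep = 40
    for _ in range(n_rep):
        scores, labels = _two_groups(rng, sep=0.0)
        if cluster_separation_test(scores, labels).p_value < 0.05:
            sig += 1
    assert sig <= 0.2 * n_rep


def test_cluster_separation_label_permutation_destroys_signal():
    rng = np.random.default_rng(6)
    scores, labels = _two_groups(rng, sep=10.0)
    ps = []
    for _ in range(50):
        perm = pd.Series(rng.permutation(labels.to_numpy()),
                         index=labels.index)
        ps.append(cluster_separation_test(scores, perm).p_value)
    assert np.median(ps) > 0.1


def test_cluster_separation_validates_groups():
    rng = np.random.default_rng(7)
    scores, labels = _two_groups(rng, n=5)
    labels.iloc[:] = "a"
    with pytest.raises(ValueError, match="two groups"):
        cluster_separation_test(scores, labels)
    scores2, labels2 = _two_groups(rng, n=5)
    labels2.iloc[:2] = "c"
    with pytest.raises(ValueError):
        cluster_separation_test(scores2, labels2)


def test_cluster_separation_unpaired_variant():
    rng = np.random.default_rng(9)
    scores, labels = _two_groups(rng, sep=10.0)
    res = cluster_separation_test(scores, labels, paired=False)
    assert res.method == "rank-sum"
    assert res.p_value < 0.01
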