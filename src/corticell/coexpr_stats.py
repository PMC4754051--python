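"""Co-expression permutation tests, PCA and the cluster-separation test.

The co-expression test asks, for a pair of marker genes, whether their
Pearson correlation across single cells exceeds what label-shuffling
produces: one gene's values are permuted across wells (10 000 draws by
default) and the empirical two-tailed p-value is the add-one-smoothed
fraction of permutations whose |r| reaches the observed |r|. P-values are
corrected across the tested family by Benjamini–Hochberg. For four to eight
wells an exhaustive mode enumerates every permutation instead.

Cluster separation on a PCA plane is tested by comparing, per point, the
Euclidean distance to its own group's centroid against the distance to the
pooled centroid of both groups, with a paired two-sided Wilcoxon signed-rank
test over all points; well-separated groups make own-centroid distances
systematically smaller.

Values may be the LOD-anchored continuous expression or 0/1 detection calls
(giving a phi coefficient); the caller picks the scale and it is recorded in
the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

_EXHAUSTIVE_MAX_N = 8
_TOL = 1e-12


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values
    return multipletests(p_values, method="fdr_bh")[1]


def pairwise_corr(values: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Pearson correlation matrix over wells for the given genes.

    ``values`` is wells × genes (continuous expression or 0/1 detection
    calls). Pairs where either gene has zero variance are undefined (NaN).
    """
    if genes is not None:
        missing = [g for g in genes if g not in values.columns]
        if missing:
            raise ValueError(f"genes absent from matrix: {missing}")
        values = values[list(genes)]
    if len(values) < 3:
        raise ValueError("need at least 3 wells")
    return values.corr(method="pearson")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return np.nan
    return float((xc @ yc) / denom)


def _perm_p_sampled(x: np.ndarray, y: np.ndarray, r_obs: float,
                    n_perm: int, rng: np.random.Generator) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    n = len(x)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    r_perm = (yc[perm_idx] @ xc) / denom
    hits = int(np.sum(np.abs(r_perm) >= abs(r_obs) - _TOL))
    return (1 + hits) / (1 + n_perm)


def _perm_p_exhaustive(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    hits = 0
    total = math.factorial(n)
    for perm in _permutations(range(n)):
        r = (yc[list(perm)] @ xc) / denom
        if abs(r) >= abs(r_obs) - _TOL:
            hits += 1
    return hits / total


def perm_corr_test(
    values: pd.DataFrame,
    pairs: list[tuple[str, str]],
    n_perm: int = 10_000,
    seed: int = 0,
    mode: str = "sampled",
    scale: str = "expression",
) -> pd.DataFrame:
    """Permutation test of Pearson co-expression for each gene pair.

    The second gene of each pair is permuted across wells. ``mode`` is
    ``sampled`` (n_perm seeded draws, add-one-smoothed p) or ``exhaustive``
    (all n! permutations, exact p; n ≤ 8). Zero-variance genes make a pair
    not evaluable; evaluable pairs form the BH family.

    Returns one row per pair: gene_a, gene_b, r_obs, p_emp, q, n_perm, seed,
    mode, scale, evaluable.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if mode not in ("sampled", "exhaustive"):
        raise ValueError(f"unknown mode {mode!r}")
    for a, b in pairs:
        for g in (a, b):
            if g not in values.columns:
                raise ValueError(f"gene {g!r} absent from matrix")
    n = len(values)
    if mode == "exhaustive" and n > _EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive mode limited to n <= {_EXHAUSTIVE_MAX_N} wells")

    rng = np.random.default_rng(seed)
    rows = []
    for a, b in pairs:
        x = values[a].to_numpy(dtype=float)
        y = values[b].to_numpy(dtype=float)
        r_obs = _pearson(x, y)
        if np.isnan(r_obs):
            rows.append((a, b, np.nan, np.nan, False))
            continue
        if mode == "exhaustive":
            p = _perm_p_exhaustive(x, y, r_obs)
        else:
            p = _perm_p_sampled(x, y, r_obs, n_perm, rng)
        rows.append((a, b, r_obs, p, True))

    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r_obs", "p_emp",
                                      "evaluable"])
    out["q"] = np.nan
    ev = out["evaluable"].to_numpy()
    if ev.any():
        out.loc[ev, "q"] = bh_adjust(out.loc[ev, "p_emp"].to_numpy())
    out["n_perm"] = n_perm if mode == "sampled" else math.factorial(n)
    out["seed"] = seed
    out["mode"] = mode
    out["scale"] = scale
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame        # wells × components
    loadings: pd.DataFrame      # genes × components
    variance_explained: np.ndarray  # fraction of total variance per component


def pca(values: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Centered (not scaled) PCA with a fixed sign convention.

    The largest-magnitude loading of each component is forced positive so
    scores are reproducible across library versions.
    """
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 wells and 2 genes")
    arr = values.to_numpy(dtype=float)
    if np.allclose(arr.var(axis=0).sum(), 0.0):
        raise ValueError("matrix has no variance")
    n_components = min(n_components, min(arr.shape) - 0, arr.shape[1])
    n_components = min(n_components, arr.shape[0] - 1)
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(arr)
    loadings = model.components_.T  # genes × components
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=values.columns, columns=comp_names),
        variance_explained=model.explained_variance_ratio_.copy(),
    )


@dataclass
class ClusterSepResult:
    labels: pd.Series
    own_distance: pd.Series
    pooled_distance: pd.Series
    statistic: float
    p_value: float
    method: str  # "signed-rank" or "rank-sum"


def cluster_separation_test(
    scores: pd.DataFrame,
    labels: pd.Series,
    paired: bool = True,
) -> ClusterSepResult:
    """Test whether two groups of points separate on the first two PCs.

    Per point, the Euclidean distance to its own group's centroid is paired
    with the distance to the pooled centroid; a two-sided Wilcoxon
    signed-rank test over all points (zero differences excluded) gives the
    significance. ``paired=False`` uses an unpaired rank-sum comparison of
    the two distance sets instead.
    """
    labels = labels.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("every point needs a group label")
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 points")

    xy = scores.iloc[:, :2].to_numpy(dtype=float)
    pooled_centroid = xy.mean(axis=0)
    own = np.empty(len(xy))
    for g in groups:
        mask = (labels == g).to_numpy()
        centroid = xy[mask].mean(axis=0)
        own[mask] = np.linalg.norm(xy[mask] - centroid, axis=1)
    pooled = np.linalg.norm(xy - pooled_centroid, axis=1)

    if paired:
        diffs = own - pooled
        if np.allclose(diffs, 0.0):
            statistic, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(own, pooled, zero_method="wilcox",
                                 alternative="two-sided")
            statistic, p = float(res.statistic), float(res.pvalue)
        method = "signed-rank"
    else:
        res = stats.mannwhitneyu(own, pooled, alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "rank-sum"

    return ClusterSepResult(
        labels=labels,
        own_distance=pd.Series(own, index=scores.index),
        pooled_distance=pd.Series(pooled, index=scores.index),
        statistic=statistic,
        p_value=min(max(p, np.nextafter(0, 1)), 1.0),
        method=method,
    )
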