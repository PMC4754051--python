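"""Single-cell RNA-seq desk-side computations.

Cell QC applies three filters to a count matrix, each evaluated once on the
full input cohort (no iterative re-fitting):

* ``low_gene_count`` — detected-gene count below the Tukey boxplot lower
  limit (Q1 − 1.5·IQR) of the cohort;
* ``high_mito`` — fraction of assigned fragments on mitochondrial genes
  strictly above 0.15;
* ``pca_outlier`` — Euclidean distance from the cohort centroid in the top-2
  PC space of size-factor-normalised log1p counts greater than 5× the median
  absolute deviation of all cells' distances.

Library sizes are put on a common scale with median-of-ratios size factors
(per-gene geometric means over genes with all-nonzero counts; per-cell
factor = median ratio). FPKM divides counts by gene length in kb and by
assigned fragments per million. The differential-expression post-filter
keeps a significant gene only if it is detectable in >10% of cells at mean
FPKM > 1 in at least one group and the detection-fraction and mean-level
changes agree in direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr_stats import bh_adjust, pca
from .io_ct import CountMatrix, GeneAnnotation

FAIL_REASONS = ("low_gene_count", "high_mito", "pca_outlier")


def detectable_genes(counts: CountMatrix) -> pd.Series:
    """Per-cell set of detected genes (count ≥ 1 fragment)."""
    nz = counts.counts > 0
    return pd.Series(
        {c: frozenset(counts.gene_ids[nz[c]]) for c in counts.cell_ids}
    )


def n_detected_genes(counts: CountMatrix) -> pd.Series:
    return (counts.counts > 0).sum(axis=0)


def mito_fraction(counts: CountMatrix, annotation: GeneAnnotation) -> pd.Series:
    """Fraction of assigned fragments on mitochondrial genes, per cell."""
    missing = counts.gene_ids.difference(annotation.gene_ids)
    if len(missing):
        raise ValueError(f"annotation missing genes: {sorted(missing)}")
    mito = annotation.is_mito.reindex(counts.gene_ids)
    totals = counts.counts.sum(axis=0)
    mito_counts = counts.counts.loc[mito.to_numpy()].sum(axis=0)
    return (mito_counts / totals.replace(0, np.nan)).fillna(0.0)


def size_factors(counts: CountMatrix, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios per-cell size factors.

    Geometric means are taken over genes with nonzero counts in every cell;
    each cell's factor is the median of its count/geomean ratios over those
    genes. If no gene is nonzero in all cells, pass a positive
    ``pseudocount`` to compute factors over all genes.
    """
    mat = counts.counts.to_numpy(dtype=float) + pseudocount
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has nonzero counts in every cell; "
            "use pseudocount > 0 to enable all-gene factors"
        )
    sub = mat[all_nonzero]
    geomean = np.exp(np.mean(np.log(sub), axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.cell_ids, name="size_factor")


def cell_qc(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    mito_threshold: float = 0.15,
    mad_multiplier: float = 5.0,
) -> pd.DataFrame:
    """Single-pass cell QC report with per-cell fail reasons.

    Returns a DataFrame indexed by cell with columns ``n_detected_genes``,
    ``mito_fraction``, ``pca_distance``, the three boolean fail reasons and
    ``pass``.
    """
    n_cells = len(counts.cell_ids)
    if n_cells < 4:
        raise ValueError("boxplot lower limit needs at least 4 cells")

    n_det = n_detected_genes(counts)
    q1, q3 = np.percentile(n_det.to_numpy(), [25, 75])
    lower_limit = q1 - 1.5 * (q3 - q1)
    low_gene = n_det < lower_limit

    mito = mito_fraction(counts, annotation)
    high_mito = mito > mito_threshold

    sf = size_factors(counts, pseudocount=0.0 if _has_common_gene(counts) else 1.0)
    norm = np.log1p(counts.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :])
    cells_by_genes = pd.DataFrame(norm.T, index=counts.cell_ids,
                                  columns=counts.gene_ids)
    if np.allclose(cells_by_genes.to_numpy().var(axis=0).sum(), 0.0):
        # identical cells: no PC space, nobody is an outlier
        dist = pd.Series(0.0, index=counts.cell_ids)
        pca_out = pd.Series(False, index=counts.cell_ids)
    else:
        res = pca(cells_by_genes, n_components=2)
        xy = res.scores.to_numpy()
        d = np.linalg.norm(xy - xy.mean(axis=0), axis=1)
        dist = pd.Series(d, index=counts.cell_ids)
        mad = float(np.median(np.abs(d - np.median(d))))
        if mad == 0:
            pca_out = pd.Series(False, index=counts.cell_ids)
        else:
            pca_out = dist > mad_multiplier * mad

    report = pd.DataFrame(
        {
            "n_detected_genes": n_det,
            "mito_fraction": mito,
            "pca_distance": dist,
            "low_gene_count": low_gene,
            "high_mito": high_mito,
            "pca_outlier": pca_out,
        }
    )
    report["pass"] = ~report[list(FAIL_REASONS)].any(axis=1)
    report["fail_reasons"] = report[list(FAIL_REASONS)].apply(
        lambda row: ";".join(r for r in FAIL_REASONS if row[r]), axis=1
    )
    return report


def _has_common_gene(counts: CountMatrix) -> bool:
    return bool((counts.counts.to_numpy() > 0).all(axis=1).any())


def fpkm(counts: CountMatrix, annotation: GeneAnnotation) -> pd.DataFrame:
    """Fragments per kilobase of gene per million assigned fragments.

    fpkm[g, c] = counts[g, c] / (length_kb[g] × total_counts[c] / 1e6).
    """
    missing = counts.gene_ids.difference(annotation.gene_ids)
    if len(missing):
        raise ValueError(f"annotation missing genes: {sorted(missing)}")
    totals = counts.counts.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        bad = counts.cell_ids[totals == 0].tolist()
        raise ValueError(f"cells with zero total counts: {bad}")
    length_kb = annotation.length_bp.reindex(counts.gene_ids).to_numpy() / 1_000.0
    vals = counts.counts.to_numpy(dtype=float) / (
        length_kb[:, None] * (totals[None, :] / 1e6)
    )
    return pd.DataFrame(vals, index=counts.gene_ids, columns=counts.cell_ids)


@dataclass(frozen=True)
class DEPostFilterRule:
    """Post-filter thresholds for a differential-expression gene list."""

    min_detect_fraction: float = 0.10
    min_mean_fpkm: float = 1.0
    direction_concordance: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_detect_fraction <= 1.0:
            raise ValueError("min_detect_fraction must be in [0, 1]")


def de_post_filter(de_table: pd.DataFrame,
                   rule: DEPostFilterRule | None = None) -> pd.Index:
    """Filter a two-group DE table down to robustly supported genes.

    ``de_table`` is indexed by gene with columns ``mean_fpkm_a``,
    ``mean_fpkm_b``, ``detect_frac_a``, ``detect_frac_b`` and
    ``significant``. A gene is retained iff it is significant, at least one
    group passes the abundance gate (detect fraction > 0.10 and mean FPKM
    > 1, both strict) and the changes in detection fraction and mean level
    point the same way (zero change in either fails concordance).
    """
    rule = rule or DEPostFilterRule()
    required = {"mean_fpkm_a", "mean_fpkm_b", "detect_frac_a", "detect_frac_b",
                "significant"}
    missing = required - set(de_table.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")

    t = de_table
    gate = (
        ((t["detect_frac_a"] > rule.min_detect_fraction)
         & (t["mean_fpkm_a"] > rule.min_mean_fpkm))
        | ((t["detect_frac_b"] > rule.min_detect_fraction)
           & (t["mean_fpkm_b"] > rule.min_mean_fpkm))
    )
    keep = t["significant"].astype(bool) & gate
    if rule.direction_concordance:
        d_frac = t["detect_frac_b"] - t["detect_frac_a"]
        d_mean = t["mean_fpkm_b"] - t["mean_fpkm_a"]
        concordant = np.sign(d_frac) * np.sign(d_mean) > 0
        keep &= concordant
    return t.index[keep]


def ranksum_de_flags(fpkm_matrix: pd.DataFrame, groups: pd.Series,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Synthetic stand-in DE caller for end-to-end runs on simulated data.

    Wilcoxon rank-sum per gene between two groups of cells with BH control
    at ``alpha``; produces the group means, detection fractions and
    significance flags that :func:`de_post_filter` consumes. This is a
    simple two-group screen for exercising the pipeline, not a model-based
    single-cell DE method.
    """
    labels = groups.reindex(fpkm_matrix.columns)
    names = sorted(labels.unique())
    if len(names) != 2:
        raise ValueError("need exactly two groups")
    a = fpkm_matrix.loc[:, (labels == names[0]).to_numpy()]
    b = fpkm_matrix.loc[:, (labels == names[1]).to_numpy()]
    p = np.array([
        stats.ranksums(a.loc[g], b.loc[g]).pvalue
        if (a.loc[g].var() > 0 or b.loc[g].var() > 0) else 1.0
        for g in fpkm_matrix.index
    ])
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean_fpkm_a": a.mean(axis=1),
            "mean_fpkm_b": b.mean(axis=1),
            "detect_frac_a": (a > 0).mean(axis=1),
            "detect_frac_b": (b > 0).mean(axis=1),
            "p_value": p,
            "q_value": q,
            "significant": q < alpha,
        },
        index=fpkm_matrix.index,
    )


def pooled_vs_bulk_corr(single_expr: pd.DataFrame,
                        bulk_expr: pd.Series) -> tuple[float, float]:
    """Pearson correlation of pooled (cell-averaged) single-cell expression
    with a bulk per-gene profile over the shared gene set."""
    shared = single_expr.index.intersection(bulk_expr.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    pooled = single_expr.loc[shared].mean(axis=1)
    res = stats.pearsonr(pooled.to_numpy(), bulk_expr.loc[shared].to_numpy())
    return float(res.statistic), float(res.pvalue)
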