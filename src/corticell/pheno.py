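"""Marker-panel phenotype and cortical-layer calls, composition comparison.

A QC-passing well is a *neuron* if any of MAP2 / NCAM1 / TUBB3 is detected.
Neurons get a laminar category from the canonical layer markers:

* ``deep``  — ≥1 deep marker (BCL11B, TBR1) and no upper marker
* ``upper`` — ≥1 upper marker (CUX1, POU3F2, SATB2) and no deep marker
* ``mixed`` — at least one marker of each class
* ``none``  — no layer marker detected

GABAergic status (GAD1) is only called on neurons; glial marker detection
(GFAP / OLIG2) is flagged independently and co-flagged wells are reported,
with neuron status taking precedence for layer assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import MarkerPanel
from .qc_norm import DetectionMatrix

LAYER_CATEGORIES = ("deep", "upper", "mixed", "none")
COMPOSITION_COLUMNS = LAYER_CATEGORIES + ("non-neuron",)


def assign_layer(det_row: pd.Series, panel: MarkerPanel | None = None) -> str:
    """Laminar category of one neuron's detection row."""
    panel = panel or MarkerPanel()
    has_deep = bool(det_row[list(panel.deep_markers)].any())
    has_upper = bool(det_row[list(panel.upper_markers)].any())
    if has_deep and has_upper:
        return "mixed"
    if has_deep:
        return "deep"
    if has_upper:
        return "upper"
    return "none"


def classify_cells(det: DetectionMatrix,
                   panel: MarkerPanel | None = None) -> pd.DataFrame:
    """Per-well phenotype calls from a detection matrix of QC-passing wells.

    Returns a DataFrame indexed by well with columns ``is_neuron``,
    ``is_gaba``, ``is_glia`` and ``layer`` (one of deep/upper/mixed/none for
    neurons, pandas NA otherwise).
    """
    panel = panel or MarkerPanel()
    missing = panel.missing_from(det.gene_ids)
    if missing:
        raise ValueError(f"panel genes absent from matrix: {missing}")

    d = det.detected
    is_neuron = d[list(panel.neuron_markers)].any(axis=1)
    is_gaba = is_neuron & d[panel.gaba_marker]
    is_glia = d[list(panel.glia_markers)].any(axis=1)

    has_deep = d[list(panel.deep_markers)].any(axis=1)
    has_upper = d[list(panel.upper_markers)].any(axis=1)
    layer = pd.Series(pd.NA, index=d.index, dtype=object)
    layer[is_neuron & has_deep & has_upper] = "mixed"
    layer[is_neuron & has_deep & ~has_upper] = "deep"
    layer[is_neuron & ~has_deep & has_upper] = "upper"
    layer[is_neuron & ~has_deep & ~has_upper] = "none"

    return pd.DataFrame(
        {
            "is_neuron": is_neuron,
            "is_gaba": is_gaba,
            "is_glia": is_glia,
            "layer": layer,
        }
    )


def composition_table(calls: pd.DataFrame,
                      groups: pd.Series | None = None) -> pd.DataFrame:
    """Contingency table of cell categories (layer classes + non-neuron) per group.

    ``groups`` maps well id → group label; omit it for a single overall row.
    Row sums equal group sizes; every well lands in exactly one category.
    """
    if groups is None:
        groups = pd.Series("all", index=calls.index)
    groups = groups.reindex(calls.index)
    if groups.isna().any():
        missing = calls.index[groups.isna()].tolist()
        raise ValueError(f"wells missing a grouping key: {missing[:5]}")

    category = calls["layer"].where(calls["is_neuron"], "non-neuron")
    table = pd.crosstab(groups, category)
    table = table.reindex(columns=list(COMPOSITION_COLUMNS), fill_value=0)
    table.index.name = "group"
    table.columns.name = "category"
    return table


@dataclass
class CompositionComparison:
    test: str  # "chi-square" or "monte-carlo-exact"
    statistic: float
    df: int | None
    p_value: float
    n_mc: int | None = None


def _mc_exact_p(table: np.ndarray, n_mc: int, seed: int) -> float:
    """Monte-Carlo exact test of homogeneity with fixed margins.

    Samples tables by permuting category labels over pooled cells (the
    conditional null with both margins fixed) and compares the chi-square
    statistic of each sample against the observed one.
    """
    rng = np.random.default_rng(seed)
    n_groups, n_cats = table.shape
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    total = table.sum()
    expected = np.outer(row_tot, col_tot) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_stat = np.nansum((table - expected) ** 2 / expected)

    labels = np.repeat(np.arange(n_cats), col_tot)
    group_slices = np.concatenate([[0], np.cumsum(row_tot)])
    exceed = 0
    for _ in range(n_mc):
        rng.shuffle(labels)
        sim = np.zeros_like(table)
        for gi in range(n_groups):
            seg = labels[group_slices[gi]:group_slices[gi + 1]]
            sim[gi] = np.bincount(seg, minlength=n_cats)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.nansum((sim - expected) ** 2 / expected)
        if s >= obs_stat - 1e-12:
            exceed += 1
    return (1 + exceed) / (1 + n_mc)


def compare_compositions(table: pd.DataFrame, n_mc: int = 10_000,
                         seed: int = 0) -> CompositionComparison:
    """Test homogeneity of cell-type composition across groups.

    Chi-square test of the contingency table; switches to a seeded
    Monte-Carlo exact test (Fisher–Freeman–Halton style) when more than 20%
    of expected cell counts fall below 5.
    """
    if table.shape[0] < 2:
        raise ValueError("need at least 2 groups")
    arr = table.to_numpy(dtype=float)
    if (arr.sum(axis=1) == 0).any():
        empty = table.index[arr.sum(axis=1) == 0].tolist()
        raise ValueError(f"groups with no cells: {empty}")
    # drop all-zero categories; they contribute nothing and break expecteds
    arr = arr[:, arr.sum(axis=0) > 0]
    if arr.shape[1] < 2:
        raise ValueError("need at least 2 non-empty categories")

    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    sparse = (expected < 5).mean() > 0.20
    if sparse:
        p = _mc_exact_p(arr.astype(int), n_mc=n_mc, seed=seed)
        stat = float(stats.chi2_contingency(arr, correction=False).statistic)
        return CompositionComparison("monte-carlo-exact", stat, None, p, n_mc)
    res = stats.chi2_contingency(arr, correction=False)
    return CompositionComparison(
        "chi-square", float(res.statistic), int(res.dof), float(res.pvalue)
    )
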