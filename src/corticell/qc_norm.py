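"""Detection calling, well QC, batch adjustment and the Ct → expression map.

The limit of detection (LOD) is Ct 30: a reaction is *detected* iff its Ct is
strictly below the LOD. Wells are kept only if the housekeeper GAPDH is
detected (a failed reverse transcription leaves no housekeeper signal).
Batches (chips) are aligned by subtracting, from every measured Ct of a
batch, the mean housekeeper offset of that batch relative to a reference
chip. Continuous expression is the LOD-anchored value ``lod − Ct`` with
undetected reactions at 0, which keeps dropouts in correlation analyses as
zeros rather than missing values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_ct import SENTINEL, CtMatrix
from .panel import HOUSEKEEPERS

DEFAULT_LOD = 30.0


@dataclass
class DetectionMatrix:
    """Boolean detected calls per (well, gene) at a given LOD."""

    detected: pd.DataFrame  # bool, wells × genes
    lod: float

    @property
    def well_ids(self) -> pd.Index:
        return self.detected.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.detected.columns


@dataclass
class ExpressionMatrix:
    """LOD-anchored continuous expression, ``max(0, lod − ct)``."""

    expression: pd.DataFrame  # float, wells × genes
    lod: float


@dataclass
class BatchAdjustment:
    """Per-batch additive Ct shifts estimated from housekeeper genes."""

    shifts: pd.Series  # batch label -> cycles
    reference_batch: str
    housekeepers: tuple[str, ...]


def call_detection(ct: CtMatrix, lod: float = DEFAULT_LOD) -> DetectionMatrix:
    """Call a gene detected in a well iff Ct < lod (strict inequality)."""
    if lod <= 0:
        raise ValueError("lod must be positive")
    return DetectionMatrix(detected=ct.ct < lod, lod=float(lod))


def well_qc(det: DetectionMatrix, housekeeper: str = "GAPDH") -> pd.DataFrame:
    """Per-well QC: a well passes iff the housekeeper gene is detected.

    Returns a DataFrame indexed by well with columns ``pass`` and
    ``housekeeper_detected``; use ``report[report['pass']].index`` as the
    valid-well set.
    """
    if housekeeper not in det.gene_ids:
        raise ValueError(f"housekeeper gene {housekeeper!r} absent from panel")
    ok = det.detected[housekeeper]
    return pd.DataFrame({"pass": ok, "housekeeper_detected": ok})


def valid_wells(det: DetectionMatrix, housekeeper: str = "GAPDH") -> pd.Index:
    report = well_qc(det, housekeeper)
    return report.index[report["pass"]]


def batch_adjust(
    ct: CtMatrix,
    reference_batch: str,
    lod: float = DEFAULT_LOD,
    housekeepers: tuple[str, ...] = HOUSEKEEPERS,
) -> tuple[CtMatrix, BatchAdjustment]:
    """Align batches by their mean housekeeper Ct relative to the reference.

    For each batch b, the shift is the mean over housekeeper genes of
    (mean detected Ct of the gene in b − mean detected Ct in the reference),
    computed over QC-passing wells only; the shift is subtracted from every
    measured (non-sentinel) Ct of the batch. The reference shift is 0 by
    construction.
    """
    if reference_batch not in set(ct.batch):
        raise ValueError(f"reference batch {reference_batch!r} not present")
    missing = [g for g in housekeepers if g not in ct.gene_ids]
    if missing:
        raise ValueError(f"housekeeper genes absent from panel: {missing}")

    det = call_detection(ct, lod)
    keep = valid_wells(det, housekeeper=housekeepers[0])

    def hk_means(batch: str) -> pd.Series:
        wells = keep[ct.batch.loc[keep] == batch]
        if len(wells) == 0:
            raise ValueError(f"batch {batch!r} has no QC-passing wells")
        sub = ct.ct.loc[wells, list(housekeepers)]
        msk = det.detected.loc[wells, list(housekeepers)]
        means = sub.where(msk).mean()
        if means.isna().any():
            bad = means.index[means.isna()].tolist()
            raise ValueError(
                f"batch {batch!r} has no detected wells for housekeepers {bad}"
            )
        return means

    ref_means = hk_means(reference_batch)
    batches = pd.Index(sorted(ct.batch.unique()))
    shifts = pd.Series(0.0, index=batches)
    for b in batches:
        shifts[b] = float((hk_means(b) - ref_means).mean())
    shifts[reference_batch] = 0.0

    adjusted = ct.ct.copy()
    measured = ct.ct.to_numpy() != SENTINEL
    shift_per_well = ct.batch.map(shifts).to_numpy()
    vals = adjusted.to_numpy()
    vals[measured] = vals[measured] - np.broadcast_to(
        shift_per_well[:, None], vals.shape
    )[measured]
    vals[measured] = np.clip(vals[measured], 0.01, SENTINEL - 1.0)
    adjusted = pd.DataFrame(vals, index=ct.ct.index, columns=ct.ct.columns)

    return (
        CtMatrix(adjusted, ct.batch.copy()),
        BatchAdjustment(shifts=shifts, reference_batch=reference_batch,
                        housekeepers=tuple(housekeepers)),
    )


def replicate_reliability(
    ct_a: CtMatrix,
    ct_b: CtMatrix,
    min_pairs: int = 3,
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-gene inter-chip reliability of technical replicates.

    For every gene shared by the two chips, squared Pearson correlation of Ct
    over wells measured (non-sentinel) on both chips. Genes with fewer than
    ``min_pairs`` paired measurements are not evaluable; evaluable genes with
    r² below ``r2_threshold`` are flagged for exclusion.

    Returns a DataFrame indexed by gene with columns ``r2``, ``n_pairs``,
    ``evaluable`` and ``exclude``.
    """
    wells = ct_a.well_ids.intersection(ct_b.well_ids)
    if len(wells) == 0:
        raise ValueError("chips share no wells")
    genes = ct_a.gene_ids.intersection(ct_b.gene_ids)
    rows = []
    for g in genes:
        a = ct_a.ct.loc[wells, g].to_numpy()
        b = ct_b.ct.loc[wells, g].to_numpy()
        both = (a != SENTINEL) & (b != SENTINEL)
        n = int(both.sum())
        r2 = np.nan
        if n >= min_pairs and np.std(a[both]) > 0 and np.std(b[both]) > 0:
            r = stats.pearsonr(a[both], b[both]).statistic
            r2 = float(r * r)
        rows.append((g, r2, n))
    out = pd.DataFrame(rows, columns=["gene", "r2", "n_pairs"]).set_index("gene")
    out["evaluable"] = out["r2"].notna()
    out["exclude"] = out["evaluable"] & (out["r2"] < r2_threshold)
    return out


def dilution_linearity(ct_series: CtMatrix, log_dilutions: np.ndarray,
                       lod: float = DEFAULT_LOD) -> pd.DataFrame:
    """Per-gene r² of Ct against log2 dilution over detected points.

    ``ct_series`` has one row per dilution point; ``log_dilutions`` gives the
    log2 dilution factor of each row. Genes with fewer than 3 detected points
    or zero Ct variance are not evaluable.
    """
    log_dilutions = np.asarray(log_dilutions, dtype=float)
    if len(log_dilutions) != len(ct_series.well_ids):
        raise ValueError("one log-dilution per row required")
    if len(log_dilutions) < 3:
        raise ValueError("need at least 3 dilution points")
    rows = []
    for g in ct_series.gene_ids:
        y = ct_series.ct[g].to_numpy()
        ok = y < lod
        n = int(ok.sum())
        r2 = np.nan
        if n >= 3 and np.std(y[ok]) > 0 and np.std(log_dilutions[ok]) > 0:
            res = stats.linregress(log_dilutions[ok], y[ok])
            r2 = float(res.rvalue**2)
        rows.append((g, r2, n))
    out = pd.DataFrame(rows, columns=["gene", "r2", "n_points"]).set_index("gene")
    out["evaluable"] = out["r2"].notna()
    return out


def to_expression(ct: CtMatrix, lod: float = DEFAULT_LOD) -> ExpressionMatrix:
    """LOD-anchored expression: ``lod − Ct`` where detected, else 0."""
    if lod <= 0:
        raise ValueError("lod must be positive")
    expr = (lod - ct.ct).where(ct.ct < lod, 0.0).clip(lower=0.0)
    return ExpressionMatrix(expression=expr, lod=float(lod))
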