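"""End-to-end orchestration of the qPCR and RNA-seq analyses.

``run_qpcr_pipeline`` executes the published analysis order on a Ct matrix:
detection calling → housekeeper well QC → batch adjustment → phenotype and
layer classification → composition table → marker co-expression permutation
tests → PCA and the cluster-separation test. ``run_rnaseq_qc`` runs the
RNA-seq side: cell QC, size factors and FPKM. Both write per-stage CSVs, a
human-readable summary and a machine-readable JSON manifest (config, seed,
input digests, package version) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .coexpr_stats import cluster_separation_test, pca, perm_corr_test
from .io_ct import CountMatrix, CtMatrix, GeneAnnotation
from .panel import DEEP_MARKERS, MarkerPanel, UPPER_MARKERS
from .pheno import classify_cells, compare_compositions, composition_table
from .qc_norm import batch_adjust, call_detection, to_expression, well_qc
from .scrnaseq import cell_qc, fpkm, size_factors

log = logging.getLogger("corticell")


@dataclass
class PipelineConfig:
    """Tunable parameters of both pipelines (see docs/methods.md)."""

    lod: float = 30.0
    reference_batch: str | None = None  # default: first batch label seen
    n_perm: int = 10_000
    seed: int = 0
    mito_threshold: float = 0.15
    mad_multiplier: float = 5.0
    min_detect_fraction: float = 0.10
    min_mean_fpkm: float = 1.0
    coexpr_scale: str = "expression"  # or "detection"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.lod <= 0:
            raise ValueError("lod must be positive")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 <= self.mito_threshold <= 1:
            raise ValueError("mito_threshold must be in [0, 1]")
        if self.mad_multiplier <= 0:
            raise ValueError("mad_multiplier must be positive")
        if self.coexpr_scale not in ("expression", "detection"):
            raise ValueError("coexpr_scale must be 'expression' or 'detection'")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: PipelineConfig,
                    inputs: dict[str, Path], stages: list[str]) -> None:
    manifest = {
        "package": "corticell",
        "version": __version__,
        "config": asdict(config),
        "inputs": {k: {"path": str(p), "sha256_16": _digest(p)}
                   for k, p in inputs.items()},
        "stages": stages,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


class StageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def qpcr_summary(calls: pd.DataFrame, n_total_wells: int,
                 n_valid_wells: int) -> dict:
    """Counts and one-decimal percentages of the classification taxonomy."""
    neurons = calls[calls["is_neuron"]]
    n_neurons = len(neurons)
    layer_counts = neurons["layer"].value_counts()
    n_deep = int(layer_counts.get("deep", 0))
    n_upper = int(layer_counts.get("upper", 0))
    n_mixed = int(layer_counts.get("mixed", 0))
    n_none = int(layer_counts.get("none", 0))
    n_single = n_deep + n_upper
    n_any_layer = n_single + n_mixed
    n_gaba = int(neurons["is_gaba"].sum())

    def pct(a: int, b: int) -> float:
        return round(100.0 * a / b, 1) if b else float("nan")

    return {
        "n_wells": int(n_total_wells),
        "n_valid_wells": int(n_valid_wells),
        "pct_valid_wells": pct(n_valid_wells, n_total_wells),
        "n_neurons": n_neurons,
        "pct_neurons": pct(n_neurons, n_valid_wells),
        "n_single_layer": n_single,
        "pct_single_layer": pct(n_single, n_neurons),
        "n_deep": n_deep,
        "n_upper": n_upper,
        "n_mixed": n_mixed,
        "pct_mixed": pct(n_mixed, n_neurons),
        "n_no_layer": n_none,
        "pct_no_layer": pct(n_none, n_neurons),
        "pct_single_among_layer_positive": pct(n_single, n_any_layer),
        "n_gaba": n_gaba,
        "pct_gaba": pct(n_gaba, n_neurons),
        "n_glia_flagged": int(calls["is_glia"].sum()),
    }


def run_qpcr_pipeline(
    ct: CtMatrix,
    config: PipelineConfig | None = None,
    groups: pd.Series | None = None,
    out_dir: str | Path | None = None,
    input_paths: dict[str, Path] | None = None,
) -> dict:
    """Run the full qPCR analysis; returns a dict of in-memory results.

    If ``out_dir`` is given, per-stage CSVs, the summary and the manifest
    are written there.
    """
    config = config or PipelineConfig()
    panel = MarkerPanel()
    stages: list[str] = []

    det = _stage("call_detection")(call_detection)(ct, config.lod)
    stages.append("call_detection")

    qc = _stage("well_qc")(well_qc)(det)
    stages.append("well_qc")
    valid = qc.index[qc["pass"]]

    reference = config.reference_batch or str(ct.batch.iloc[0])
    adjusted, adjustment = _stage("batch_adjust")(batch_adjust)(
        ct, reference, lod=config.lod
    )
    stages.append("batch_adjust")

    det_valid = call_detection(adjusted.subset_wells(valid), config.lod)
    calls = _stage("classify")(classify_cells)(det_valid, panel)
    stages.append("classify")

    comp = _stage("composition")(composition_table)(
        calls, groups.reindex(valid) if groups is not None else None
    )
    stages.append("composition")
    comparison = None
    if comp.shape[0] >= 2:
        comparison = compare_compositions(comp, seed=config.seed)

    expr = to_expression(adjusted.subset_wells(valid), config.lod)
    neurons = calls.index[calls["is_neuron"]]
    layer_genes = list(DEEP_MARKERS) + list(UPPER_MARKERS)
    values = (
        expr.expression.loc[neurons, layer_genes]
        if config.coexpr_scale == "expression"
        else det_valid.detected.loc[neurons, layer_genes].astype(float)
    )
    pairs = list(combinations(layer_genes, 2))
    coexpr = _stage("coexpression")(perm_corr_test)(
        values, pairs, n_perm=config.n_perm, seed=config.seed,
        scale=config.coexpr_scale,
    )
    stages.append("coexpression")

    pca_res = None
    cluster = None
    layered = calls.loc[neurons]
    layered = layered[layered["layer"].isin(["deep", "upper"])]
    if len(neurons) >= 3:
        pca_res = _stage("pca")(pca)(expr.expression.loc[neurons], 2)
        stages.append("pca")
        by_layer = layered["layer"]
        if (by_layer == "deep").sum() >= 3 and (by_layer == "upper").sum() >= 3:
            cluster = _stage("cluster_test")(cluster_separation_test)(
                pca_res.scores.loc[layered.index], by_layer
            )
            stages.append("cluster_test")

    summary = qpcr_summary(calls, n_total_wells=len(ct.well_ids),
                           n_valid_wells=len(valid))

    results = {
        "detection": det,
        "well_qc": qc,
        "batch_adjustment": adjustment,
        "calls": calls,
        "composition": comp,
        "composition_comparison": comparison,
        "coexpression": coexpr,
        "pca": pca_res,
        "cluster_test": cluster,
        "summary": summary,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        qc_out = qc.copy()
        qc_out["batch"] = ct.batch
        qc_out["shift_applied"] = ct.batch.map(adjustment.shifts)
        qc_out.index.name = "well_id"
        qc_out.to_csv(out / "well_qc.csv")
        calls_out = calls.copy()
        calls_out.index.name = "well_id"
        calls_out.to_csv(out / "cell_calls.csv")
        comp.to_csv(out / "composition.csv")
        coexpr.to_csv(out / "coexpression.csv", index=False)
        if pca_res is not None:
            pca_res.scores.to_csv(out / "pca_scores.csv")
        if cluster is not None:
            pd.DataFrame(
                [{"method": cluster.method, "statistic": cluster.statistic,
                  "p_value": cluster.p_value}]
            ).to_csv(out / "cluster_test.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        _write_manifest(out, config, input_paths or {}, stages)

    return results


def run_rnaseq_qc(
    counts: CountMatrix,
    annotation: GeneAnnotation,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    input_paths: dict[str, Path] | None = None,
) -> dict:
    """Run RNA-seq cell QC, size factors and FPKM; optionally write reports."""
    config = config or PipelineConfig()
    stages: list[str] = []

    report = _stage("cell_qc")(cell_qc)(
        counts, annotation, mito_threshold=config.mito_threshold,
        mad_multiplier=config.mad_multiplier,
    )
    stages.append("cell_qc")

    from .scrnaseq import _has_common_gene

    sf = _stage("size_factors")(size_factors)(
        counts, pseudocount=0.0 if _has_common_gene(counts) else 1.0
    )
    stages.append("size_factors")

    fpkm_mat = _stage("fpkm")(fpkm)(counts, annotation)
    stages.append("fpkm")

    results = {"cell_qc": report, "size_factors": sf, "fpkm": fpkm_mat,
               "n_pass": int(report["pass"].sum())}

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rep = report.copy()
        rep.index.name = "cell_id"
        rep.to_csv(out / "cell_qc.csv")
        sf.rename_axis("cell_id").to_csv(out / "size_factors.csv")
        fpkm_out = fpkm_mat.copy()
        fpkm_out.index.name = "gene_id"
        fpkm_out.to_csv(out / "fpkm.tsv", sep="\t")
        _write_manifest(out, config, input_paths or {}, stages)

    return results
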