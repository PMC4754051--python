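"""Synthetic data with known ground truth for the qPCR and RNA-seq pipelines.

Two generators and one deterministic fixture:

* :func:`simulate_qpcr` draws a 96-gene single-cell Ct matrix from a mixture
  of cell archetypes (deep / upper / mixed / markerless neurons, glia, failed
  wells) with per-gene dropout, Gaussian Ct noise, per-chip batch shifts and
  limit-of-detection censoring at the 999 sentinel.
* :func:`simulate_counts` draws a single-cell RNA-seq count matrix
  (gamma-Poisson, i.e. negative binomial) with per-cell true size factors,
  mitochondrial genes and optionally planted QC-failing cells.
* :func:`make_worked_example_fixture` builds, with no randomness, a 478-well
  Ct matrix whose classification marginals equal the published cell-count
  taxonomy: 406 housekeeper-positive wells, 380 neurons, 184 single-layer
  (100 deep-only / 84 upper-only), 85 mixed-layer, 111 layer-negative and 91
  GABAergic neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_ct import SENTINEL, CountMatrix, CtMatrix, GeneAnnotation
from .panel import (
    DEEP_MARKERS,
    GABA_MARKER,
    GLIA_MARKERS,
    GLUT_MARKER,
    HOUSEKEEPERS,
    NEURON_MARKERS,
    PANEL_GENES,
    UPPER_MARKERS,
)

#: Cell archetypes the qPCR simulator can draw.
ARCHETYPES = (
    "deep-neuron",
    "upper-neuron",
    "mixed-neuron",
    "markerless-neuron",
    "glia",
    "failed-well",
)

# Background genes expressed by every neuron archetype beyond the identity
# markers, so simulated neurons carry a realistic synaptic programme.
_NEURON_BACKGROUND = (
    "SYN1", "SYP", "SNAP25", "DLG4", "GRIA1", "GRIN2B", "SYT1", "VAMP2",
    "NEFL", "MAP1B", "RBFOX3", "ENO2",
)
_GLIA_BACKGROUND = ("S100B", "AQP4", "SLC1A3", "VIM")


def archetype_expressing_genes(archetype: str) -> frozenset[str]:
    """True expressing gene set for one archetype (before dropout)."""
    if archetype == "failed-well":
        return frozenset()
    base = set(HOUSEKEEPERS)
    if archetype == "glia":
        return frozenset(base | set(GLIA_MARKERS) | set(_GLIA_BACKGROUND))
    base |= set(NEURON_MARKERS) | {GLUT_MARKER} | set(_NEURON_BACKGROUND)
    if archetype == "deep-neuron":
        base |= set(DEEP_MARKERS)
    elif archetype == "upper-neuron":
        base |= set(UPPER_MARKERS)
    elif archetype == "mixed-neuron":
        base |= set(DEEP_MARKERS) | set(UPPER_MARKERS)
    elif archetype != "markerless-neuron":
        raise ValueError(f"unknown archetype {archetype!r}")
    return frozenset(base)


@dataclass
class QpcrSimConfig:
    """Parameters of the synthetic sorted-plate qPCR experiment.

    ``dropout`` is the probability that an expressed gene is *detected* in a
    cell (1.0 = no dropout); give a mapping for per-gene values, any gene not
    listed uses ``default_dropout``. ``batch_shifts`` maps chip labels to
    additive Ct offsets in cycles; wells are split evenly across chips.
    """

    n_wells: int = 478
    composition: Mapping[str, float] = field(
        default_factory=lambda: {
            "deep-neuron": 0.21,
            "upper-neuron": 0.18,
            "mixed-neuron": 0.18,
            "markerless-neuron": 0.23,
            "glia": 0.05,
            "failed-well": 0.15,
        }
    )
    dropout: float | Mapping[str, float] = 0.85
    mean_ct_on: float = 20.0
    ct_sd: float = 2.0
    batch_shifts: Mapping[str, float] = field(default_factory=lambda: {"batch1": 0.0})
    gaba_fraction: float = 0.24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells <= 0:
            raise ValueError("n_wells must be positive")
        total = float(sum(self.composition.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition proportions must sum to 1, got {total}")
        unknown = set(self.composition) - set(ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        for g, p in self._dropout_items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"dropout for {g} must be in [0, 1]")
        if not 0.0 <= self.gaba_fraction <= 1.0:
            raise ValueError("gaba_fraction must be in [0, 1]")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be non-negative")
        if not self.batch_shifts:
            raise ValueError("batch_shifts must name at least one chip")

    def _dropout_items(self):
        if isinstance(self.dropout, Mapping):
            return list(self.dropout.items())
        return [("(all genes)", float(self.dropout))]

    def dropout_for(self, gene: str) -> float:
        if isinstance(self.dropout, Mapping):
            return float(self.dropout.get(gene, 1.0))
        return float(self.dropout)


@dataclass
class GroundTruth:
    """Ground-truth labels carried alongside a simulated dataset.

    For qPCR simulations ``wells`` has one row per well (archetype, batch,
    is_gaba) and ``expressing`` the true well × gene expressing status. For
    count simulations ``cells`` has one row per cell (size_factor, outlier,
    outlier_kind).
    """

    wells: pd.DataFrame | None = None
    expressing: pd.DataFrame | None = None
    cells: pd.DataFrame | None = None

    def write(self, path) -> None:
        """Write the per-well (or per-cell) table as a sidecar CSV."""
        table = self.wells if self.wells is not None else self.cells
        if table is None:
            raise ValueError("empty ground truth")
        out = table.copy()
        out.index.name = "well_id" if self.wells is not None else "cell_id"
        out.to_csv(path)


def _allocate_counts(n: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n wells to archetypes (deterministic)."""
    keys = sorted(proportions)
    raw = {k: n * proportions[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    by_frac = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def simulate_qpcr(config: QpcrSimConfig) -> tuple[CtMatrix, GroundTruth]:
    """Draw a synthetic sorted-plate Ct matrix from the archetype mixture."""
    rng = np.random.default_rng(config.seed)
    n = config.n_wells
    genes = list(PANEL_GENES)

    counts = _allocate_counts(n, config.composition)
    labels = np.array(
        [a for a in sorted(counts) for _ in range(counts[a])], dtype=object
    )
    rng.shuffle(labels)

    chips = sorted(config.batch_shifts)
    chip_of_well = np.array([chips[i % len(chips)] for i in range(n)], dtype=object)

    width = len(str(n))
    well_ids = [f"well_{i + 1:0{width}d}" for i in range(n)]

    expressing = np.zeros((n, len(genes)), dtype=bool)
    gene_pos = {g: j for j, g in enumerate(genes)}
    is_gaba = np.zeros(n, dtype=bool)
    for i, arch in enumerate(labels):
        for g in archetype_expressing_genes(arch):
            expressing[i, gene_pos[g]] = True
        if arch.endswith("neuron") and rng.random() < config.gaba_fraction:
            expressing[i, gene_pos[GABA_MARKER]] = True
            is_gaba[i] = True

    detect_p = np.array([config.dropout_for(g) for g in genes])
    detected = expressing & (rng.random((n, len(genes))) < detect_p[None, :])

    shifts = np.array([config.batch_shifts[c] for c in chip_of_well])
    ct = np.full((n, len(genes)), SENTINEL)
    noise = rng.normal(0.0, config.ct_sd, size=(n, len(genes)))
    values = config.mean_ct_on + shifts[:, None] + noise
    values = np.clip(values, 0.01, SENTINEL - 1.0)  # Ct is a cycle count, > 0
    ct[detected] = values[detected]

    matrix = CtMatrix(
        pd.DataFrame(ct, index=well_ids, columns=genes),
        pd.Series(chip_of_well, index=well_ids),
    )
    truth = GroundTruth(
        wells=pd.DataFrame(
            {"archetype": labels, "batch": chip_of_well, "is_gaba": is_gaba},
            index=well_ids,
        ),
        expressing=pd.DataFrame(expressing, index=well_ids, columns=genes),
    )
    return matrix, truth


# Worked-example layout: counts of the published single-cell taxonomy.
WORKED_EXAMPLE_COUNTS = {
    "total_wells": 478,
    "failed_wells": 72,
    "gapdh_positive": 406,
    "non_neuronal": 26,
    "neurons": 380,
    "deep_only": 100,   # deep+upper single-layer split is arbitrary; only
    "upper_only": 84,   # the aggregate 184 is published
    "mixed_layer": 85,
    "no_layer_marker": 111,
    "gaba_neurons": 91,
}

_FIXTURE_CT = 20.0  # any Ct below the detection limit would do


def make_worked_example_fixture() -> tuple[CtMatrix, GroundTruth]:
    """Deterministic 478-well Ct matrix reproducing the published taxonomy.

    No randomness: detected reactions get Ct 20, everything else the 999
    sentinel. Wells are laid out in blocks (failed, non-neuronal, deep-only,
    upper-only, mixed, layer-negative); the first 91 neurons are GABAergic.
    """
    c = WORKED_EXAMPLE_COUNTS
    genes = list(PANEL_GENES)
    n = c["total_wells"]
    well_ids = [f"well_{i + 1:03d}" for i in range(n)]
    ct = pd.DataFrame(SENTINEL, index=well_ids, columns=genes)

    i = c["failed_wells"]  # wells [0, i) stay all-sentinel
    gapdh_pos = well_ids[i:]
    ct.loc[gapdh_pos, ["GAPDH", "ACTB"]] = _FIXTURE_CT

    i += c["non_neuronal"]  # housekeeper-only wells
    neurons = well_ids[i:]
    assert len(neurons) == c["neurons"]
    ct.loc[neurons, ["MAP2", "TUBB3"]] = _FIXTURE_CT

    deep = neurons[: c["deep_only"]]
    upper = neurons[c["deep_only"] : c["deep_only"] + c["upper_only"]]
    mixed = neurons[
        c["deep_only"] + c["upper_only"] :
        c["deep_only"] + c["upper_only"] + c["mixed_layer"]
    ]
    ct.loc[deep, "BCL11B"] = _FIXTURE_CT
    ct.loc[upper, "CUX1"] = _FIXTURE_CT
    ct.loc[mixed, ["TBR1", "SATB2"]] = _FIXTURE_CT

    gaba = neurons[: c["gaba_neurons"]]
    ct.loc[gaba, "GAD1"] = _FIXTURE_CT

    archetype = pd.Series("failed-well", index=well_ids, dtype=object)
    archetype.iloc[c["failed_wells"] : c["failed_wells"] + c["non_neuronal"]] = (
        "non-neuronal"
    )
    archetype.loc[deep] = "deep-neuron"
    archetype.loc[upper] = "upper-neuron"
    archetype.loc[mixed] = "mixed-neuron"
    archetype.loc[neurons[-c["no_layer_marker"] :]] = "markerless-neuron"

    is_gaba = pd.Series(False, index=well_ids)
    is_gaba.loc[gaba] = True

    batch = pd.Series("batch1", index=well_ids)
    matrix = CtMatrix(ct, batch)
    truth = GroundTruth(
        wells=pd.DataFrame(
            {"archetype": archetype, "batch": batch, "is_gaba": is_gaba}
        ),
        expressing=ct < SENTINEL,
    )
    return matrix, truth


def simulate_counts(
    n_cells: int,
    n_genes: int,
    mito_genes: int = 13,
    size_factor_range: tuple[float, float] = (0.5, 2.0),
    planted_outliers: int = 0,
    seed: int = 0,
    dispersion: float = 0.2,
) -> tuple[CountMatrix, GeneAnnotation, GroundTruth]:
    """Draw a gamma-Poisson scRNA-seq count matrix with known size factors.

    Planted outlier cells alternate between a high mitochondrial fraction
    (mito counts inflated to ~50% of the library) and collapsed complexity
    (90% of genes zeroed); ground truth records the kind planted.
    """
    if n_cells <= 0 or n_genes <= 0:
        raise ValueError("dimensions must be positive")
    if mito_genes >= n_genes:
        raise ValueError("mito_genes must be smaller than n_genes")
    lo, hi = size_factor_range
    if lo <= 0 or hi <= 0 or hi < lo:
        raise ValueError("size factors must be positive with lo <= hi")
    if planted_outliers > n_cells:
        raise ValueError("cannot plant more outliers than cells")

    rng = np.random.default_rng(seed)
    gene_ids = [f"MT-G{j + 1}" if j < mito_genes else f"G{j + 1:05d}"
                for j in range(n_genes)]
    cell_ids = [f"cell_{i + 1:04d}" for i in range(n_cells)]

    base_mean = rng.lognormal(mean=1.5, sigma=1.0, size=n_genes)
    size_factors = rng.uniform(lo, hi, size=n_cells)
    mu = base_mean[:, None] * size_factors[None, :]
    if dispersion > 0:
        gamma = rng.gamma(shape=1.0 / dispersion, scale=dispersion,
                          size=(n_genes, n_cells))
        mu = mu * gamma
    counts = rng.poisson(mu).astype(np.int64)

    outlier = np.zeros(n_cells, dtype=bool)
    kind = np.array([""] * n_cells, dtype=object)
    planted = rng.choice(n_cells, size=planted_outliers, replace=False)
    mito_mask = np.zeros(n_genes, dtype=bool)
    mito_mask[:mito_genes] = True
    for rank, idx in enumerate(sorted(planted)):
        outlier[idx] = True
        if rank % 2 == 0:
            # raise mito counts so mito fraction ~0.5 of the library
            non_mito_total = counts[~mito_mask, idx].sum()
            target = max(int(non_mito_total), 1)
            per_gene = np.maximum(target // max(mito_genes, 1), 1)
            counts[mito_mask, idx] = per_gene
            kind[idx] = "high_mito"
        else:
            keep = rng.random(n_genes) < 0.1
            counts[~keep, idx] = 0
            kind[idx] = "low_complexity"

    # every cell must have at least one assigned fragment
    empty = counts.sum(axis=0) == 0
    counts[0, empty] = 1

    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=cell_ids))
    ann = GeneAnnotation(
        pd.DataFrame(
            {
                "is_mito": mito_mask,
                "length_bp": rng.uniform(500, 10_000, size=n_genes),
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
    )
    truth = GroundTruth(
        cells=pd.DataFrame(
            {"size_factor": size_factors, "outlier": outlier, "outlier_kind": kind},
            index=cell_ids,
        )
    )
    return matrix, ann, truth
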