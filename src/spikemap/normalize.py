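"""QC filtering, normalization layers, cluster averages, homeolog sums.

QC keeps cells whose detected-gene and total-UMI counts fall inside closed
intervals. Two normalization layers are provided: counts per million (CPM,
the layer used for cross-modal cosine similarity) and LogNormalize
(ln(1 + count / total * scale_factor), Seurat's convention). Cluster
profiles are arithmetic means of normalized expression per cluster, and
homeolog aggregation sums the members of each triad into one group column
for cross-study comparisons in polyploid wheat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Closed-interval QC bounds on detected genes and total UMIs per cell.

    Defaults are the single-cell study's published cutoffs.
    """

    min_genes: int = 1500
    max_genes: int = 25_000
    min_umi: int = 8000
    max_umi: int = 300_000

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes exceeds max_genes")
        if self.min_umi > self.max_umi:
            raise ValueError("min_umi exceeds max_umi")


@dataclass
class ClusterProfile:
    """Mean normalized expression per cluster (clusters x genes) with sizes."""

    means: pd.DataFrame
    sizes: pd.Series
    layer: str = "lognorm"

    def __post_init__(self) -> None:
        if (self.sizes < 1).any():
            raise ValueError("every cluster needs at least one cell")
        if not self.means.index.equals(self.sizes.index):
            raise ValueError("means and sizes indexed by different clusters")

    @property
    def clusters(self) -> list:
        return list(self.means.index)

    @property
    def genes(self) -> list[str]:
        return list(self.means.columns)


def qc_filter_cells(m: CountMatrix, thresholds: QCThresholds) -> CountMatrix:
    """Keep cells with detected genes and total UMIs inside the closed
    intervals; the gene set is unchanged."""
    if m.layer != "raw":
        raise ValueError("QC filtering requires the raw layer")
    detected = (m.values > 0).sum(axis=1)
    total = m.values.sum(axis=1)
    keep = (
        (detected >= thresholds.min_genes) & (detected <= thresholds.max_genes)
        & (total >= thresholds.min_umi) & (total <= thresholds.max_umi)
    )
    if not keep.any():
        raise ValueError("QC filter removed every cell")
    kept = [c for c, k in zip(m.cell_ids, keep) if k]
    return m.subset_cells(kept)


def _cell_totals(m: CountMatrix) -> np.ndarray:
    totals = m.values.sum(axis=1)
    if (totals <= 0).any():
        zero = [c for c, t in zip(m.cell_ids, totals) if t <= 0]
        raise ValueError(f"cells with zero total counts: {zero[:5]}")
    return totals


def cpm(m: CountMatrix) -> CountMatrix:
    """Counts per million: value(c, g) = raw(c, g) / total(c) * 1e6."""
    if m.layer != "raw":
        raise ValueError("CPM requires the raw layer")
    totals = _cell_totals(m)
    values = m.values / totals[:, None] * 1e6
    return CountMatrix(values, list(m.cell_ids), list(m.gene_ids),
                       modality=m.modality, stage=m.stage, layer="cpm")


def lognormalize(m: CountMatrix, scale_factor: float = 1e4) -> CountMatrix:
    """LogNormalize: ln(1 + raw / total * scale_factor)."""
    if m.layer != "raw":
        raise ValueError("lognormalize requires the raw layer")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = _cell_totals(m)
    values = np.log1p(m.values / totals[:, None] * scale_factor)
    return CountMatrix(values, list(m.cell_ids), list(m.gene_ids),
                       modality=m.modality, stage=m.stage, layer="lognorm")


def cluster_average(m: CountMatrix, labels: Mapping[str, object] | pd.Series) -> ClusterProfile:
    """Arithmetic mean of (normalized) expression per cluster per gene."""
    labels = pd.Series(labels)
    missing = [c for c in m.cell_ids if c not in labels.index]
    if missing:
        raise ValueError(f"unlabeled cells: {missing[:5]}")
    lab = labels.loc[m.cell_ids]
    df = m.to_frame()
    means = df.groupby(lab.to_numpy()).mean()
    sizes = pd.Series(lab.to_numpy()).value_counts().sort_index()
    sizes = sizes.loc[means.index]
    return ClusterProfile(means=means, sizes=sizes, layer=m.layer)


def aggregate_homeologs(
    m: CountMatrix, homeolog_map: Mapping[str, Sequence[str]]
) -> CountMatrix:
    """Sum member-gene columns into one column per homeolog group.

    Members absent from the matrix contribute 0 (cross-study panels differ);
    a member listed twice within a group is an error; genes not covered by
    the map are dropped.
    """
    gene_idx = m.gene_index()
    out = np.zeros((m.n_cells, len(homeolog_map)))
    groups = list(homeolog_map)
    for j, grp in enumerate(groups):
        members = list(homeolog_map[grp])
        if len(set(members)) != len(members):
            raise ValueError(f"group {grp!r} lists a member twice")
        cols = [gene_idx[g] for g in members if g in gene_idx]
        if cols:
            out[:, j] = m.values[:, cols].sum(axis=1)
    return CountMatrix(out, list(m.cell_ids), groups,
                       modality=m.modality, stage=m.stage, layer=m.layer)


def aggregate_profile_homeologs(
    p: ClusterProfile, homeolog_map: Mapping[str, Sequence[str]]
) -> ClusterProfile:
    """Homeolog aggregation applied to a cluster profile (sums commute
    with cluster means)."""
    out = {}
    for grp, members in homeolog_map.items():
        if len(set(members)) != len(list(members)):
            raise ValueError(f"group {grp!r} lists a member twice")
        present = [g for g in members if g in p.means.columns]
        out[grp] = p.means[present].sum(axis=1) if present else pd.Series(
            0.0, index=p.means.index)
    return ClusterProfile(means=pd.DataFrame(out), sizes=p.sizes, layer=p.layer)
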