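"""Informative-gene filtering and cluster-cluster Pearson correlations.

Cluster profiles (mean normalized expression per cluster) are compared
with Pearson correlation over an "informative" gene set: genes whose
coefficient of variation across cluster means exceeds a floor (removing
flatly expressed genes) and whose total across clusters lies inside a band
(removing extremes and near-all-zero genes). Cross-study comparisons are
computed over shared gene ids, optionally after homeolog aggregation in the
polyploid study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import ClusterProfile, aggregate_profile_homeologs


@dataclass(frozen=True)
class GeneFilterParams:
    """Defaults are the published filter: CV > 0.5, cluster-sum in [0.1, 20].

    CV uses the sample standard deviation (ddof=1) by default; the sum band
    is closed at both ends (only strictly-outside genes are eliminated).
    """

    cv_min: float = 0.5
    sum_min: float = 0.1
    sum_max: float = 20.0
    sd_ddof: int = 1

    def __post_init__(self) -> None:
        if self.sum_min >= self.sum_max:
            raise ValueError("sum_min must be below sum_max")
        if self.cv_min < 0:
            raise ValueError("cv_min must be nonnegative")


@dataclass
class CorrelationMatrix:
    """Pearson r between cluster profiles; square matrices are symmetric
    with unit diagonal. ``dropped`` lists zero-variance clusters whose
    correlations are reported missing."""

    r: pd.DataFrame
    n_genes: int
    dropped: list = None

    def __post_init__(self) -> None:
        if self.dropped is None:
            self.dropped = []


def informative_gene_filter(
    p: ClusterProfile, params: GeneFilterParams = GeneFilterParams()
) -> list[str]:
    """Genes with CV (sd/mean over cluster means) > cv_min and total over
    cluster means inside [sum_min, sum_max]. Genes with mean 0 are excluded
    (their CV is undefined)."""
    if len(p.clusters) < 2:
        raise ValueError("need at least 2 clusters to compute CV")
    means = p.means.to_numpy()
    gene_mean = means.mean(axis=0)
    gene_sd = means.std(axis=0, ddof=params.sd_ddof)
    gene_sum = means.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(gene_mean > 0, gene_sd / gene_mean, np.nan)
    keep = (
        (gene_mean > 0)
        & (cv > params.cv_min)
        & (gene_sum >= params.sum_min)
        & (gene_sum <= params.sum_max)
    )
    return [g for g, k in zip(p.genes, keep) if k]


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between every row of a and every row of b."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    an = np.linalg.norm(ac, axis=1)
    bn = np.linalg.norm(bc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ac @ bc.T) / np.outer(an, bn)
    return np.clip(r, -1.0, 1.0, out=r, where=~np.isnan(r))


def cluster_correlation_matrix(
    p: ClusterProfile, genes: Sequence[str]
) -> CorrelationMatrix:
    """Symmetric Pearson matrix among cluster profiles over ``genes``.

    A zero-variance cluster row gets missing correlations (off-diagonal
    NaN) and is reported in ``dropped``.
    """
    genes = list(genes)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    sub = p.means[genes].to_numpy()
    r = _pearson_rows(sub, sub)
    sd = sub.std(axis=1)
    dropped = [c for c, s in zip(p.clusters, sd) if s == 0]
    np.fill_diagonal(r, 1.0)
    df = pd.DataFrame(r, index=p.clusters, columns=p.clusters)
    return CorrelationMatrix(df, n_genes=len(genes), dropped=dropped)


def cross_study_correlation(
    a: ClusterProfile,
    b: ClusterProfile,
    shared: Sequence[str] | None = None,
    homeolog_map: Mapping[str, Sequence[str]] | None = None,
    aggregate: str = "b",
) -> CorrelationMatrix:
    """Rectangular Pearson matrix (clusters of a x clusters of b) over
    shared gene ids, optionally summing homeolog triads first in one study
    (``aggregate`` = "a" or "b") so ids become comparable across ploidy."""
    if homeolog_map is not None:
        if aggregate == "a":
            a = aggregate_profile_homeologs(a, homeolog_map)
        elif aggregate == "b":
            b = aggregate_profile_homeologs(b, homeolog_map)
        else:
            raise ValueError("aggregate must be 'a' or 'b'")
    if shared is None:
        shared = [g for g in a.genes if g in set(b.genes)]
    shared = list(shared)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    ra = a.means[shared].to_numpy()
    rb = b.means[shared].to_numpy()
    r = _pearson_rows(ra, rb)
    dropped = [c for c, s in zip(a.clusters, ra.std(axis=1)) if s == 0]
    dropped += [c for c, s in zip(b.clusters, rb.std(axis=1)) if s == 0]
    df = pd.DataFrame(r, index=a.clusters, columns=b.clusters)
    return CorrelationMatrix(df, n_genes=len(shared), dropped=dropped)


def dendrogram_order(cm: CorrelationMatrix) -> list:
    """Leaf order from complete-linkage hierarchical clustering of the
    correlation matrix rows (Euclidean distance) — an output-ordering
    convenience, not an analysis result."""
    from scipy.cluster.hierarchy import leaves_list, linkage

    if cm.r.shape[0] < 2:
        return list(cm.r.index)
    link = linkage(cm.r.to_numpy(), method="complete", metric="euclidean")
    return [cm.r.index[i] for i in leaves_list(link)]
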