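"""Marker detection, co-expression screening, protoplasting diagnostics.

Markers are found one-vs-rest per cluster with a two-sided Wilcoxon
rank-sum test (normal approximation with tie and continuity correction),
expression fractions pct.1/pct.2, a group-level-pseudocount log2 fold
change, and Bonferroni-adjusted p-values. Two published filter presets are
provided (strict for most clusters, relaxed for marker-poor ones).

The co-expression screen correlates a target gene with every other
detected gene across all cells and selects genes whose Pearson r exceeds
the screen's mean + 4 SD.

Protoplasting diagnostics score each cluster by (a) the share of its
markers overlapping a known protoplasting-stress gene list and (b) the
share absent from intact-tissue bulk RNA-seq; agreement between the two is
summarized by their cross-cluster Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix

MARKER_COLUMNS = ("cluster", "gene_id", "log2fc", "pct1", "pct2", "p", "p_adj")

STRICT_FILTER = dict(log2fc_min=1.0, pct1_min=0.10, pct2_max=0.10, p_adj_max=0.001)
RELAXED_FILTER = dict(log2fc_min=1.0, pct1_min=None, pct2_max=0.2, p_adj_max=0.01)


@dataclass(frozen=True)
class MarkerFilterParams:
    """Strict-inequality thresholds on a marker record.

    strict preset: log2FC > 1, pct.1 > 0.10, pct.2 < 0.10, p_adj < 0.001.
    relaxed preset: log2FC > 1, no pct.1 filter, pct.2 < 0.2, p_adj < 0.01.
    """

    log2fc_min: float = 1.0
    pct1_min: float | None = 0.10
    pct2_max: float = 0.10
    p_adj_max: float = 0.001

    @classmethod
    def preset(cls, mode: str) -> "MarkerFilterParams":
        if mode == "strict":
            return cls(**STRICT_FILTER)
        if mode == "relaxed":
            return cls(**RELAXED_FILTER)
        raise ValueError("mode must be 'strict' or 'relaxed'")

    def keep(self, log2fc: float, pct1: float, pct2: float, p_adj: float) -> bool:
        if not log2fc > self.log2fc_min:
            return False
        if self.pct1_min is not None and not pct1 > self.pct1_min:
            return False
        if not pct2 < self.pct2_max:
            return False
        if np.isnan(p_adj) or not p_adj < self.p_adj_max:
            return False
        return True


@dataclass
class CoexpressionResult:
    target: str
    r: pd.Series          # per-gene Pearson r (NaN for constant genes)
    mean_r: float
    sd_r: float
    threshold: float      # mean_r + sd_mult * sd_r
    selected: list[str]   # genes with r > threshold, sorted by r descending


@dataclass
class ProtoplastingReport:
    """Per-cluster stress-overlap and bulk-absence percentages (0-100) and
    their cross-cluster Pearson correlation."""

    table: pd.DataFrame   # index cluster; pct_stress_overlap, pct_bulk_absent
    correlation: float
    missing_clusters: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Marker ranking
# ---------------------------------------------------------------------------


def rank_markers(
    m: CountMatrix,
    labels: Mapping[str, object] | pd.Series,
    min_cluster_size: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker statistics for every (cluster, gene).

    Requires the lognorm layer. Per record: two-sided rank-sum p (normal
    approximation, tie + continuity corrected), pct.1/pct.2 (fraction of
    cells with value > 0 inside / outside the cluster), log2FC on de-logged
    group means with a pseudocount of 1 added at the group level, and
    Bonferroni p_adj over genes x clusters. Clusters smaller than
    ``min_cluster_size`` get records with missing p.
    """
    if m.layer != "lognorm":
        raise ValueError("rank_markers requires the lognorm layer")
    labels = pd.Series(labels).loc[m.cell_ids]
    clusters = sorted(pd.unique(labels), key=str)
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    expm = np.expm1(m.values)
    expressed = m.values > 0
    frames = []
    for cl in clusters:
        mask = (labels == cl).to_numpy()
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        pct1 = expressed[mask].mean(axis=0)
        pct2 = expressed[~mask].mean(axis=0)
        log2fc = np.log2(
            (expm[mask].mean(axis=0) + 1.0) / (expm[~mask].mean(axis=0) + 1.0)
        )
        if n_in >= min_cluster_size and n_out >= min_cluster_size:
            res = stats.mannwhitneyu(
                m.values[mask], m.values[~mask], axis=0,
                alternative="two-sided", method="asymptotic",
            )
            p = np.asarray(res.pvalue, dtype=float)
        else:
            p = np.full(m.n_genes, np.nan)
        frames.append(pd.DataFrame({
            "cluster": cl, "gene_id": m.gene_ids,
            "log2fc": log2fc, "pct1": pct1, "pct2": pct2, "p": p,
        }))
    table = pd.concat(frames, ignore_index=True)
    table["p_adj"] = adjust_pvalues(table["p"].to_numpy())
    return table


def adjust_pvalues(p: np.ndarray, method: str = "bonferroni") -> np.ndarray:
    """Bonferroni (default) or Benjamini-Hochberg adjustment; NaNs pass
    through and do not count as tests."""
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    n = int(ok.sum())
    if n == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(p[ok] * n, 1.0)
    elif method == "bh":
        order = np.argsort(p[ok])
        ranked = p[ok][order] * n / (np.arange(n) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.empty(n)
        adj[order] = np.minimum(ranked, 1.0)
        out[ok] = adj
    else:
        raise ValueError("method must be 'bonferroni' or 'bh'")
    return out


def filter_markers(
    table: pd.DataFrame, params: MarkerFilterParams | str = "strict"
) -> dict[object, list[str]]:
    """Apply the strict/relaxed predicate per record -> cluster -> genes,
    ordered by descending log2FC within each cluster."""
    if isinstance(params, str):
        params = MarkerFilterParams.preset(params)
    keep = table.apply(
        lambda rec: params.keep(rec["log2fc"], rec["pct1"], rec["pct2"],
                                rec["p_adj"]),
        axis=1,
    )
    out: dict[object, list[str]] = {}
    kept = table[keep].sort_values("log2fc", ascending=False)
    for cl in pd.unique(table["cluster"]):
        out[cl] = list(kept.loc[kept["cluster"] == cl, "gene_id"])
    return out


# ---------------------------------------------------------------------------
# Co-expression screen
# ---------------------------------------------------------------------------


def detected_genes(m: CountMatrix, min_cells: int = 3) -> list[str]:
    """Genes expressed (value > 0) in at least ``min_cells`` cells."""
    n_expr = (m.values > 0).sum(axis=0)
    return [g for g, n in zip(m.gene_ids, n_expr) if n >= min_cells]


def coexpression_screen(
    m: CountMatrix,
    target: str,
    sd_mult: float = 4.0,
    min_cells_detected: int = 3,
) -> CoexpressionResult:
    """Pearson r between ``target`` and every other detected gene across
    all cells; select genes with r above mean_r + ``sd_mult`` * sd_r.

    The target itself and constant (zero-variance) genes are excluded from
    the r distribution used for the threshold.
    """
    if target not in m.gene_index():
        raise KeyError(f"target gene {target!r} not in matrix")
    genes = [g for g in detected_genes(m, min_cells_detected) if g != target]
    t = m.values[:, m.gene_index()[target]].astype(float)
    if t.std() == 0:
        raise ValueError("target gene is constant across cells")
    sub = m.subset_genes(genes).values
    tc = t - t.mean()
    sc = sub - sub.mean(axis=0, keepdims=True)
    denom = np.linalg.norm(tc) * np.linalg.norm(sc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, tc @ sc / denom, np.nan)
    r = pd.Series(np.clip(r, -1.0, 1.0), index=genes, name="r")
    valid = r.dropna()
    mean_r = float(valid.mean())
    sd_r = float(valid.std(ddof=1))
    threshold = mean_r + sd_mult * sd_r
    selected = list(valid[valid > threshold].sort_values(ascending=False).index)
    return CoexpressionResult(target, r, mean_r, sd_r, threshold, selected)


# ---------------------------------------------------------------------------
# Protoplasting diagnostics
# ---------------------------------------------------------------------------


def protoplasting_scores(
    marker_lists: Mapping[object, Iterable[str]],
    stress_list: Iterable[str],
    bulk_detected: Iterable[str],
) -> ProtoplastingReport:
    """Two per-cluster artifact metrics: percent of markers on the stress
    list, and percent of markers absent from bulk-detected genes; plus the
    Pearson correlation between the two percentage vectors across clusters."""
    stress = set(stress_list)
    bulk = set(bulk_detected)
    rows, missing = [], []
    for cl, markers in marker_lists.items():
        markers = list(markers)
        if not markers:
            missing.append(cl)
            continue
        n = len(markers)
        pct_stress = 100.0 * sum(g in stress for g in markers) / n
        pct_absent = 100.0 * sum(g not in bulk for g in markers) / n
        rows.append((cl, n, pct_stress, pct_absent))
    table = pd.DataFrame(
        rows, columns=["cluster", "n_markers", "pct_stress_overlap",
                       "pct_bulk_absent"],
    ).set_index("cluster")
    if len(table) >= 2 and table["pct_stress_overlap"].std() > 0 \
            and table["pct_bulk_absent"].std() > 0:
        corr = float(np.corrcoef(table["pct_stress_overlap"],
                                 table["pct_bulk_absent"])[0, 1])
    else:
        corr = float("nan")
    return ProtoplastingReport(table, corr, missing)
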