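"""Cross-modal cosine-kNN integration of smFISH and scRNA-seq cells.

The method: over the shared gene panel (the genes probed in both assays,
CPM-normalized), find for each query cell the k reference cells with the
highest cosine similarity s = (q . r) / (|q| |r|), i.e. 1 - cosine
distance, in [0, 1] for nonnegative expression. Three consumers:

* **imputation** — each spatial cell receives, for every reference gene
  (including the ~70k genes never probed spatially), the similarity-
  weighted average of its k nearest scRNA-seq neighbors;
* **reverse projection** — each scRNA-seq cell is assigned the most
  frequent smFISH cluster label among its k nearest spatial neighbors,
  after discarding neighbors with similarity <= a floor (0.3); all-unique
  labels mean no projection;
* **contribution matrix** — projected labels are cross-tabulated against
  the scRNA-seq cells' own clusters and normalized by each smFISH
  cluster's total size, anchoring transcriptome clusters in space.

The kNN search is exact (chunked full similarity computation); ties in
similarity are broken by reference cell id so results are deterministic.
Stages are integrated separately and merged afterward.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

DEFAULT_K = 5
DEFAULT_MIN_SIMILARITY = 0.3


@dataclass
class IntegrationParams:
    k: int = DEFAULT_K
    min_similarity: float = DEFAULT_MIN_SIMILARITY  # projection filter only
    shared_genes: list[str] = field(default_factory=list)
    layer: str = "cpm"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must lie in [0, 1]")
        if self.layer not in ("cpm", "lognorm"):
            raise ValueError("layer must be 'cpm' or 'lognorm'")


@dataclass
class NeighborMap:
    """Per query cell, its nearest reference cells with cosine similarities,
    ordered by decreasing similarity (ties by reference id).

    Query cells that are all-zero over the shared panel have an undefined
    cosine; they are excluded and listed in ``excluded_queries``.
    """

    neighbors: dict[str, list[tuple[str, float]]]
    excluded_queries: list[str] = field(default_factory=list)
    excluded_references: list[str] = field(default_factory=list)
    k: int = DEFAULT_K

    def __post_init__(self) -> None:
        for q, lst in self.neighbors.items():
            sims = [s for _, s in lst]
            if any(s2 > s1 + 1e-12 for s1, s2 in zip(sims, sims[1:])):
                raise ValueError(f"similarities not non-increasing for {q!r}")


@dataclass
class ImputedMatrix:
    """Imputed expression for query cells over the reference gene set.

    Rows for queries with no qualifying neighbor are NaN and listed in
    ``missing_cells``. In merged (multi-stage) matrices, NaN also marks
    genes that were not imputed for a cell's stage.
    """

    values: pd.DataFrame
    stage: str = "mixed"
    params: IntegrationParams | None = None
    missing_cells: list[str] = field(default_factory=list)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProjectionTable:
    """Per scRNA-seq cell: projected smFISH cluster label (or None),
    supporting vote count, and summed similarity of the supporting votes."""

    table: pd.DataFrame  # columns: label (object), votes (int), summed_similarity

    def labels(self) -> pd.Series:
        return self.table["label"]


@dataclass
class ContributionMatrix:
    """smFISH clusters x scRNA clusters: projected-cell counts and the
    count / smFISH-cluster-size fractions used to anchor scRNA clusters."""

    counts: pd.DataFrame
    fractions: pd.DataFrame
    smfish_sizes: pd.Series


# ---------------------------------------------------------------------------
# kNN
# ---------------------------------------------------------------------------


def _unit_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(values, axis=1)
    ok = norms > 0
    unit = np.zeros_like(values, dtype=float)
    unit[ok] = values[ok] / norms[ok, None]
    return unit, ok


def cosine_knn(
    query: CountMatrix,
    reference: CountMatrix,
    params: IntegrationParams,
    chunk_size: int = 1024,
) -> NeighborMap:
    """Exact k-nearest-neighbor search under cosine similarity over the
    shared gene panel.

    Both matrices are restricted to ``params.shared_genes`` (which must be
    present in both); similarity ties are broken by reference cell id in
    lexicographic order. All-zero cells over the panel are excluded and
    reported, not silently dropped.
    """
    if not params.shared_genes:
        raise ValueError("shared_genes must be nonempty")
    q = query.subset_genes(params.shared_genes)
    r = reference.subset_genes(params.shared_genes)

    r_unit, r_ok = _unit_rows(r.values)
    excluded_refs = [c for c, ok in zip(r.cell_ids, r_ok) if not ok]
    ref_ids = np.asarray(r.cell_ids, dtype=object)[r_ok]
    r_unit = r_unit[r_ok]
    if r_unit.shape[0] == 0:
        raise ValueError("no usable reference cells (all zero over panel)")
    # pre-sort references by id so similarity ties resolve lexicographically
    order = np.argsort(ref_ids)
    ref_ids = ref_ids[order]
    r_unit = r_unit[order]

    q_unit, q_ok = _unit_rows(q.values)
    excluded_queries = [c for c, ok in zip(q.cell_ids, q_ok) if not ok]

    k = min(params.k, r_unit.shape[0])
    neighbors: dict[str, list[tuple[str, float]]] = {}
    q_ids = np.asarray(q.cell_ids, dtype=object)
    for start in range(0, q_unit.shape[0], chunk_size):
        stop = min(start + chunk_size, q_unit.shape[0])
        sims = q_unit[start:stop] @ r_unit.T  # chunk x refs
        # stable sort on -sim keeps the id-sorted order within ties
        top = np.argsort(-sims, axis=1, kind="stable")[:, :k]
        for i in range(stop - start):
            qi = start + i
            if not q_ok[qi]:
                continue
            cols = top[i]
            neighbors[q_ids[qi]] = [
                (str(ref_ids[j]), float(np.clip(sims[i, j], -1.0, 1.0)))
                for j in cols
            ]
    return NeighborMap(neighbors, excluded_queries, excluded_refs, k=params.k)


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_expression(
    nm: NeighborMap,
    reference_full: CountMatrix,
    weight_mode: str = "normalized",
) -> ImputedMatrix:
    """Similarity-weighted average of neighbor expression over the full
    reference gene set.

    normalized mode (default): value(q, g) = sum_i s_i ref(r_i, g) / sum_i s_i
    — a convex combination of neighbor values. A query whose similarities
    sum to 0 gets a NaN row, reported in ``missing_cells``.
    """
    if weight_mode not in ("normalized", "unnormalized"):
        raise ValueError("weight_mode must be 'normalized' or 'unnormalized'")
    ref_idx = reference_full.cell_index()
    queries = list(nm.neighbors)
    out = np.full((len(queries), reference_full.n_genes), np.nan)
    missing: list[str] = []
    for i, qid in enumerate(queries):
        pairs = nm.neighbors[qid]
        unknown = [rid for rid, _ in pairs if rid not in ref_idx]
        if unknown:
            raise KeyError(f"neighbor cells absent from reference: {unknown[:5]}")
        rows = [ref_idx[rid] for rid, _ in pairs]
        sims = np.array([s for _, s in pairs], dtype=float)
        if weight_mode == "normalized":
            total = sims.sum()
            if total <= 0:
                missing.append(qid)
                continue
            out[i] = sims @ reference_full.values[rows] / total
        else:
            out[i] = sims @ reference_full.values[rows]
    values = pd.DataFrame(out, index=queries, columns=reference_full.gene_ids)
    return ImputedMatrix(values, stage=reference_full.stage, missing_cells=missing)


# ---------------------------------------------------------------------------
# Reverse projection
# ---------------------------------------------------------------------------


def project_cluster_labels(
    nm: NeighborMap,
    smfish_clusters: Mapping[str, object] | pd.Series,
    params: IntegrationParams,
) -> ProjectionTable:
    """Majority-vote label transfer from smFISH neighbors to scRNA cells.

    Neighbors with similarity <= ``params.min_similarity`` are discarded.
    Among the remaining labels, the unique most frequent label wins; if
    every label occurs once, the cell gets no projection. Frequency ties
    among non-unique labels are broken by larger summed similarity; an
    exact tie there also yields no projection.
    """
    clusters = pd.Series(smfish_clusters)
    rows = []
    for qid, pairs in nm.neighbors.items():
        kept = [(rid, s) for rid, s in pairs if s > params.min_similarity]
        unknown = [rid for rid, _ in kept if rid not in clusters.index]
        if unknown:
            raise KeyError(f"reference cells without cluster label: {unknown[:5]}")
        if not kept:
            rows.append((qid, None, 0, 0.0))
            continue
        votes: dict[object, int] = {}
        simsum: dict[object, float] = {}
        for rid, s in kept:
            lab = clusters.loc[rid]
            votes[lab] = votes.get(lab, 0) + 1
            simsum[lab] = simsum.get(lab, 0.0) + s
        top_votes = max(votes.values())
        if top_votes == 1:
            # all labels unique -> no projection
            rows.append((qid, None, 0, 0.0))
            continue
        leaders = [lab for lab, v in votes.items() if v == top_votes]
        if len(leaders) == 1:
            winner = leaders[0]
        else:
            best = max(simsum[lab] for lab in leaders)
            winners = [lab for lab in leaders if simsum[lab] == best]
            if len(winners) > 1:
                rows.append((qid, None, 0, 0.0))
                continue
            winner = winners[0]
        rows.append((qid, winner, top_votes, simsum[winner]))
    table = pd.DataFrame(rows, columns=["cell_id", "label", "votes",
                                        "summed_similarity"]).set_index("cell_id")
    return ProjectionTable(table)


def contribution_matrix(
    pt: ProjectionTable,
    sc_clusters: Mapping[str, object] | pd.Series,
    smfish_cluster_sizes: Mapping[object, int] | pd.Series,
) -> ContributionMatrix:
    """Cross-tabulate projected smFISH labels against scRNA clusters and
    normalize each row by the smFISH cluster's total cell count."""
    sc = pd.Series(sc_clusters)
    sizes = pd.Series(smfish_cluster_sizes)
    if (sizes <= 0).any():
        raise ValueError("smFISH cluster sizes must be positive")
    proj = pt.table["label"].dropna()
    missing_lab = [lab for lab in proj.unique() if lab not in sizes.index]
    if missing_lab:
        raise KeyError(f"projected labels missing from size table: {missing_lab}")
    unknown = [c for c in proj.index if c not in sc.index]
    if unknown:
        raise KeyError(f"projected cells without scRNA cluster: {unknown[:5]}")
    sc_lab = sc.loc[proj.index]
    counts = pd.crosstab(proj, sc_lab)
    counts = counts.reindex(index=sizes.index, fill_value=0)
    counts.index.name = "smfish_cluster"
    counts.columns.name = "sc_cluster"
    fractions = counts.div(sizes, axis=0)
    return ContributionMatrix(counts=counts, fractions=fractions, smfish_sizes=sizes)


# ---------------------------------------------------------------------------
# Stage merge
# ---------------------------------------------------------------------------


def merge_stage_results(a: ImputedMatrix, b: ImputedMatrix) -> ImputedMatrix:
    """Combine per-stage imputed matrices over the cell union x gene union.

    Cell sets must be disjoint. A gene imputed for only one stage is NaN
    (missing, not zero) for the other stage's cells; the merged gene count
    obeys |A| + |B| - |A n B|.
    """
    overlap = set(a.cell_ids) & set(b.cell_ids)
    if overlap:
        raise ValueError(f"overlapping cell ids: {sorted(overlap)[:5]}")
    genes = list(a.gene_ids) + [g for g in b.gene_ids if g not in set(a.gene_ids)]
    merged = pd.concat([a.values, b.values], axis=0).reindex(columns=genes)
    return ImputedMatrix(
        merged, stage="mixed",
        missing_cells=list(a.missing_cells) + list(b.missing_cells),
    )
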