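"""End-to-end pipeline over a synthetic paired dataset.

Wires the stages in method order — simulate, write/read artifacts,
normalize, integrate (kNN imputation + reverse projection + contribution
matrix), cluster correlations, markers / co-expression / protoplasting
scores, spot-density statistics — with one seed, a resolved-config
snapshot, and deterministic outputs. Defaults follow the published
analysis parameters (k = 5 neighbors, similarity floor 0.3, CV > 0.5,
cluster-sum in [0.1, 20], mean + 4 SD co-expression threshold, strict
marker filters).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

from . import clustercorr, integrate, io_formats, markers, normalize, spatialstats
from .synthdata import (
    CoexprPair, StressGene, SynthConfig, generate_paired_dataset,
    generate_region_expression, generate_spot_table,
)

log = logging.getLogger("spikemap")


@dataclass
class RunConfig:
    """Parameters of an end-to-end run; defaults are the published values."""

    seed: int = 0
    out_dir: str = "spikemap_run"
    k: int = 5
    min_similarity: float = 0.3
    cv_min: float = 0.5
    sum_min: float = 0.1
    sum_max: float = 20.0
    sd_mult: float = 4.0
    marker_mode: str = "strict"
    synth: SynthConfig | None = None  # None -> default_synth_config(seed)


def default_synth_config(seed: int) -> SynthConfig:
    """The study-conditions synthetic dataset: 6 clusters, 1,500 spatial x
    3,000 single cells, a 95-gene shared panel inside 2,000 genes, one
    planted co-expressed pair (latent correlation 0.7) and four planted
    stress genes, each strongly induced in one designated cluster."""
    cfg = SynthConfig(seed=seed)
    genes = cfg.gene_ids()
    n = cfg.n_panel_genes
    pair = CoexprPair(genes[n], genes[n + 1], 0.7)
    # stress genes are near-silent in intact tissue (low baseline) and
    # strongly induced in one designated cluster each
    stress = [
        StressGene(genes[n + 2 + k], clusters=(k,), multiplier=100.0,
                   base_mean=0.05)
        for k in range(4)
    ]
    return SynthConfig(seed=seed, coexpr_pairs=[pair], stress_genes=stress)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the synthetic dataset; write artifacts under
    ``config.out_dir`` and return the headline quantities."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(_resolved(config), indent=1))
    rng_seed = config.seed

    log.info("simulating paired dataset (seed=%d)", rng_seed)
    synth_cfg = config.synth or default_synth_config(rng_seed)
    spatial, cell_table, sc, truth = generate_paired_dataset(synth_cfg)

    io_formats.write_count_matrix(spatial, out / "spatial_counts")
    io_formats.write_count_matrix(sc, out / "sc_counts")
    io_formats.write_cell_table(cell_table, out / "cells.csv")

    # normalization layers
    sp_cpm = normalize.cpm(spatial)
    sc_cpm = normalize.cpm(sc)
    sc_log = normalize.lognormalize(sc)

    # integration: imputation into spatial cells
    panel = synth_cfg.panel_genes()
    params = integrate.IntegrationParams(
        k=config.k, min_similarity=config.min_similarity, shared_genes=panel)
    nm = integrate.cosine_knn(sp_cpm, sc_cpm, params)
    imputed = integrate.impute_expression(nm, sc_cpm)

    # reverse projection of smFISH cluster labels onto scRNA cells
    sp_clusters = cell_table.set_index("cell_id")["cluster"]
    nm_rev = integrate.cosine_knn(sc_cpm, sp_cpm, params)
    projection = integrate.project_cluster_labels(nm_rev, sp_clusters, params)
    sc_clusters = truth.sc_cell_cluster.map(lambda k: f"c{k}")
    sizes = sp_clusters.value_counts()
    contrib = integrate.contribution_matrix(projection, sc_clusters, sizes)
    contrib.fractions.to_csv(out / "contribution_fractions.csv")

    # cluster correlations on the single-cell side
    profile = normalize.cluster_average(sc_log, sc_clusters)
    informative = clustercorr.informative_gene_filter(
        profile, clustercorr.GeneFilterParams(
            cv_min=config.cv_min, sum_min=config.sum_min, sum_max=config.sum_max))
    corr = clustercorr.cluster_correlation_matrix(profile, informative) \
        if len(informative) >= 3 else None
    if corr is not None:
        corr.r.to_csv(out / "cluster_correlations.csv")

    # markers, co-expression, protoplasting
    marker_table = markers.rank_markers(sc_log, sc_clusters)
    marker_lists = markers.filter_markers(marker_table, config.marker_mode)
    coexpr = None
    if synth_cfg.coexpr_pairs:
        coexpr = markers.coexpression_screen(
            sc_log, synth_cfg.coexpr_pairs[0].gene_a, sd_mult=config.sd_mult)
    stress_genes = [sg.gene for sg in synth_cfg.stress_genes]
    bulk_detected = [g for g in sc.gene_ids if g not in stress_genes]
    proto = markers.protoplasting_scores(
        {cl: gl for cl, gl in marker_lists.items() if gl},
        stress_genes, bulk_detected)
    marker_table.to_csv(out / "markers.csv", index=False)

    # spatial statistics on generated spots
    spot_table = generate_spot_table(spatial, cell_table, cell_radius=2.5,
                                     seed=rng_seed + 1)
    io_formats.write_spot_table(spot_table, out / "spots.csv")
    extent = synth_cfg.grid_extent
    region = io_formats.PolygonRegion.from_vertices(
        "tile0", [(0, 0), (extent / 3, 0), (extent / 3, extent / 2),
                  (0, extent / 2)])
    dens = spatialstats.spot_density(spot_table, region, panel[0])

    region_table = generate_region_expression(
        truth, region_effects={panel[0]: (3.0, 1.0, 1.0)}, noise_sd=0.1,
        seed=rng_seed + 2)
    sub = region_table[region_table["gene_id"].isin(panel[:20])]
    assignments = spatialstats.region_assignment(sub)

    results = {
        "n_spatial_cells": spatial.n_cells,
        "n_sc_cells": sc.n_cells,
        "n_imputed_genes": imputed.values.shape[1],
        "n_projected_cells": int(projection.table["label"].notna().sum()),
        "n_informative_genes": len(informative),
        "n_marker_records": len(marker_table),
        "coexpr_threshold": coexpr.threshold if coexpr else None,
        "protoplasting_correlation": proto.correlation,
        "example_density": dens.density,
        "n_region_winners": int(assignments["winner"].notna().sum()),
    }
    (out / "results.json").write_text(json.dumps(results, indent=1))
    log.info("pipeline complete: %s", results)
    return results


def _resolved(config: RunConfig) -> dict:
    d = asdict(config)
    synth = config.synth or default_synth_config(config.seed)
    d["synth"] = asdict(synth)
    return d
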