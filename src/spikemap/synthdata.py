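"""Paired synthetic smFISH / scRNA-seq data with known ground truth.

Both modalities draw negative-binomial counts from the same cluster-specific
mean profile: the spatial modality sees only the shared gene panel (the
smFISH probe set), the single-cell modality sees the full gene universe.
Spatial cells get cluster-contiguous coordinates on a tiled grid, planted
co-expressed gene pairs share a per-cell lognormal latent factor, and
planted protoplasting-stress genes are induced only in designated clusters
of the single-cell modality.

The negative binomial is parameterized by mean mu and dispersion alpha with
variance mu + alpha * mu^2; alpha = 0 degenerates to Poisson.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

# Defaults mirror the study's scale ratios at desk size: a ~hundred-gene
# shared panel inside a large transcriptome, a few thousand cells per
# modality, moderate overdispersion.
DEFAULT_N_CLUSTERS = 6
DEFAULT_N_SPATIAL_CELLS = 1500
DEFAULT_N_SC_CELLS = 3000
DEFAULT_N_PANEL_GENES = 95
DEFAULT_N_SC_GENES = 2000
DEFAULT_NB_DISPERSION = 0.3
DEFAULT_LIBRARY_SIZE_SPATIAL = 300.0
DEFAULT_LIBRARY_SIZE_SC = 5000.0
DEFAULT_GRID_EXTENT = 600.0
DEFAULT_CLUSTER_LOGFOLD_SD = 1.0
DEFAULT_LIBRARY_LOG_SD = 0.3
COEXPR_BASE_MEAN = 5.0  # baseline (relative units) for planted pair genes


@dataclass(frozen=True)
class CoexprPair:
    """A planted co-expressed gene pair with latent correlation in [0, 1]."""

    gene_a: str
    gene_b: str
    rho: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("latent correlation must lie in [0, 1]")


@dataclass(frozen=True)
class StressGene:
    """A gene induced by a given multiplier, only in ``clusters`` of the
    single-cell modality (emulating protoplasting stress response).

    ``base_mean``, when given, overrides the gene's drawn baseline — set it
    to 0 for a gene silent in intact tissue and (multiplicatively) absent
    everywhere, or to a small value for a gene detectable only when induced.
    """

    gene: str
    clusters: tuple[int, ...]
    multiplier: float
    base_mean: float | None = None


@dataclass
class SynthConfig:
    n_clusters: int = DEFAULT_N_CLUSTERS
    n_spatial_cells: int = DEFAULT_N_SPATIAL_CELLS
    n_sc_cells: int = DEFAULT_N_SC_CELLS
    n_panel_genes: int = DEFAULT_N_PANEL_GENES
    n_sc_genes: int = DEFAULT_N_SC_GENES
    nb_dispersion: float = DEFAULT_NB_DISPERSION
    library_size_spatial: float = DEFAULT_LIBRARY_SIZE_SPATIAL
    library_size_sc: float = DEFAULT_LIBRARY_SIZE_SC
    coexpr_pairs: list[CoexprPair] = field(default_factory=list)
    stress_genes: list[StressGene] = field(default_factory=list)
    grid_extent: float = DEFAULT_GRID_EXTENT
    cluster_logfold_sd: float = DEFAULT_CLUSTER_LOGFOLD_SD
    library_log_sd: float = DEFAULT_LIBRARY_LOG_SD
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_clusters", "n_spatial_cells", "n_sc_cells",
                     "n_panel_genes", "n_sc_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_panel_genes > self.n_sc_genes:
            raise ValueError("n_panel_genes must not exceed n_sc_genes")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be nonnegative")
        if self.library_size_spatial <= 0 or self.library_size_sc <= 0:
            raise ValueError("library sizes must be positive")
        if self.grid_extent <= 0:
            raise ValueError("grid_extent must be positive")
        genes = self.gene_ids()
        universe = set(genes)
        for pair in self.coexpr_pairs:
            if pair.gene_a not in universe or pair.gene_b not in universe:
                raise ValueError(f"planted pair {pair} outside gene universe")
        for sg in self.stress_genes:
            if sg.gene not in universe:
                raise ValueError(f"planted stress gene {sg.gene!r} outside universe")
            for k in sg.clusters:
                if not 0 <= k < self.n_clusters:
                    raise ValueError(f"stress cluster {k} out of range")

    def gene_ids(self) -> list[str]:
        """Panel genes first (g0000..), then single-cell-only genes."""
        return [f"g{i:04d}" for i in range(self.n_sc_genes)]

    def panel_genes(self) -> list[str]:
        return self.gene_ids()[: self.n_panel_genes]


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery checks.

    ``cluster_mean_matrix`` is the shared relative expression profile
    (clusters x genes, as a DataFrame); multiply by a modality's library
    scale (``spatial_scale`` / ``sc_scale``) and a cell's induced factors
    to get expected counts.
    """

    cluster_mean_matrix: pd.DataFrame
    spatial_cell_cluster: pd.Series
    sc_cell_cluster: pd.Series
    planted_coexpr: list[CoexprPair]
    planted_stress: list[StressGene]
    spatial_scale: float
    sc_scale: float

    def __post_init__(self) -> None:
        if (self.cluster_mean_matrix.to_numpy() < 0).any():
            raise ValueError("cluster_mean_matrix must be nonnegative")
        n = len(self.cluster_mean_matrix)
        for labels in (self.spatial_cell_cluster, self.sc_cell_cluster):
            lab = labels.to_numpy()
            if lab.size and (lab.min() < 0 or lab.max() >= n):
                raise ValueError("cell label outside the valid cluster range")

    def expected_counts(self, modality: str) -> pd.DataFrame:
        scale = self.spatial_scale if modality == "smFISH" else self.sc_scale
        return self.cluster_mean_matrix * scale


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mu, alpha) with variance mu + alpha mu^2, via gamma-Poisson."""
    if alpha == 0.0:
        return rng.poisson(mu)
    size = 1.0 / alpha  # gamma shape
    lam = rng.gamma(shape=size, scale=mu * alpha)
    return rng.poisson(lam)


def _latent_factors(
    rng: np.random.Generator,
    pairs: Sequence[CoexprPair],
    gene_index: dict[str, int],
    n_cells: int,
    n_genes: int,
) -> np.ndarray:
    """Per-cell lognormal factors coupling each planted pair.

    Per pair: shared z ~ N(0,1) per cell, per-gene mix
    sqrt(rho) z + sqrt(1-rho) eps, exponentiated with mean-1 correction so
    expectations (and hence ground-truth means) are unchanged.
    """
    factors = np.ones((n_cells, n_genes))
    for pair in pairs:
        z = rng.standard_normal(n_cells)
        for gene in (pair.gene_a, pair.gene_b):
            eps = rng.standard_normal(n_cells)
            u = math.sqrt(pair.rho) * z + math.sqrt(1.0 - pair.rho) * eps
            factors[:, gene_index[gene]] *= np.exp(u - 0.5)
    return factors


def generate_paired_dataset(
    config: SynthConfig,
) -> tuple[CountMatrix, pd.DataFrame, CountMatrix, GroundTruth]:
    """Generate (spatial counts, spatial cell table, scRNA counts, truth).

    The seed in ``config`` fully determines the output.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_ids()
    gene_index = {g: j for j, g in enumerate(genes)}
    K = config.n_clusters

    # Shared relative profile: lognormal baseline per gene times
    # cluster-specific lognormal fold changes.
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_sc_genes)
    folds = np.exp(rng.normal(0.0, config.cluster_logfold_sd,
                              size=(K, config.n_sc_genes)))
    # Planted co-expressed pairs are co-regulated: both genes share one
    # cluster profile and a moderate baseline, as real co-expressed
    # transcription-factor pairs do (cluster structure is itself a driver
    # of observed co-expression).
    for pair in config.coexpr_pairs:
        ja, jb = gene_index[pair.gene_a], gene_index[pair.gene_b]
        folds[:, jb] = folds[:, ja]
        base[ja] = base[jb] = COEXPR_BASE_MEAN
    for sg in config.stress_genes:
        if sg.base_mean is not None:
            base[gene_index[sg.gene]] = sg.base_mean
    mean_matrix = base[None, :] * folds  # clusters x genes

    panel_cols = np.arange(config.n_panel_genes)
    sp_row_mean = float(mean_matrix[:, panel_cols].sum(axis=1).mean())
    sc_row_mean = float(mean_matrix.sum(axis=1).mean())
    spatial_scale = config.library_size_spatial / sp_row_mean
    sc_scale = config.library_size_sc / sc_row_mean

    # Cluster labels: spatial cells in contiguous tiles, sc cells shuffled.
    sp_labels = _tile_assignment(config.n_spatial_cells, K)
    sc_labels = rng.integers(0, K, size=config.n_sc_cells)

    sp_cells = [f"sp{i:05d}" for i in range(config.n_spatial_cells)]
    sc_cells = [f"sc{i:05d}" for i in range(config.n_sc_cells)]

    # Per-cell library factor, lognormal with mean 1.
    s = config.library_log_sd
    sp_lib = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=config.n_spatial_cells)
    sc_lib = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=config.n_sc_cells)

    sp_factors = _latent_factors(rng, config.coexpr_pairs, gene_index,
                                 config.n_spatial_cells, config.n_sc_genes)
    sc_factors = _latent_factors(rng, config.coexpr_pairs, gene_index,
                                 config.n_sc_cells, config.n_sc_genes)

    # Stress induction: sc modality only, designated clusters only.
    stress_mult = np.ones((K, config.n_sc_genes))
    for sg in config.stress_genes:
        for k in sg.clusters:
            stress_mult[k, gene_index[sg.gene]] *= sg.multiplier

    sp_mu = (mean_matrix[np.ix_(sp_labels, panel_cols)]
             * sp_factors[:, panel_cols] * sp_lib[:, None] * spatial_scale)
    sc_mu = (mean_matrix[sc_labels, :] * stress_mult[sc_labels, :]
             * sc_factors * sc_lib[:, None] * sc_scale)

    sp_counts = _nb_sample(rng, sp_mu, config.nb_dispersion)
    sc_counts = _nb_sample(rng, sc_mu, config.nb_dispersion)

    x, y = _tile_coordinates(rng, sp_labels, K, config.grid_extent)
    cell_table = pd.DataFrame({
        "cell_id": sp_cells,
        "x": x,
        "y": y,
        "area": np.full(config.n_spatial_cells, 25.0),
        "section_id": "synthetic-1",
        "stage": "W2.5",
        "cluster": [f"c{k}" for k in sp_labels],
    })

    spatial = CountMatrix(sp_counts, sp_cells, genes[: config.n_panel_genes],
                          modality="smFISH", stage="W2.5", layer="raw")
    sc = CountMatrix(sc_counts, sc_cells, genes,
                     modality="scRNA", stage="W2.5", layer="raw")
    truth = GroundTruth(
        cluster_mean_matrix=pd.DataFrame(
            mean_matrix, index=[f"c{k}" for k in range(K)], columns=genes),
        spatial_cell_cluster=pd.Series(sp_labels, index=sp_cells, name="cluster"),
        sc_cell_cluster=pd.Series(sc_labels, index=sc_cells, name="cluster"),
        planted_coexpr=list(config.coexpr_pairs),
        planted_stress=list(config.stress_genes),
        spatial_scale=spatial_scale,
        sc_scale=sc_scale,
    )
    return spatial, cell_table, sc, truth


def _tile_assignment(n_cells: int, n_clusters: int) -> np.ndarray:
    """Deterministic near-equal split of cells over cluster tiles."""
    return (np.arange(n_cells) * n_clusters) // n_cells


def _tile_coordinates(
    rng: np.random.Generator, labels: np.ndarray, n_clusters: int, extent: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-contiguous layout: each cluster owns one rectangular tile of
    the [0, extent]^2 grid; cell centers are uniform jitter within the tile."""
    n_cols = int(math.ceil(math.sqrt(n_clusters)))
    n_rows = int(math.ceil(n_clusters / n_cols))
    tile_w = extent / n_cols
    tile_h = extent / n_rows
    col = labels % n_cols
    row = labels // n_cols
    x = (col + rng.random(labels.size)) * tile_w
    y = (row + rng.random(labels.size)) * tile_h
    return x, y


def generate_spot_table(
    spatial: CountMatrix, cell_table: pd.DataFrame, cell_radius: float, seed: int
) -> pd.DataFrame:
    """Explode each (cell, gene) count c into exactly c spot records placed
    uniformly within the cell's disc of ``cell_radius`` um.

    Per gene, total spots equal the count-matrix column sum.
    """
    if cell_radius < 0:
        raise ValueError("cell_radius must be nonnegative")
    if spatial.layer != "raw":
        raise ValueError("spot generation needs the raw count layer")
    ct = cell_table.set_index("cell_id")
    missing = [c for c in spatial.cell_ids if c not in ct.index]
    if missing:
        raise ValueError(f"cells without coordinates: {missing[:5]}")
    rng = np.random.default_rng(seed)
    counts = spatial.values.astype(int)
    cell_rows, gene_cols = np.nonzero(counts)
    reps = counts[cell_rows, gene_cols]
    cell_rep = np.repeat(cell_rows, reps)
    gene_rep = np.repeat(gene_cols, reps)
    n_spots = cell_rep.size
    r = cell_radius * np.sqrt(rng.random(n_spots))
    theta = rng.random(n_spots) * 2.0 * np.pi
    cx = ct.loc[spatial.cell_ids, "x"].to_numpy(dtype=float)
    cy = ct.loc[spatial.cell_ids, "y"].to_numpy(dtype=float)
    sec = ct.loc[spatial.cell_ids, "section_id"].to_numpy()
    spots = pd.DataFrame({
        "gene_id": np.asarray(spatial.gene_ids, dtype=object)[gene_rep],
        "x": cx[cell_rep] + r * np.cos(theta),
        "y": cy[cell_rep] + r * np.sin(theta),
        "section_id": sec[cell_rep],
        "cell_id": np.asarray(spatial.cell_ids, dtype=object)[cell_rep],
    })
    return spots


def generate_region_expression(
    truth: GroundTruth,
    n_regions: int = 3,
    n_reps: int = 3,
    region_effects: dict[str, Sequence[float]] | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    region_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Bulk-like gene x region x replicate table on a TMM-like scale.

    value = base expression (cluster-mean average) x region multiplier x
    lognormal(0, noise_sd) noise. ``region_effects`` maps gene -> one
    multiplier per region (genes absent from the map get all-ones).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per region")
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    region_effects = region_effects or {}
    for g, mult in region_effects.items():
        if len(mult) != n_regions:
            raise ValueError(f"gene {g!r}: need {n_regions} region multipliers")
        if any(m <= 0 for m in mult):
            raise ValueError(f"gene {g!r}: multipliers must be positive")
    if region_names is None:
        region_names = (["base", "middle", "tip"] if n_regions == 3
                        else [f"region{i}" for i in range(n_regions)])
    rng = np.random.default_rng(seed)
    base = truth.cluster_mean_matrix.mean(axis=0)
    rows = []
    for gene in base.index:
        mult = np.asarray(region_effects.get(gene, np.ones(n_regions)), dtype=float)
        for ri, region in enumerate(region_names):
            for rep in range(1, n_reps + 1):
                noise = rng.lognormal(0.0, noise_sd) if noise_sd > 0 else 1.0
                rows.append((gene, region, rep, base[gene] * mult[ri] * noise))
    return pd.DataFrame(rows, columns=["gene_id", "region", "replicate", "value"])
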