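"""On-disk formats and validated in-memory containers.

Matrices travel as Matrix Market triplets with TSV gene/barcode sidecars
(genes x cells on disk, the CellRanger convention; cells x genes in memory).
Tabular data are comma-separated UTF-8 CSV with a header row; delineated
regions are GeoJSON polygons; gene lists and homeolog maps are TSV.

All readers validate and reject rather than coerce; every writer produces
files its paired reader round-trips bit-exactly for integers and to 1e-12
relative tolerance for reals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from shapely.geometry import Polygon, shape

MODALITIES = ("smFISH", "scRNA", "imputed")
STAGES = ("W1.5", "W2.5", "W3.5", "mixed")
LAYERS = ("raw", "cpm", "lognorm")

CELL_TABLE_REQUIRED = ("cell_id", "x", "y", "section_id")
SPOT_TABLE_REQUIRED = ("gene_id", "x", "y", "section_id")
REGION_TABLE_REQUIRED = ("gene_id", "region", "replicate", "value")


class FormatError(ValueError):
    """Raised when an on-disk artifact fails validation."""


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Cells x genes expression matrix with modality/stage/layer tags.

    ``values`` is a dense float array (desk-scale data); the raw layer must
    be integer-valued and nonnegative. NaN entries are allowed only in the
    merged imputed layer, where they mark genes not imputed for a stage.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    modality: str = "scRNA"
    stage: str = "mixed"
    layer: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.ndim != 2:
            raise FormatError("values must be 2-D (cells x genes)")
        n_cells, n_genes = self.values.shape
        if n_cells != len(self.cell_ids) or n_genes != len(self.gene_ids):
            raise FormatError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.cell_ids)} cell ids / {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise FormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise FormatError("duplicate gene ids")
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage {self.stage!r}")
        if self.layer not in LAYERS:
            raise FormatError(f"unknown layer {self.layer!r}")
        if self.layer == "raw":
            if np.isnan(self.values).any():
                raise FormatError("raw layer contains NaN")
            if (self.values < 0).any():
                raise FormatError("negative values in raw layer")
            if not np.array_equal(self.values, np.round(self.values)):
                raise FormatError("raw layer is not integer-valued")
        elif self.modality != "imputed" and np.isnan(self.values).any():
            raise FormatError("NaN values outside the merged imputed layer")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        """Column subset in the given gene order; unknown genes are an error."""
        idx = self.gene_index()
        missing = [g for g in genes if g not in idx]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        cols = [idx[g] for g in genes]
        return CountMatrix(
            self.values[:, cols], list(self.cell_ids), list(genes),
            modality=self.modality, stage=self.stage, layer=self.layer,
        )

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index()
        missing = [c for c in cells if c not in idx]
        if missing:
            raise KeyError(f"cells absent from matrix: {missing[:5]}")
        rows = [idx[c] for c in cells]
        return CountMatrix(
            self.values[rows, :], list(cells), list(self.gene_ids),
            modality=self.modality, stage=self.stage, layer=self.layer,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def write_count_matrix(m: CountMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` (genes x cells), ``<prefix>.genes.tsv``,
    ``<prefix>.barcodes.tsv`` and a ``<prefix>.meta.json`` sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    on_disk = scipy.sparse.coo_matrix(m.values.T)  # genes x cells
    if m.layer == "raw":
        on_disk = on_disk.astype(np.int64)
        scipy.io.mmwrite(str(prefix) + ".mtx", on_disk, field="integer")
    else:
        scipy.io.mmwrite(str(prefix) + ".mtx", on_disk, precision=17)
    Path(str(prefix) + ".genes.tsv").write_text("".join(g + "\n" for g in m.gene_ids))
    Path(str(prefix) + ".barcodes.tsv").write_text("".join(c + "\n" for c in m.cell_ids))
    meta = {
        "modality": m.modality, "stage": m.stage, "layer": m.layer,
        "orientation": "genes-by-cells",
    }
    Path(str(prefix) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_count_matrix(
    prefix: str | Path, orientation: str | None = None
) -> CountMatrix:
    """Read the MTX triplet + sidecars written by :func:`write_count_matrix`.

    ``orientation`` overrides the sidecar/default orientation
    ("genes-by-cells" or "cells-by-genes").
    """
    prefix = Path(prefix)
    meta: dict = {}
    meta_path = Path(str(prefix) + ".meta.json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    orientation = orientation or meta.get("orientation", "genes-by-cells")
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise FormatError(f"unknown orientation {orientation!r}")
    mat = scipy.io.mmread(str(prefix) + ".mtx")
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = Path(str(prefix) + ".genes.tsv").read_text().splitlines()
    cells = Path(str(prefix) + ".barcodes.tsv").read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    cells = [c.split("\t")[0] for c in cells if c]
    if orientation == "genes-by-cells":
        dense = dense.T
    if dense.shape != (len(cells), len(genes)):
        raise FormatError(
            f"dimension mismatch between MTX header {dense.shape[::-1]} and "
            f"id files ({len(genes)} genes, {len(cells)} barcodes)"
        )
    return CountMatrix(
        dense, cells, genes,
        modality=meta.get("modality", "scRNA"),
        stage=meta.get("stage", "mixed"),
        layer=meta.get("layer", "raw"),
    )


def read_dense_count_matrix(path: str | Path, **tags) -> CountMatrix:
    """Read a dense CSV table (cells in rows, genes in columns, ids in
    the first column / header)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")
    gene_cols = header[1:]
    if len(set(gene_cols)) != len(gene_cols):
        raise FormatError("duplicate gene id in dense table")
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise FormatError("duplicate cell id in dense table")
    return CountMatrix(df.to_numpy(dtype=float), list(df.index.astype(str)),
                       list(df.columns.astype(str)), **tags)


# ---------------------------------------------------------------------------
# Tabular readers
# ---------------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing required column(s) {missing}")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Cell table: cell_id, x, y (um), section_id, optional area/stage/cluster.

    Unknown columns are preserved untouched.
    """
    df = pd.read_csv(path)
    _require_columns(df, CELL_TABLE_REQUIRED, "cell table")
    if df["cell_id"].duplicated().any():
        raise FormatError("cell table: duplicate cell_id")
    for col in ("x", "y"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise FormatError(f"cell table: non-finite {col}")
    if "area" in df.columns:
        area = df["area"].to_numpy(dtype=float)
        if np.any(area[~np.isnan(area)] <= 0):
            raise FormatError("cell table: non-positive area")
    df["cell_id"] = df["cell_id"].astype(str)
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, CELL_TABLE_REQUIRED, "cell table")
    df.to_csv(path, index=False)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    """Spot table: gene_id, x, y (um), section_id."""
    df = pd.read_csv(path)
    _require_columns(df, SPOT_TABLE_REQUIRED, "spot table")
    if (df["gene_id"].astype(str).str.len() == 0).any() or df["gene_id"].isna().any():
        raise FormatError("spot table: empty gene_id")
    for col in ("x", "y"):
        if not np.isfinite(df[col].to_numpy(dtype=float)).all():
            raise FormatError(f"spot table: non-finite {col}")
    df["gene_id"] = df["gene_id"].astype(str)
    return df


def write_spot_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, SPOT_TABLE_REQUIRED, "spot table")
    df.to_csv(path, index=False)


def read_region_table(path: str | Path) -> pd.DataFrame:
    """Region-level bulk expression: gene_id, region, replicate, value
    (pre-normalized, TMM scale). Every (gene, region) needs >= 2 replicates."""
    df = pd.read_csv(path)
    _require_columns(df, REGION_TABLE_REQUIRED, "region table")
    if (df["value"].to_numpy(dtype=float) < 0).any():
        raise FormatError("region table: negative expression value")
    counts = df.groupby(["gene_id", "region"]).size()
    if (counts < 2).any():
        bad = counts[counts < 2].index[0]
        raise FormatError(f"region table: fewer than 2 replicates for {bad}")
    df["gene_id"] = df["gene_id"].astype(str)
    df["region"] = df["region"].astype(str)
    return df


def write_region_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, REGION_TABLE_REQUIRED, "region table")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Regions (GeoJSON)
# ---------------------------------------------------------------------------


@dataclass
class PolygonRegion:
    """A manually delineated region in um coordinates (image convention:
    y grows downward). The ring must be simple (non-self-intersecting)."""

    name: str
    polygon: Polygon = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.polygon.exterior.coords) - 1 < 3:
            raise FormatError("polygon needs >= 3 vertices")
        if not self.polygon.is_valid:
            raise FormatError("polygon ring is self-intersecting or degenerate")
        if self.polygon.area <= 0:
            raise FormatError("polygon has zero area")

    @property
    def area(self) -> float:
        """Region area in um^2."""
        return float(self.polygon.area)

    @property
    def vertices(self) -> list[tuple[float, float]]:
        return [(float(x), float(y)) for x, y in self.polygon.exterior.coords]

    def covers_points(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership (even-odd interior plus the ring)."""
        import shapely

        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.covers(self.polygon, pts)

    @classmethod
    def from_vertices(cls, name: str, vertices: Sequence[tuple[float, float]]) -> "PolygonRegion":
        return cls(name, Polygon(vertices))


def read_polygon(path: str | Path, name: str | None = None) -> PolygonRegion:
    """Read a GeoJSON Polygon (bare geometry, Feature, or a
    single-feature FeatureCollection)."""
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "FeatureCollection":
        feats = obj.get("features", [])
        if len(feats) != 1:
            raise FormatError("expected exactly one feature in FeatureCollection")
        obj = feats[0]
    props: Mapping = {}
    if obj.get("type") == "Feature":
        props = obj.get("properties") or {}
        obj = obj["geometry"]
    if obj.get("type") != "Polygon":
        raise FormatError(f"expected Polygon geometry, got {obj.get('type')!r}")
    geom = shape(obj)
    return PolygonRegion(name or str(props.get("name", Path(path).stem)), geom)


def write_polygon(region: PolygonRegion, path: str | Path) -> None:
    gj = {
        "type": "Feature",
        "properties": {"name": region.name},
        "geometry": {"type": "Polygon", "coordinates": [list(region.vertices)]},
    }
    Path(path).write_text(json.dumps(gj))


# ---------------------------------------------------------------------------
# Gene lists and homeolog maps
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line (first TSV column); blanks skipped,
    duplicates rejected."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            genes.append(line.split("\t")[0])
    if len(set(genes)) != len(genes):
        raise FormatError("gene list contains duplicates")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_homeolog_map(path: str | Path) -> dict[str, list[str]]:
    """TSV of (group_id, member gene id) rows -> group_id -> members.

    A gene may belong to exactly one group (homeolog triads partition genes).
    """
    groups: dict[str, list[str]] = {}
    seen: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"homeolog map line {ln}: need group and gene columns")
        group, gene = parts[0], parts[1]
        if gene in seen and seen[gene] != group:
            raise FormatError(
                f"homeolog map: gene {gene!r} assigned to groups "
                f"{seen[gene]!r} and {group!r}"
            )
        if gene in seen:
            raise FormatError(f"homeolog map: gene {gene!r} listed twice in {group!r}")
        seen[gene] = group
        groups.setdefault(group, []).append(gene)
    return groups


def write_homeolog_map(groups: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [f"{grp}\t{g}\n" for grp, members in groups.items() for g in members]
    Path(path).write_text("".join(lines))
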