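"""Spot-density quantification and region statistics.

Hybridization density for a gene in a delineated region is the number of
its smFISH spots inside the region (boundary inclusive) per 100 um^2.
Between-stage comparisons average technical replicates (sections from the
same spike) first, then run a two-sided Welch t-test on per-spike
densities. Region-of-spike assignment takes a pre-normalized bulk table
(gene x region x replicate), runs Tukey HSD over the regions and declares
the max-mean region the winner when it significantly beats the runner-up.
Cluster region enrichment is a chi-square goodness-of-fit of marker-gene
winning regions against a uniform distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PolygonRegion

REGIONS = ("base", "middle", "tip")


@dataclass
class DensityRecord:
    """Spot density for one gene in one region of one section."""

    gene_id: str
    section_id: str
    region_name: str
    spot_count: int
    region_area: float     # um^2
    spike_id: str | None = None   # biological replicate
    stage: str | None = None

    @property
    def density(self) -> float:
        """Spots per 100 um^2."""
        return self.spot_count / self.region_area * 100.0


@dataclass
class StageComparison:
    fold_change: float
    p: float
    stage_means: dict
    per_spike: pd.DataFrame
    zero_denominator: bool = False


@dataclass
class RegionAssignment:
    gene_id: str
    winner: str | None
    region_means: dict
    tukey_p: dict            # (region_i, region_j) -> p, i < j in region order
    degenerate: bool = False  # zero within-group variance with unequal means


@dataclass
class EnrichmentResult:
    cluster: object
    counts: pd.Series        # winners per region
    chi2: float
    df: int
    p: float
    small_count_warning: bool = False
    n_assigned: int = 0


# ---------------------------------------------------------------------------
# Spot density
# ---------------------------------------------------------------------------


def spot_density(
    spots: pd.DataFrame,
    region: PolygonRegion,
    gene: str,
    section_id: str | None = None,
    spike_id: str | None = None,
    stage: str | None = None,
) -> DensityRecord:
    """Count the gene's spots inside the region (boundary inclusive,
    even-odd rule) and convert to spots per 100 um^2."""
    if region.area <= 0:
        raise ValueError("region has zero area")
    sub = spots[spots["gene_id"] == gene]
    if section_id is not None:
        sub = sub[sub["section_id"] == section_id]
    if len(sub):
        inside = region.covers_points(sub["x"].to_numpy(), sub["y"].to_numpy())
        count = int(inside.sum())
    else:
        count = 0
    return DensityRecord(
        gene_id=gene, section_id=section_id or "all", region_name=region.name,
        spot_count=count, region_area=region.area, spike_id=spike_id,
        stage=stage,
    )


def compare_stage_density(
    records: Sequence[DensityRecord], stage_of: Mapping[str, str] | None = None
) -> StageComparison:
    """Between-stage density comparison for one gene.

    Technical replicates (same spike) are averaged into one per-spike
    density first; a two-sided Welch t-test then compares the two stages'
    per-spike densities. Fold change is mean(stage1) / mean(stage2) in the
    stages' sorted order; a zero denominator yields inf with a flag, never
    an exception. With fewer than 2 spikes in a stage, p is missing but the
    fold change is still reported.
    """
    rows = []
    for rec in records:
        stage = rec.stage if rec.stage is not None else (
            stage_of[rec.section_id] if stage_of else None)
        if stage is None:
            raise ValueError(f"no stage for section {rec.section_id!r}")
        spike = rec.spike_id or rec.section_id
        rows.append((stage, spike, rec.density))
    df = pd.DataFrame(rows, columns=["stage", "spike_id", "density"])
    per_spike = (df.groupby(["stage", "spike_id"], as_index=False)["density"]
                 .mean())
    stages = sorted(per_spike["stage"].unique())
    if len(stages) != 2:
        raise ValueError(f"need exactly 2 stages, got {stages}")
    a = per_spike.loc[per_spike["stage"] == stages[0], "density"].to_numpy()
    b = per_spike.loc[per_spike["stage"] == stages[1], "density"].to_numpy()
    mean_a, mean_b = float(a.mean()), float(b.mean())
    zero_den = mean_b == 0.0
    fold = math.inf if zero_den and mean_a > 0 else (
        float("nan") if zero_den else mean_a / mean_b)
    if len(a) >= 2 and len(b) >= 2:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    else:
        p = float("nan")
    return StageComparison(
        fold_change=fold, p=p,
        stage_means={stages[0]: mean_a, stages[1]: mean_b},
        per_spike=per_spike, zero_denominator=zero_den,
    )


# ---------------------------------------------------------------------------
# Region assignment (bulk Tukey)
# ---------------------------------------------------------------------------


def region_assignment(
    table: pd.DataFrame, alpha: float = 0.05, require_all: bool = False
) -> pd.DataFrame:
    """Per gene: Tukey HSD over region replicate values; the region with
    the largest mean wins if its contrast with the runner-up has p < alpha
    (with ``require_all``, it must beat every other region).

    Returns a frame indexed by gene with winner (or None), per-region
    means, the runner-up Tukey p, and a degeneracy flag (zero within-group
    variance everywhere with unequal means -> winner assigned, p ~ 0,
    flagged).
    """
    out = []
    for gene, sub in table.groupby("gene_id", sort=True):
        groups = {reg: g["value"].to_numpy(dtype=float)
                  for reg, g in sub.groupby("region", sort=True)}
        regions = list(groups)
        if len(regions) < 2:
            raise ValueError(f"gene {gene!r}: need >= 2 regions")
        if any(len(v) < 2 for v in groups.values()):
            raise ValueError(f"gene {gene!r}: need >= 2 replicates per region")
        means = {reg: float(v.mean()) for reg, v in groups.items()}
        order = sorted(regions, key=lambda r: means[r], reverse=True)
        sse = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        degenerate = sse == 0.0 and len(set(means.values())) > 1
        tukey_p: dict[tuple[str, str], float] = {}
        if degenerate:
            for i, ri in enumerate(regions):
                for rj in regions[i + 1:]:
                    tukey_p[(ri, rj)] = 0.0 if means[ri] != means[rj] else 1.0
        else:
            res = stats.tukey_hsd(*[groups[r] for r in regions])
            for i, ri in enumerate(regions):
                for j in range(i + 1, len(regions)):
                    tukey_p[(ri, regions[j])] = float(res.pvalue[i, j])

        def pair_p(r1: str, r2: str) -> float:
            key = (r1, r2) if (r1, r2) in tukey_p else (r2, r1)
            return tukey_p[key]

        top = order[0]
        rivals = order[1:] if require_all else order[1:2]
        won = bool(rivals) and all(
            means[top] > means[r] and pair_p(top, r) < alpha for r in rivals)
        winner: str | None = top if won else None
        out.append({
            "gene_id": gene, "winner": winner, "degenerate": degenerate,
            "runner_up_p": pair_p(order[0], order[1]) if len(order) > 1 else np.nan,
            **{f"mean_{r}": means[r] for r in regions},
        })
    return pd.DataFrame(out).set_index("gene_id")


# ---------------------------------------------------------------------------
# Region enrichment (chi-square)
# ---------------------------------------------------------------------------


def region_enrichment(
    markers: Iterable[str],
    assignments: pd.DataFrame,
    cluster: object = None,
    regions: Sequence[str] = REGIONS,
    min_assigned: int = 5,
) -> EnrichmentResult:
    """Chi-square goodness-of-fit of the cluster's marker winning regions
    against a uniform expectation; df = #regions - 1. Markers without a
    winner are excluded; fewer than ``min_assigned`` assigned genes sets a
    small-count warning flag."""
    winners = []
    for g in markers:
        if g in assignments.index:
            w = assignments.loc[g, "winner"]
            if w is not None and not (isinstance(w, float) and np.isnan(w)):
                winners.append(w)
    counts = pd.Series(
        {r: sum(w == r for w in winners) for r in regions}, name="count")
    n = int(counts.sum())
    if n == 0:
        return EnrichmentResult(cluster, counts, float("nan"),
                                len(regions) - 1, float("nan"),
                                small_count_warning=True, n_assigned=0)
    chi2, p = stats.chisquare(counts.to_numpy())
    return EnrichmentResult(
        cluster, counts, float(chi2), len(regions) - 1, float(p),
        small_count_warning=n < min_assigned, n_assigned=n,
    )
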