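import numpy as np
import pandas as pd
import pytest

from spikemap import CountMatrix, SynthConfig, generate_paired_dataset
from spikemap.pipeline import default_synth_config


@pytest.fixture(scope="session")
def default_dataset():
    """The study-conditions paired dataset (6 clusters, 1500 spatial x
    3000 single cells, 95-of-2000 shared panel) at a fixed seed."""
    cfg = default_synth_config(1)
    spatial, cell_table, sc, truth = generate_paired_dataset(cfg)
    return cfg, spatial, cell_table, sc, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A faster paired dataset for structural checks."""
    cfg = SynthConfig(
        seed=7, n_clusters=3, n_spatial_cells=120, n_sc_cells=200,
        n_panel_genes=20, n_sc_genes=60,
    )
    spatial, cell_table, sc, truth = generate_paired_dataset(cfg)
    return cfg, spatial, cell_table, sc, truth


@pytest.fixture
def toy_raw_matrix():
    values = np.array([
        [5, 0, 0, 0],
        [10, 20, 15, 5],
        [100, 200, 100, 100],
    ])
    return CountMatrix(values, ["c1", "c2", "c3"], ["gA", "gB", "gC", "gD"],
                       modality="scRNA", stage="W2.5", layer="raw")


def brute_force_cosine_knn(query_df: pd.DataFrame, ref_df: pd.DataFrame, k: int):
    """Independent all-pairs cosine ranking: per query cell, compute
    s = q.r/(|q||r|) with explicit loops over reference cells and sort by
    (-s, reference id)."""
    ref_rows = [(str(rid), ref_df.loc[rid].to_numpy(dtype=float))
                for rid in ref_df.index]
    out = {}
    for qid in query_df.index:
        qv = query_df.loc[qid].to_numpy(dtype=float)
        qn = np.sqrt((qv ** 2).sum())
        if qn == 0:
            continue
        sims = []
        for rid, rv in ref_rows:
            rn = np.sqrt((rv ** 2).sum())
            if rn == 0:
                continue
            sims.append((rid, float(qv @ rv / (qn * rn))))
        sims.sort(key=lambda t: (-t[1], t[0]))
        out[str(qid)] = sims[:k]
    return out


def textbook_pearson(x, y):
    """Pearson r via the sum formula, independent of numpy.corrcoef."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x ** 2).sum() - sx ** 2) * np.sqrt(
        n * (y ** 2).sum() - sy ** 2)
    return num / den


def ranksum_pvalue(x, y):
    """Two-sided Wilcoxon rank-sum p-value from the textbook normal
    approximation with tie and continuity correction."""
    from scipy import stats

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u = max(u1, n1 * n2 - u1)
    n = n1 + n2
    _, t = np.unique(combined, return_counts=True)
    tie_term = (t ** 3 - t).sum()
    sigma = np.sqrt(n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1))))
    if sigma == 0:
        return 1.0
    z = (u - n1 * n2 / 2 - 0.5) / sigma
    return min(1.0, 2 * stats.norm.sf(z))


def tukey_pvalues(groups):
    """Tukey-Kramer pairwise p-values via the studentized-range
    distribution, computed from the one-way ANOVA mean square error."""
    from scipy.stats import studentized_range

    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    df = n_total - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(mse / 2 * (1 / len(groups[i]) + 1 / len(groups[j])))
            q = abs(groups[i].mean() - groups[j].mean()) / se
            out[(i, j)] = float(studentized_range.sf(q, k, df))
    return out
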