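"""Pairwise-tissue differential expression of small-RNA counts.

Each sequence is tested between library pairs with the pooled
two-proportion Z-test of Kal et al. (1999) on raw counts against library
totals; p-values are Benjamini-Hochberg corrected per pair.  Sequences
with q < 0.05 in at least one pair are "significant"; non-significant
sequences expressed at >= 5 RPM with a >= 2-fold RPM change in some pair
are "likely" differentially expressed; everything else is "ns".
Significant sequences are row-standardised (Z-scores, sample sd) and
clustered into expression groups (complete-linkage, Euclidean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm

log = logging.getLogger(__name__)

PSEUDO_RPM = 0.1  # fold-change denominator floor when one side is zero


def kal_test(count_a: int, total_a: int, count_b: int, total_b: int) -> tuple[float, float]:
    """Pooled two-proportion Z-test for one tag between two libraries.

    Returns (z, two-sided p).  When the pooled proportion is degenerate
    (both counts zero, or both equal to their totals) the test is undefined
    and p = 1 by convention.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if count_a > total_a or count_b > total_b or min(count_a, count_b) < 0:
        raise ValueError("counts must satisfy 0 <= count <= total")
    p_a = count_a / total_a
    p_b = count_b / total_b
    p0 = (count_a + count_b) / (total_a + total_b)
    if p0 <= 0.0 or p0 >= 1.0:
        return 0.0, 1.0
    se = np.sqrt(p0 * (1.0 - p0) * (1.0 / total_a + 1.0 / total_b))
    z = (p_a - p_b) / se
    return float(z), float(2.0 * norm.sf(abs(z)))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (stable under input order)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DEThresholds:
    fdr_cut: float = 0.05
    min_rpm: float = 5.0
    min_fold: float = 2.0


def run_pairwise_tests(
    counts: pd.DataFrame,
    library_totals: Mapping[str, int],
    pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Kal's test + BH-FDR for every sequence and library pair.

    ``counts``: sequences x libraries raw counts.  Returns a long table
    with columns (sequence, lib_a, lib_b, z, p, q, rpm_a, rpm_b,
    fold_change, max_rpm).
    """
    libs = list(counts.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(libs) for b in libs[i + 1:]]
    rows = []
    for a, b in pairs:
        ta, tb = library_totals[a], library_totals[b]
        for seq, row in counts.iterrows():
            z, p = kal_test(int(row[a]), ta, int(row[b]), tb)
            rpm_a = row[a] * 1e6 / ta
            rpm_b = row[b] * 1e6 / tb
            lo = min(rpm_a, rpm_b)
            fold = max(rpm_a, rpm_b) / (lo if lo > 0 else PSEUDO_RPM)
            rows.append((seq, a, b, z, p, rpm_a, rpm_b, fold, max(rpm_a, rpm_b)))
    df = pd.DataFrame(
        rows,
        columns=["sequence", "lib_a", "lib_b", "z", "p", "rpm_a", "rpm_b",
                 "fold_change", "max_rpm"],
    )
    df["q"] = np.nan
    for (a, b), idx in df.groupby(["lib_a", "lib_b"]).groups.items():
        df.loc[idx, "q"] = bh_fdr(df.loc[idx, "p"].to_numpy())
    return df


def categorize(
    results: pd.DataFrame, thresholds: DEThresholds | None = None
) -> pd.Series:
    """Per-sequence category over all pairs: significant / likely / ns."""
    t = thresholds or DEThresholds()
    cats = {}
    for seq, grp in results.groupby("sequence"):
        if (grp["q"] < t.fdr_cut).any():
            cats[seq] = "significant"
        elif ((grp["max_rpm"] >= t.min_rpm) & (grp["fold_change"] >= t.min_fold)).any():
            cats[seq] = "likely"
        else:
            cats[seq] = "ns"
    return pd.Series(cats, name="category").sort_index()


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-scores with sample (n-1) sd; constant rows become 0."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    z = matrix.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return z.fillna(0.0)


def zscore_and_cluster(matrix: pd.DataFrame, k_groups: int = 5) -> pd.DataFrame:
    """Standardise rows and cut a complete-linkage tree into k groups.

    Returns the Z-scored matrix with a ``cluster_group`` column.  Fewer
    than two rows cannot be clustered: all rows get group 1.
    """
    z = zscore_rows(matrix)
    if len(z) < 2:
        groups = np.ones(len(z), dtype=int)
    else:
        lk = linkage(z.to_numpy(), method="complete", metric="euclidean")
        groups = fcluster(lk, t=min(k_groups, len(z)), criterion="maxclust")
    out = z.copy()
    out["cluster_group"] = groups
    return out


def differential_expression(
    counts: pd.DataFrame,
    library_totals: Mapping[str, int],
    pairs: Sequence[tuple[str, str]] | None = None,
    thresholds: DEThresholds | None = None,
    k_groups: int = 5,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Full DE stage: tests, categories, clustering of significant rows."""
    results = run_pairwise_tests(counts, library_totals, pairs)
    cats = categorize(results, thresholds)
    sig = cats[cats == "significant"].index
    rpm = counts.mul(
        {l: 1e6 / t for l, t in library_totals.items()}, axis=1
    )
    clustered = zscore_and_cluster(rpm.loc[sig], k_groups=k_groups)
    return results, cats, clustered


def plot_heatmap(clustered: pd.DataFrame, path) -> None:
    """Optional rendering of the clustered Z-score matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = clustered.drop(columns="cluster_group")
    order = clustered["cluster_group"].argsort(kind="stable")
    fig, ax = plt.subplots(figsize=(6, max(2, 0.05 * len(mat))))
    ax.imshow(mat.iloc[order].to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(mat.shape[1]), mat.columns)
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
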