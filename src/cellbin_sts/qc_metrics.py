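"""Quality-control metrics: per-cellbin medians, UMI recall, gene recall.

The gene recall/unrecall classification tests, per gene, whether the
fraction of its UMIs inside cellbins deviates from the dataset-wide recall
rate: an exact two-sided binomial test against the global rate, with
Benjamini-Hochberg correction across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .cellbin_segmentation import CellbinSet
from .spatial_core import SpotTable

__all__ = [
    "QCSummary",
    "umi_recall_rate",
    "lower_median",
    "summarize_cellbins",
    "classify_gene_recall",
    "gene_recall_table",
]


@dataclass(frozen=True)
class QCSummary:
    n_cellbins: int
    median_area_bins: float
    median_umi: float
    median_genes: float
    median_mito_fraction: float
    umi_recall_rate: float | None = None
    saturation: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def umi_recall_rate(assigned_umi: int, total_umi: int) -> float:
    """Fraction of all UMIs that fall inside segmented cellbins."""
    if total_umi <= 0:
        raise ValueError("total_umi must be positive")
    if not 0 <= assigned_umi <= total_umi:
        raise ValueError(f"need 0 <= assigned <= total, got ({assigned_umi}, {total_umi})")
    return assigned_umi / total_umi


def lower_median(values: np.ndarray) -> float:
    """Median using the lower of the two middle order statistics for even n."""
    v = np.sort(np.asarray(values))
    if v.size == 0:
        raise ValueError("median of empty sequence")
    return float(v[(v.size - 1) // 2])


def summarize_cellbins(
    cellbins: CellbinSet,
    umi_recall: float | None = None,
    saturation: float | None = None,
) -> QCSummary:
    """Medians of area / UMI / gene count / mito fraction over retained cellbins."""
    t = cellbins.table
    if len(t) == 0:
        raise ValueError("cannot summarize an empty CellbinSet")
    return QCSummary(
        n_cellbins=len(t),
        median_area_bins=lower_median(t["area_bins"].to_numpy()),
        median_umi=lower_median(t["total_umi"].to_numpy()),
        median_genes=lower_median(t["n_genes"].to_numpy()),
        median_mito_fraction=lower_median(t["mito_fraction"].to_numpy()),
        umi_recall_rate=umi_recall,
        saturation=saturation,
    )


def classify_gene_recall(
    records: pd.DataFrame, global_rate: float, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify genes as significantly recalled / unrecalled / neither.

    ``records`` needs columns ``gene, umi_in, umi_total``.  Per gene, an
    exact two-sided binomial test of ``umi_in ~ Binomial(umi_total,
    global_rate)``; p-values are BH-adjusted across genes.  ``recalled``
    requires ``p_adj < alpha`` and an in-cellbin proportion above the global
    rate; ``unrecalled`` the same below it.  Genes with ``umi_total == 0``
    are ``neither`` with ``p_adj = 1``.
    """
    if not 0 < global_rate < 1:
        raise ValueError("global_rate must lie strictly inside (0, 1)")
    out = records[["gene", "umi_in", "umi_total"]].copy()
    if (out["umi_in"] > out["umi_total"]).any():
        raise ValueError("umi_in cannot exceed umi_total")

    pvals = np.ones(len(out))
    testable = out["umi_total"].to_numpy() > 0
    for i in np.flatnonzero(testable):
        k = int(out["umi_in"].iloc[i])
        n = int(out["umi_total"].iloc[i])
        pvals[i] = binomtest(k, n, global_rate, alternative="two-sided").pvalue

    p_adj = np.ones(len(out))
    if testable.any():
        p_adj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    out["p_value"] = pvals
    out["p_adj"] = p_adj

    with np.errstate(invalid="ignore"):
        prop = np.where(out["umi_total"] > 0, out["umi_in"] / out["umi_total"].clip(lower=1), np.nan)
    significant = testable & (p_adj < alpha)
    cls = np.full(len(out), "neither", dtype=object)
    cls[significant & (prop > global_rate)] = "recalled"
    cls[significant & (prop < global_rate)] = "unrecalled"
    out["recall_class"] = cls
    return out


def gene_recall_table(spots: SpotTable, labels: np.ndarray) -> pd.DataFrame:
    """Per-gene (umi_in, umi_total) given a cellbin label map."""
    df = spots.data
    inside = labels[df["y_bin"].to_numpy(), df["x_bin"].to_numpy()] > 0
    totals = df.groupby("gene", sort=True)["umi_count"].sum()
    inside_counts = df.loc[inside].groupby("gene", sort=True)["umi_count"].sum()
    out = pd.DataFrame(
        {
            "gene": totals.index,
            "umi_in": inside_counts.reindex(totals.index, fill_value=0).to_numpy(),
            "umi_total": totals.to_numpy(),
        }
    ).reset_index(drop=True)
    return out
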