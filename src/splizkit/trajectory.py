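"""Pseudotime-correlated splicing screen and quantile-binned summaries.

For each gene with a computable SpliZ in at least 100 cells carrying a
pseudotime value, Spearman's correlation between SpliZ and pseudotime is
computed (average-rank ties, t-approximation p-value) and Bonferroni-corrected
over the tested genes; a gene is developmentally regulated when
|rho| > 0.1 and the corrected p is below 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MIN_CELLS_TRAJECTORY = 100
RHO_THRESHOLD = 0.1

__all__ = ["trajectory_screen", "quantile_bin_summary"]


def trajectory_screen(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    min_cells: int = MIN_CELLS_TRAJECTORY,
    rho_threshold: float = RHO_THRESHOLD,
    alpha: float = 0.05,
    value_col: str = "spliz",
) -> pd.DataFrame:
    """Per-gene Spearman screen of splicing against pseudotime.

    Returns columns ``gene, n_cells, rho, p, p_bonferroni, significant``; genes
    below the cell gate are not tested, and genes with constant score or
    constant pseudotime are skipped with a log message.
    """
    if "pseudotime" not in annotations.columns:
        raise ValueError("annotations lack a pseudotime column")
    merged = scores.loc[scores["computable"], ["cell_id", "gene", value_col]].merge(
        annotations[["cell_id", "pseudotime"]].dropna(subset=["pseudotime"]), on="cell_id"
    )
    rows = []
    for gene, block in merged.groupby("gene", sort=True):
        if len(block) < min_cells:
            continue
        vals = block[value_col].to_numpy()
        pt = block["pseudotime"].to_numpy()
        if np.ptp(vals) == 0 or np.ptp(pt) == 0:
            logger.info("gene %s skipped: constant score or pseudotime", gene)
            continue
        rho, p = stats.spearmanr(vals, pt)
        rows.append({"gene": gene, "n_cells": len(block), "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows, columns=["gene", "n_cells", "rho", "p"])
    if out.empty:
        out["p_bonferroni"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    out["significant"] = (out["rho"].abs() > rho_threshold) & (out["p_bonferroni"] < alpha)
    return out


def quantile_bin_summary(
    cell_values: pd.DataFrame,
    annotations: pd.DataFrame,
    n_bins: int,
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Mean of each value column within equal-count pseudotime bins.

    ``cell_values`` carries one row per cell (column ``cell_id`` plus numeric
    columns, e.g. SpliZ and weighted-average rank).  Cells are split into
    ``n_bins`` equal-count bins by pseudotime order; requires n_bins >= 2 and
    at least one cell per bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    merged = cell_values.merge(
        annotations[["cell_id", "pseudotime"]].dropna(subset=["pseudotime"]), on="cell_id"
    )
    if len(merged) < n_bins:
        raise ValueError(f"fewer cells ({len(merged)}) than bins ({n_bins})")
    if value_cols is None:
        value_cols = [c for c in merged.columns if c not in ("cell_id", "pseudotime") and merged[c].dtype.kind in "fi"]
    order_rank = merged["pseudotime"].rank(method="first")
    merged["bin"] = pd.qcut(order_rank, n_bins, labels=False)
    agg = merged.groupby("bin").agg(
        n_cells=("cell_id", "count"),
        pseudotime_mean=("pseudotime", "mean"),
        **{f"{c}_mean": (c, "mean") for c in value_cols},
    )
    return agg.reset_index()
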