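"""The SpliZ statistic: distance ranks, population residuals, per-cell-gene scores.

A splice site that appears in junctions with two or more distinct partner
sites is an *anchor*.  Its partners are ranked by unsigned genomic distance
(rank 1 = nearest, i.e. the shortest intron).  Each observed rank is converted
to a mean-zero, unit-variance residual against the whole-dataset rank
distribution at that anchor; a cell-gene SpliZ is the sum of the residuals of
its reads divided by the square root of the number of residuals.  Under
within-group homogeneity the score is approximately standard normal: negative
values mean the cell favours nearer-than-average partners (shorter introns),
positive values farther-than-average ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_READS_DEFAULT = 5

__all__ = [
    "RankModel",
    "build_rank_models",
    "read_residual",
    "compute_spliz",
    "weighted_average_rank",
    "MIN_READS_DEFAULT",
]


@dataclass
class RankModel:
    """Distance-rank distribution of one anchor splice site over the whole dataset."""

    gene: str
    chrom: str
    strand: str
    position: int
    role: str  # the anchor's own role in its junctions: 'donor' or 'acceptor'
    partner_ranks: dict[int, int]  # partner position -> rank (1 = nearest)
    mean: float  # read-weighted population mean rank
    sd: float  # read-weighted population standard deviation (>0)
    n_reads: int

    @property
    def n_partners(self) -> int:
        return len(self.partner_ranks)

    def residual(self, partner_pos: int) -> float:
        return (self.partner_ranks[int(partner_pos)] - self.mean) / self.sd


def read_residual(rank: float, model: RankModel) -> float:
    """Mean-zero, variance-one residual of an observed rank at an anchor."""
    return (rank - model.mean) / model.sd


def _anchor_long_view(counts: pd.DataFrame) -> pd.DataFrame:
    """Each junction record twice: once donor-anchored, once acceptor-anchored."""
    donor = counts.rename(columns={"donor_pos": "anchor_pos", "acceptor_pos": "partner_pos"}).assign(role="donor")
    acceptor = counts.rename(columns={"acceptor_pos": "anchor_pos", "donor_pos": "partner_pos"}).assign(
        role="acceptor"
    )
    cols = ["cell_id", "gene", "chrom", "strand", "role", "anchor_pos", "partner_pos", "count"]
    return pd.concat([donor[cols], acceptor[cols]], ignore_index=True)


def _rank_partners(anchor_pos: int, partners: np.ndarray) -> dict[int, int]:
    # Two distinct partners on the same side of an anchor cannot be equidistant;
    # equidistant opposite-side partners break ties by ascending coordinate.
    dist = np.abs(partners - anchor_pos)
    order = np.lexsort((partners, dist))
    if len(np.unique(dist)) < len(partners):
        logger.info("equidistant partners at anchor %d broken by ascending coordinate", anchor_pos)
    return {int(partners[i]): r + 1 for r, i in enumerate(order)}


def build_rank_models(counts: pd.DataFrame) -> dict[tuple[str, int, str], RankModel]:
    """Build one rank model per anchor with >=2 observed partners.

    Both directions anchor: every donor over its acceptors and every acceptor
    over its donors.  Population mean and standard deviation of the rank are
    computed over all reads in the dataset, each read weighted equally
    (population, not sample, standard deviation — residuals then have exactly
    zero mean and unit variance over the anchor's reads).  Anchors with a
    single partner or zero rank variance are excluded with a logged count.
    """
    if counts.empty:
        raise ValueError("cannot build rank models from an empty junction table")
    long = _anchor_long_view(counts)
    models: dict[tuple[str, int, str], RankModel] = {}
    n_excluded = 0
    grouped = long.groupby(["gene", "role", "anchor_pos"], sort=True)
    for (gene, role, anchor_pos), block in grouped:
        per_partner = block.groupby("partner_pos", sort=True)["count"].sum()
        partners = per_partner.index.to_numpy(dtype=np.int64)
        if len(partners) < 2:
            n_excluded += 1
            continue
        ranks_map = _rank_partners(int(anchor_pos), partners)
        ranks = np.array([ranks_map[int(p)] for p in partners], dtype=float)
        weights = per_partner.to_numpy(dtype=float)
        total = weights.sum()
        mean = float(np.sum(ranks * weights) / total)
        var = float(np.sum(weights * (ranks - mean) ** 2) / total)
        if var <= 0.0:
            n_excluded += 1
            continue
        models[(gene, int(anchor_pos), role)] = RankModel(
            gene=gene,
            chrom=str(block["chrom"].iloc[0]),
            strand=str(block["strand"].iloc[0]),
            position=int(anchor_pos),
            role=role,
            partner_ranks=ranks_map,
            mean=mean,
            sd=math.sqrt(var),
            n_reads=int(total),
        )
    if n_excluded:
        logger.info("excluded %d anchors with <2 partners or zero rank variance", n_excluded)
    return models


def _residual_lookup(models: dict[tuple[str, int, str], RankModel]) -> pd.DataFrame:
    """Long table (gene, role, anchor_pos, partner_pos) -> rank, residual."""
    rows = []
    for (gene, anchor_pos, role), model in models.items():
        for partner_pos, rank in model.partner_ranks.items():
            rows.append(
                (gene, role, anchor_pos, partner_pos, rank, (rank - model.mean) / model.sd)
            )
    return pd.DataFrame(rows, columns=["gene", "role", "anchor_pos", "partner_pos", "rank", "residual"])


def residual_incidences(counts: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Per (cell, gene, anchor) read incidences carrying residuals.

    A read contributes at its donor anchor and at its acceptor anchor whenever
    each has a model, so a single junction record can yield residuals at both
    of its ends.
    """
    lookup = _residual_lookup(models)
    long = _anchor_long_view(counts)
    return long.merge(lookup, on=["gene", "role", "anchor_pos", "partner_pos"], how="inner")


def compute_spliz(
    counts: pd.DataFrame,
    models: dict[tuple[str, int, str], RankModel],
    min_reads: int = MIN_READS_DEFAULT,
) -> pd.DataFrame:
    """Per cell-gene SpliZ scores.

    Returns a frame with columns ``cell_id, gene, n_reads, n_residuals,
    spliz, computable``.  ``n_reads`` counts all spliced reads of the gene in
    the cell; a pair is computable when ``n_reads >= min_reads``.  The score is
    (sum of residuals) / sqrt(number of residuals) and is reported only for
    computable pairs.  Genes with no modeled anchors receive no rows (logged).
    """
    incid = residual_incidences(counts, models)
    if incid.empty:
        logger.info("no junction records matched any rank model")
        return pd.DataFrame(columns=["cell_id", "gene", "n_reads", "n_residuals", "spliz", "computable"])
    incid = incid.assign(wres=incid["residual"] * incid["count"])
    agg = incid.groupby(["cell_id", "gene"], sort=True).agg(
        res_sum=("wres", "sum"), n_residuals=("count", "sum")
    )
    reads = counts.groupby(["cell_id", "gene"], sort=True)["count"].sum().rename("n_reads")
    out = agg.join(reads, how="left").reset_index()
    dropped_genes = set(counts["gene"].unique()) - set(out["gene"].unique())
    if dropped_genes:
        logger.info("%d genes have no modeled anchors and receive no scores", len(dropped_genes))
    out["computable"] = out["n_reads"] >= int(min_reads)
    out["spliz"] = np.where(
        out["computable"], out["res_sum"] / np.sqrt(out["n_residuals"].to_numpy(dtype=float)), np.nan
    )
    out["n_reads"] = out["n_reads"].astype(np.int64)
    out["n_residuals"] = out["n_residuals"].astype(np.int64)
    return out[["cell_id", "gene", "n_reads", "n_residuals", "spliz", "computable"]]


def weighted_average_rank(counts: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Per (cell, anchor) read-weighted mean partner rank — the dot-plot summary.

    Columns: ``cell_id, gene, role, anchor_pos, n_reads, avg_rank`` with
    ``avg_rank`` in [1, K]; cells without reads at an anchor get no entry.
    """
    lookup = _residual_lookup(models)
    long = _anchor_long_view(counts)
    merged = long.merge(lookup, on=["gene", "role", "anchor_pos", "partner_pos"], how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["cell_id", "gene", "role", "anchor_pos", "n_reads", "avg_rank"])
    merged = merged.assign(wrank=merged["rank"] * merged["count"])
    agg = merged.groupby(["cell_id", "gene", "role", "anchor_pos"], sort=True).agg(
        n_reads=("count", "sum"), wrank=("wrank", "sum")
    )
    agg["avg_rank"] = agg["wrank"] / agg["n_reads"]
    return agg.drop(columns="wrank").reset_index()
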