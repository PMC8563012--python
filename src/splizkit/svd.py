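"""SpliZVD scores and SpliZsites from the first singular vector of the residual matrix.

For one gene, the residual matrix has one row per cell with a computable
SpliZ and one column per modeled anchor; the entry is the cell's mean read
residual at that anchor (0 when the cell has no reads there).  Columns are
mean-centered before decomposition.  The per-cell SpliZVD is the projection
of the cell's row onto the first right singular vector (sign fixed so the
largest-magnitude loading is positive); the SpliZsites of the gene are the
up-to-three anchors with the largest-magnitude loadings — the sites carrying
most of the cell-to-cell splicing variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MIN_READS_DEFAULT, RankModel, compute_spliz, residual_incidences
from .io import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "ResidualMatrix",
    "SplizVDResult",
    "SiteAnnotationStatus",
    "build_residual_matrix",
    "compute_splizvd",
    "compute_splizvd_scores",
    "call_splizsites",
    "call_splizsites_all_genes",
    "classify_site",
]


@dataclass
class ResidualMatrix:
    gene: str
    matrix: np.ndarray  # cells x anchors, column-centered
    cells: list[str]
    anchors: list[tuple[int, str]]  # (position, role), ascending coordinate
    column_means: np.ndarray


@dataclass
class SplizVDResult:
    gene: str
    scores: pd.Series  # SpliZVD per cell
    vector: np.ndarray  # first right singular vector, sign-fixed
    singular_value: float
    anchors: list[tuple[int, str]]


@dataclass
class SiteAnnotationStatus:
    position: int
    at_annotated_exon_boundary: bool
    annotated_alternative: bool
    region: str  # CDS, 5'UTR, 3'UTR, non-coding, intergenic


def build_residual_matrix(
    counts: pd.DataFrame,
    models: dict[tuple[str, int, str], RankModel],
    gene: str,
    min_reads: int = MIN_READS_DEFAULT,
    scores: pd.DataFrame | None = None,
) -> ResidualMatrix:
    """Cells-with-computable-SpliZ x modeled-anchors matrix of mean read residuals."""
    anchors = sorted([(pos, role) for (g, pos, role) in models if g == gene])
    if not anchors:
        raise ValueError(f"gene {gene}: no modeled anchors")
    if scores is None:
        scores = compute_spliz(counts, models, min_reads=min_reads)
    cells = sorted(scores.loc[(scores["gene"] == gene) & scores["computable"], "cell_id"])
    if len(cells) < 2:
        raise ValueError(f"gene {gene}: fewer than 2 cells with computable SpliZ")
    incid = residual_incidences(counts[counts["gene"] == gene], models)
    incid = incid[incid["cell_id"].isin(cells)]
    incid = incid.assign(wres=incid["residual"] * incid["count"])
    agg = incid.groupby(["cell_id", "anchor_pos", "role"], sort=True).agg(
        wres=("wres", "sum"), n=("count", "sum")
    )
    agg["mean_res"] = agg["wres"] / agg["n"]
    cell_index = {c: i for i, c in enumerate(cells)}
    anchor_index = {a: j for j, a in enumerate(anchors)}
    mat = np.zeros((len(cells), len(anchors)))
    for (cell_id, pos, role), row in agg.iterrows():
        mat[cell_index[cell_id], anchor_index[(int(pos), role)]] = row["mean_res"]
    col_means = mat.mean(axis=0)
    return ResidualMatrix(
        gene=gene, matrix=mat - col_means, cells=list(cells), anchors=anchors, column_means=col_means
    )


def _sign_fix(v: np.ndarray) -> np.ndarray:
    idx = int(np.argmax(np.abs(v)))
    return -v if v[idx] < 0 else v


def compute_splizvd(rm: ResidualMatrix) -> SplizVDResult:
    """Project each cell's residual row onto the first right singular vector."""
    if not np.any(rm.matrix):
        raise ValueError(f"gene {rm.gene}: residual matrix is all zeros")
    _, s, vt = np.linalg.svd(rm.matrix, full_matrices=False)
    v = _sign_fix(vt[0])
    scores = pd.Series(rm.matrix @ v, index=pd.Index(rm.cells, name="cell_id"), name="splizvd")
    return SplizVDResult(
        gene=rm.gene, scores=scores, vector=v, singular_value=float(s[0]), anchors=rm.anchors
    )


def compute_splizvd_scores(
    counts: pd.DataFrame,
    models: dict[tuple[str, int, str], RankModel],
    min_reads: int = MIN_READS_DEFAULT,
) -> pd.DataFrame:
    """SpliZVD for every gene with >=2 computable cells, in the same table shape
    as :func:`splizkit.core.compute_spliz` (value column ``splizvd``)."""
    scores = compute_spliz(counts, models, min_reads=min_reads)
    frames = []
    for gene in sorted({g for (g, _, _) in models}):
        try:
            rm = build_residual_matrix(counts, models, gene, min_reads=min_reads, scores=scores)
            res = compute_splizvd(rm)
        except ValueError as exc:
            logger.info("skipping gene %s: %s", gene, exc)
            continue
        df = res.scores.reset_index()
        df["gene"] = gene
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["cell_id", "gene", "n_reads", "splizvd", "computable"])
    vd = pd.concat(frames, ignore_index=True)
    out = vd.merge(scores[["cell_id", "gene", "n_reads", "computable"]], on=["cell_id", "gene"], how="left")
    return out[["cell_id", "gene", "n_reads", "splizvd", "computable"]]


def call_splizsites(result: SplizVDResult, n_sites: int = 3) -> list[tuple[int, str, float]]:
    """Up to ``n_sites`` anchors with the largest |loading| on the first singular
    vector, ordered by descending |loading|; ties break by ascending coordinate."""
    loads = [
        (pos, role, float(result.vector[j])) for j, (pos, role) in enumerate(result.anchors)
    ]
    loads.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return loads[:n_sites]


def call_splizsites_all_genes(
    counts: pd.DataFrame,
    models: dict[tuple[str, int, str], RankModel],
    min_reads: int = MIN_READS_DEFAULT,
    n_sites: int = 3,
) -> pd.DataFrame:
    """SpliZsite table (gene, chrom, pos, role, loading, rank) over all decomposable genes."""
    scores = compute_spliz(counts, models, min_reads=min_reads)
    rows = []
    for gene in sorted({g for (g, _, _) in models}):
        try:
            rm = build_residual_matrix(counts, models, gene, min_reads=min_reads, scores=scores)
            res = compute_splizvd(rm)
        except ValueError as exc:
            logger.info("skipping gene %s: %s", gene, exc)
            continue
        chrom = next(m.chrom for (g, _, _), m in models.items() if g == gene)
        for rank, (pos, role, loading) in enumerate(call_splizsites(res, n_sites=n_sites), start=1):
            rows.append(
                {"gene": gene, "chrom": chrom, "pos": pos, "role": role, "loading": loading, "rank": rank}
            )
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "role", "loading", "rank"])


# ---------------------------------------------------------------------------
# Annotation status of a splice site against gene models
# ---------------------------------------------------------------------------


def _junction_partners(model: GeneModel, pos: int) -> set[int]:
    """Distinct annotated partner boundaries the site pairs with across transcripts."""
    partners: set[int] = set()
    for exons in model.transcripts.values():
        for i, (start, end) in enumerate(exons):
            if pos == end and i + 1 < len(exons):
                partners.add(exons[i + 1][0])
            if pos == start and i > 0:
                partners.add(exons[i - 1][1])
    return partners


def _region(model: GeneModel, pos: int) -> str:
    in_cds = any(s <= pos <= e for ivs in model.cds.values() for (s, e) in ivs)
    if in_cds:
        return "CDS"
    utr5 = utr3 = in_exon = in_span = False
    for tid, exons in model.transcripts.items():
        if not exons:
            continue
        span = (exons[0][0], exons[-1][1])
        if span[0] <= pos <= span[1]:
            in_span = True
        exonic = any(s <= pos <= e for (s, e) in exons)
        if not exonic:
            continue
        in_exon = True
        cds = model.cds.get(tid)
        if not cds:
            continue
        cds_start, cds_end = cds[0][0], cds[-1][1]
        if pos < cds_start:
            utr5 |= model.strand == "+"
            utr3 |= model.strand == "-"
        elif pos > cds_end:
            utr3 |= model.strand == "+"
            utr5 |= model.strand == "-"
    if utr5:
        return "5'UTR"
    if utr3:
        return "3'UTR"
    if in_exon or in_span:
        return "non-coding"
    return "intergenic"


def classify_site(position: int, model: GeneModel | None) -> SiteAnnotationStatus:
    """Annotation status of one splice-site coordinate against a gene's model.

    A site is at an annotated exon boundary when it exactly equals an exon
    start or end (1-based).  It counts as annotated alternatively spliced when
    that boundary is present in a proper nonempty subset of the gene's
    transcripts, or pairs with more than one annotated partner boundary.
    Region precedence: CDS > UTRs > non-coding; absent gene -> intergenic.
    """
    if model is None:
        logger.info("site %d: gene absent from models", position)
        return SiteAnnotationStatus(position, False, False, "intergenic")
    with_boundary = model.transcripts_with_boundary(position)
    at_boundary = bool(with_boundary)
    proper_subset = 0 < len(with_boundary) < len(model.transcripts)
    multi_partner = len(_junction_partners(model, position)) > 1
    alternative = at_boundary and (proper_subset or multi_partner)
    return SiteAnnotationStatus(
        position=position,
        at_annotated_exon_boundary=at_boundary,
        annotated_alternative=alternative,
        region=_region(model, position),
    )
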