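"""Readers and writers for the pipeline's interchange tables.

The canonical junction-count interchange format is a 7-column TSV with header
``cell_id  gene  chrom  strand  donor_pos  acceptor_pos  count`` holding
UMI-deduplicated spliced-read counts per (cell, junction).  All genomic
coordinates are 1-based throughout the package and are never reinterpreted.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

JUNCTION_COLUMNS = ["cell_id", "gene", "chrom", "strand", "donor_pos", "acceptor_pos", "count"]
ANNOTATION_COLUMNS = ["cell_id", "individual", "tissue", "compartment", "cell_type"]
COMPARTMENTS = frozenset({"immune", "epithelial", "endothelial", "stromal", "other"})
COORD_MAP_COLUMNS = ["chrom_src", "pos_src", "chrom_dst", "pos_dst"]

__all__ = [
    "JUNCTION_COLUMNS",
    "ANNOTATION_COLUMNS",
    "COMPARTMENTS",
    "GeneModel",
    "CoordinateMap",
    "read_junction_table",
    "write_junction_table",
    "validate_junction_table",
    "read_cell_annotations",
    "write_cell_annotations",
    "read_gene_models",
    "read_coordinate_map",
    "write_coordinate_map",
    "read_scores",
    "write_scores",
    "load_yaml_config",
]


class TableFormatError(ValueError):
    """Raised when an input table violates the declared schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _to_int(df: pd.DataFrame, col: str, path) -> pd.Series:
    """Convert a string column to integers, reporting the first offending line.

    Data rows start at line 2 (line 1 is the header)."""
    converted = pd.to_numeric(df[col], errors="coerce")
    bad = converted.isna() | (converted != converted.round())
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TableFormatError(f"{path}: line {line}: column '{col}' is not an integer: {df[col].iloc[line - 2]!r}")
    return converted.astype(np.int64)


def validate_junction_table(df: pd.DataFrame, path: str = "<table>") -> pd.DataFrame:
    """Validate a junction-count frame against the schema invariants.

    Returns a typed copy. Raises :class:`TableFormatError` naming the first
    offending data line (header = line 1)."""
    _require_columns(df, JUNCTION_COLUMNS, path)
    out = df[JUNCTION_COLUMNS].copy()
    for col in ("donor_pos", "acceptor_pos", "count"):
        out[col] = _to_int(out.astype({col: str}) if out[col].dtype == object else out, col, path)

    def _first_bad_line(mask: pd.Series) -> int:
        return int(np.flatnonzero(mask.to_numpy())[0]) + 2

    bad_strand = ~out["strand"].isin(["+", "-"])
    if bad_strand.any():
        line = _first_bad_line(bad_strand)
        raise TableFormatError(f"{path}: line {line}: unknown strand symbol {out['strand'].iloc[line - 2]!r}")
    if (out["count"] <= 0).any():
        line = _first_bad_line(out["count"] <= 0)
        raise TableFormatError(f"{path}: line {line}: count must be a positive integer")
    for col in ("donor_pos", "acceptor_pos"):
        if (out[col] < 1).any():
            line = _first_bad_line(out[col] < 1)
            raise TableFormatError(f"{path}: line {line}: {col} must be >= 1 (coordinates are 1-based)")
    same = out["donor_pos"] == out["acceptor_pos"]
    if same.any():
        line = _first_bad_line(same)
        raise TableFormatError(f"{path}: line {line}: donor and acceptor positions coincide")
    key = ["cell_id", "gene", "chrom", "donor_pos", "acceptor_pos"]
    dup = out.duplicated(subset=key, keep="first")
    if dup.any():
        line = _first_bad_line(dup)
        raise TableFormatError(
            f"{path}: line {line}: duplicate (cell, junction) record; duplicates are an error, not summed"
        )
    return out.reset_index(drop=True)


def read_junction_table(path) -> pd.DataFrame:
    """Read and validate the canonical 7-column junction-count TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_junction_table(df, str(path))


def write_junction_table(df: pd.DataFrame, path) -> None:
    df = df[JUNCTION_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_cell_annotations(path, allow_unknown_compartment: bool = False) -> pd.DataFrame:
    """Read per-cell annotations (CSV or TSV; delimiter sniffed from the header).

    The ``pseudotime`` column is optional; when absent the returned frame has
    no such column (never an implicit zero).  Unknown compartment labels are an
    error unless ``allow_unknown_compartment`` is set, in which case they are
    coerced to ``"other"`` with a log message.
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if header.count("\t") >= header.count(",") else ","
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, ANNOTATION_COLUMNS, path)
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise TableFormatError(f"{path}: duplicate cell_id {dup!r}")
    unknown = ~df["compartment"].isin(sorted(COMPARTMENTS))
    if unknown.any():
        if not allow_unknown_compartment:
            bad = df.loc[unknown, "compartment"].iloc[0]
            raise TableFormatError(f"{path}: unknown compartment label {bad!r}")
        logger.info("coercing %d unknown compartment labels to 'other'", int(unknown.sum()))
        df.loc[unknown, "compartment"] = "other"
    cols = list(ANNOTATION_COLUMNS)
    if "pseudotime" in df.columns:
        df["pseudotime"] = pd.to_numeric(df["pseudotime"], errors="raise").astype(float)
        if (df["pseudotime"].dropna() < 0).any():
            raise TableFormatError(f"{path}: pseudotime must be >= 0")
        cols.append("pseudotime")
    return df[cols].reset_index(drop=True)


def write_cell_annotations(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene models (GTF)
# ---------------------------------------------------------------------------


@dataclass
class GeneModel:
    """Exon/CDS structure of one gene: per-transcript sorted 1-based closed intervals."""

    gene_id: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    cds: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def exon_boundaries(self) -> set[int]:
        out: set[int] = set()
        for exons in self.transcripts.values():
            for start, end in exons:
                out.add(start)
                out.add(end)
        return out

    def transcripts_with_boundary(self, pos: int) -> set[str]:
        return {
            tid
            for tid, exons in self.transcripts.items()
            if any(pos in (start, end) for start, end in exons)
        }


def _finalize_gene_model(model: GeneModel) -> GeneModel:
    for tid, exons in model.transcripts.items():
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 <= e1:
                raise TableFormatError(
                    f"gene {model.gene_id} transcript {tid}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
    for intervals in model.cds.values():
        intervals.sort()
    return model


def read_gene_models(path) -> dict[str, GeneModel]:
    """Parse exon (and CDS) features from a GTF into per-gene models.

    Uses an in-memory gffutils database. An exon without a transcript_id and a
    gene_id seen on both strands are errors; an empty file yields an empty
    collection with a logged warning.
    """
    import gffutils

    if os.path.getsize(path) == 0 or not open(path).read().strip():
        logger.warning("gene-model file %s is empty", path)
        return {}
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    models: dict[str, GeneModel] = {}
    for feature in db.all_features():
        if feature.featuretype not in ("exon", "CDS"):
            continue
        gene_ids = feature.attributes.get("gene_id", [])
        tx_ids = feature.attributes.get("transcript_id", [])
        if not gene_ids:
            raise TableFormatError(f"{path}: {feature.featuretype} at {feature.start} lacks gene_id")
        if not tx_ids:
            raise TableFormatError(f"{path}: {feature.featuretype} at {feature.start} lacks transcript_id")
        gene_id, tx_id = gene_ids[0], tx_ids[0]
        model = models.setdefault(gene_id, GeneModel(gene_id=gene_id, strand=feature.strand))
        if feature.strand != model.strand:
            raise TableFormatError(f"{path}: gene {gene_id} has features on both strands")
        target = model.transcripts if feature.featuretype == "exon" else model.cds
        target.setdefault(tx_id, []).append((int(feature.start), int(feature.end)))
    return {g: _finalize_gene_model(m) for g, m in models.items()}


# ---------------------------------------------------------------------------
# Cross-species coordinate maps (LiftOver output consumed as data)
# ---------------------------------------------------------------------------


@dataclass
class CoordinateMap:
    """An injective (both ways) mapping between genomic coordinates of two assemblies."""

    forward: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.forward)

    def get(self, chrom: str, pos: int) -> tuple[str, int] | None:
        return self.forward.get((chrom, int(pos)))

    def invert(self) -> "CoordinateMap":
        return CoordinateMap(forward={v: k for k, v in self.forward.items()})


def read_coordinate_map(path) -> CoordinateMap:
    """Read a 4-column TSV of coordinate pairs, keeping only uniquely mapped entries.

    Sources mapped to several destinations and destinations hit by several
    sources are both dropped (with a logged count), so the retained map is
    injective in both directions — only uniquely converted entries survive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom_src": str, "chrom_dst": str})
    if df.empty:
        return CoordinateMap()
    _require_columns(df, COORD_MAP_COLUMNS, path)
    df = df.drop_duplicates(subset=COORD_MAP_COLUMNS)
    src = list(zip(df["chrom_src"], df["pos_src"].astype(int)))
    dst = list(zip(df["chrom_dst"], df["pos_dst"].astype(int)))
    src_counts = pd.Series(src).value_counts()
    dst_counts = pd.Series(dst).value_counts()
    forward: dict[tuple[str, int], tuple[str, int]] = {}
    dropped = 0
    for s, d in zip(src, dst):
        if src_counts[s] > 1 or dst_counts[d] > 1:
            dropped += 1
            continue
        forward[s] = d
    if dropped:
        logger.info("dropped %d non-uniquely mapped coordinate pairs", dropped)
    return CoordinateMap(forward=forward)


def write_coordinate_map(cmap: CoordinateMap, path) -> None:
    rows = [
        {"chrom_src": s[0], "pos_src": s[1], "chrom_dst": d[0], "pos_dst": d[1]}
        for s, d in sorted(cmap.forward.items())
    ]
    pd.DataFrame(rows, columns=COORD_MAP_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Score tables and configuration
# ---------------------------------------------------------------------------


def write_scores(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "computable" in df.columns:
        df["computable"] = df["computable"].astype(bool)
    return df


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
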