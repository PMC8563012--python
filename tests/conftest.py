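import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_junctions() -> pd.DataFrame:
    """Three cells at one donor anchor with two acceptor partners."""
    rows = [
        ("cell1", "GENE1", "chr1", "+", 1000, 2000, 3),
        ("cell1", "GENE1", "chr1", "+", 1000, 5000, 2),
        ("cell2", "GENE1", "chr1", "+", 1000, 2000, 5),
        ("cell3", "GENE1", "chr1", "+", 1000, 5000, 6),
    ]
    return pd.DataFrame(
        rows, columns=["cell_id", "gene", "chrom", "strand", "donor_pos", "acceptor_pos", "count"]
    )


@pytest.fixture
def toy_annotations() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": ["cell1", "cell2", "cell3"],
            "individual": ["ind1"] * 3,
            "tissue": ["lung"] * 3,
            "compartment": ["immune", "immune", "epithelial"],
            "cell_type": ["macrophage", "macrophage", "basal"],
        }
    )


TOY_GTF = """\
chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t500\t600\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t150\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
chr1\ttest\texon\t300\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
chr1\ttest\texon\t500\t650\t.\t+\t.\tgene_id "G1"; transcript_id "T2";
"""


@pytest.fixture
def toy_gtf(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    return path


def two_partner_counts(n_rank1: int, n_rank2: int, cell: str = "c", gene: str = "G") -> list[tuple]:
    """Junction rows for one cell at a two-partner donor anchor (ranks by distance)."""
    rows = []
    if n_rank1:
        rows.append((cell, gene, "chr1", "+", 1000, 2000, n_rank1))
    if n_rank2:
        rows.append((cell, gene, "chr1", "+", 1000, 5000, n_rank2))
    return rows


def frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["cell_id", "gene", "chrom", "strand", "donor_pos", "acceptor_pos", "count"]
    )
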