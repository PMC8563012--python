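"""Cross-species SpliZsite sharing statistics and the three-species enrichment test.

Given SpliZsite tables for two species, a LiftOver-style coordinate map and a
gene-orthology table, the comparable set I is the species-A SpliZsites whose
genes have computable SpliZ in species B and whose coordinates map uniquely;
a site is shared when its mapped coordinate is a SpliZsite of the orthologous
gene.  The per-gene null probability of sharing is 1/N_i, where N_i counts
the distinct splice sites of the gene with junctional reads, giving the
expected fraction (1/I) sum 1/N_i; the observed count is referred to a
one-sided Binomial(I, expected) tail (an approximation, since the per-site
probabilities differ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CoordinateMap

__all__ = [
    "ConservationResult",
    "EnrichmentResult",
    "shared_site_fraction",
    "expected_null_fraction",
    "conservation_binomial_test",
    "three_species_enrichment",
]


@dataclass
class ConservationResult:
    n_comparable: int
    n_shared: int
    shared_fraction: float
    expected_fraction: float
    p_value: float


@dataclass
class EnrichmentResult:
    p_species: dict
    p_all: float
    n: int
    x: int
    p_value: float
    tail: str  # "P(X > x)" (as printed) or "P(X >= x)" (inclusive variant)


def shared_site_fraction(
    sites_a: pd.DataFrame,
    sites_b: pd.DataFrame,
    coord_map: CoordinateMap,
    computable_genes_b: set,
    orthologs: dict | None = None,
) -> tuple[int, int, float]:
    """(n_shared, I, fraction) of species-A SpliZsites conserved in species B.

    ``sites_a``/``sites_b`` need columns ``gene, chrom, pos``; ``orthologs``
    maps A gene symbols to B symbols (identity when omitted).  Sites whose
    gene lacks computable SpliZ in B or whose coordinate does not map
    uniquely are excluded from the comparison."""
    orthologs = orthologs or {}
    b_sites = {(g, c, int(p)) for g, c, p in zip(sites_b["gene"], sites_b["chrom"], sites_b["pos"])}
    n_comparable = 0
    n_shared = 0
    for g, c, p in zip(sites_a["gene"], sites_a["chrom"], sites_a["pos"]):
        gene_b = orthologs.get(g, g)
        if gene_b not in computable_genes_b:
            continue
        mapped = coord_map.get(str(c), int(p))
        if mapped is None:
            continue
        n_comparable += 1
        if (gene_b, mapped[0], mapped[1]) in b_sites:
            n_shared += 1
    if n_comparable == 0:
        raise ValueError("no comparable SpliZsites (I = 0)")
    return n_shared, n_comparable, n_shared / n_comparable


def expected_null_fraction(partner_site_counts) -> float:
    """(1/I) sum_i 1/N_i over the I compared sites (N_i distinct sites per gene)."""
    n = np.asarray(partner_site_counts, dtype=float)
    if n.size == 0:
        raise ValueError("no site counts supplied")
    if np.any(n < 1):
        raise ValueError("every N_i must be >= 1")
    return float(np.mean(1.0 / n))


def conservation_binomial_test(n_shared: int, n_comparable: int, expected_fraction: float) -> float:
    """One-sided upper tail P(X >= n_shared), X ~ Binomial(I, expected_fraction)."""
    if not (0.0 < expected_fraction < 1.0):
        raise ValueError("expected_fraction must lie in (0, 1)")
    if not 0 <= n_shared <= n_comparable:
        raise ValueError("n_shared must lie in [0, n_comparable]")
    if n_shared == 0:
        return 1.0
    return float(stats.binom.sf(n_shared - 1, n_comparable, expected_fraction))


def three_species_enrichment(
    p_species: dict,
    x: int,
    n: int,
    inclusive: bool = False,
) -> EnrichmentResult:
    """Probability of >= x genes significant in all species out of n, under independence.

    ``p_species`` maps species name to its fraction of significant genes
    (significant at least once, over genes with computable SpliZ in >= 20
    cells of some cell type).  The null per-gene probability is the product
    of the per-species fractions.  The default tail is 1 - CDF(x; n, p), i.e.
    the strict P(X > x) exactly as conventionally printed; ``inclusive``
    switches to P(X >= x).  The variant used is recorded in the result.
    """
    if x > n:
        raise ValueError("x cannot exceed n")
    p_all = float(np.prod(list(p_species.values())))
    if inclusive:
        p_value = float(stats.binom.sf(x - 1, n, p_all)) if x > 0 else 1.0
        tail = "P(X >= x)"
    else:
        p_value = float(stats.binom.sf(x, n, p_all))
        tail = "P(X > x)"
    return EnrichmentResult(p_species=dict(p_species), p_all=p_all, n=n, x=x, p_value=p_value, tail=tail)
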