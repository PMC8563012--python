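"""Differential splicing across cell types or compartments.

Cells are grouped either by *cell type* (tissue + compartment + annotated
type, e.g. "lung immune macrophage") or by *compartment* (pooled across
tissues).  Per gene, group medians of the SpliZ are screened against the
asymptotic null for the median of n iid standard normals (variance pi/(2n)),
combined across groups by a Sidak correction of the minimum group p-value;
genes passing a nominal 0.05 screen get a label-permutation p-value, and
Benjamini-Hochberg correction is applied across all tested genes.  A gene is
called significant only if it additionally clears the effect-size gate (the
largest-magnitude group median) and a within-context consistency gate.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

MIN_CELLS_DEFAULT = 10
EFFECT_THRESHOLD_SPLIZ = 0.5
EFFECT_THRESHOLD_SPLIZVD = 3.5
DELTA_THRESHOLD = 0.5

__all__ = [
    "group_labels",
    "group_medians",
    "median_null_pvalue",
    "sidak_min_p",
    "permutation_refine",
    "exact_permutation_pvalue",
    "bh_adjust",
    "call_significant",
    "run_differential",
    "replicate_concordance",
    "effect_size_sweep",
]


def group_labels(annotations: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-cell group label plus its tissue/compartment context.

    ``grouping`` is ``"cell_type"`` (tissue + compartment + cell type) or
    ``"compartment"`` (compartment pooled across tissues)."""
    if grouping == "cell_type":
        label = (
            annotations["tissue"] + " " + annotations["compartment"] + " " + annotations["cell_type"]
        )
    elif grouping == "compartment":
        label = annotations["compartment"]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    return pd.DataFrame(
        {
            "cell_id": annotations["cell_id"],
            "group": label,
            "tissue": annotations["tissue"],
            "compartment": annotations["compartment"],
        }
    )


def group_medians(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    grouping: str = "cell_type",
    min_cells: int = MIN_CELLS_DEFAULT,
    value_col: str = "spliz",
) -> pd.DataFrame:
    """Per-gene, per-eligible-group medians over computable cells.

    Groups with fewer than ``min_cells`` computable cells are omitted; genes
    left with fewer than two eligible groups are excluded from testing (the
    caller sees them disappear; a count is logged).
    """
    labels = group_labels(annotations, grouping)
    df = scores.loc[scores["computable"], ["cell_id", "gene", value_col]].merge(labels, on="cell_id")
    agg = (
        df.groupby(["gene", "group", "tissue", "compartment"], sort=True)[value_col]
        .agg(n_cells="count", median="median")
        .reset_index()
    )
    agg = agg[agg["n_cells"] >= int(min_cells)]
    # genes need >=2 eligible groups to be testable
    counts = agg.groupby("gene")["group"].transform("count")
    dropped = agg.loc[counts < 2, "gene"].nunique()
    if dropped:
        logger.info("%d genes excluded with <2 eligible groups", dropped)
    return agg[counts >= 2].reset_index(drop=True)


def _median_null_sd(n: np.ndarray) -> np.ndarray:
    # asymptotic sd of the median of n iid N(0,1): sqrt(pi / (2 n))
    return np.sqrt(np.pi / (2.0 * n))


def sidak_min_p(medians: np.ndarray, sizes: np.ndarray) -> float:
    """Gene-level screen statistic: Sidak combination of the minimum group p.

    Each group's two-sided p comes from the normal null for the median of n
    standard normals; across G groups the minimum p is corrected as
    1 - (1 - p_min)^G.
    """
    z = np.abs(medians) / _median_null_sd(sizes.astype(float))
    p_groups = 2.0 * stats.norm.sf(z)
    p_min = float(np.min(p_groups))
    if p_min >= 1.0:
        return 1.0
    g = len(p_groups)
    # log1p formulation keeps precision for tiny p_min
    return float(-np.expm1(g * np.log1p(-p_min)))


def median_null_pvalue(gm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene screen p-value from the eligible group medians table."""
    rows = []
    for gene, block in gm.groupby("gene", sort=True):
        p = sidak_min_p(block["median"].to_numpy(), block["n_cells"].to_numpy())
        rows.append({"gene": gene, "p_raw": p})
    return pd.DataFrame(rows, columns=["gene", "p_raw"])


def _at_most(stat: float, observed: float) -> bool:
    # relative tolerance: permutation statistics span many orders of magnitude
    return stat <= observed * (1.0 + 1e-12) if observed > 0 else stat <= 0.0


def _group_stat(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    medians = np.empty(n_groups)
    sizes = np.empty(n_groups)
    for g in range(n_groups):
        vals = values[codes == g]
        medians[g] = np.median(vals)
        sizes[g] = len(vals)
    return sidak_min_p(medians, sizes)


def permutation_refine(
    values: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    early_stop_exceedances: int = 50,
) -> float:
    """Label-permutation p-value for the Sidak min-p statistic.

    p = (1 + #{permutation statistic <= observed}) / (1 + B), with adaptive
    early stopping once ``early_stop_exceedances`` exceedances accumulate
    (the estimate is then already precise where it matters).  Deterministic
    given ``seed``.
    """
    if n_permutations < 100:
        logger.warning("n_permutations=%d is low; p-value resolution is coarse", n_permutations)
    values = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(pd.Series(labels), sort=True)
    n_groups = len(uniques)
    if n_groups < 2:
        raise ValueError("permutation test needs >=2 groups")
    observed = _group_stat(values, codes, n_groups)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    for b in range(n_permutations):
        perm = rng.permutation(codes)
        done += 1
        if _at_most(_group_stat(values, perm, n_groups), observed):
            hits += 1
            if hits >= early_stop_exceedances:
                break
    return (1 + hits) / (1 + done)


def exact_permutation_pvalue(values: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive-permutation p-value over all distinct label arrangements.

    Feasible only for small cell counts; p = #{statistic <= observed}/N over
    the N distinct arrangements of the observed label multiset (the identity
    arrangement is included, so p >= 1/N)."""
    values = np.asarray(values, dtype=float)
    codes, uniques = pd.factorize(pd.Series(labels), sort=True)
    n_groups = len(uniques)
    observed = _group_stat(values, codes, n_groups)
    seen = set()
    hits = total = 0
    for perm in itertools.permutations(codes):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if _at_most(_group_stat(values, np.array(perm), n_groups), observed):
            hits += 1
    return hits / total


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DifferentialOptions:
    grouping: str = "cell_type"
    value_col: str = "spliz"
    min_cells: int = MIN_CELLS_DEFAULT
    n_permutations: int = 1000
    seed: int = 0
    alpha: float = 0.05
    effect_threshold: float = EFFECT_THRESHOLD_SPLIZ
    delta_threshold: float = DELTA_THRESHOLD


def _within_context_delta(block: pd.DataFrame) -> float:
    """Largest median spread among eligible groups sharing a tissue+compartment."""
    best = np.nan
    for (_, _), ctx in block.groupby(["tissue", "compartment"]):
        if len(ctx) >= 2:
            spread = float(ctx["median"].max() - ctx["median"].min())
            best = spread if np.isnan(best) else max(best, spread)
    return best


def _compartment_consistent(block: pd.DataFrame, all_medians: pd.DataFrame) -> bool:
    """The extreme compartment's per-tissue medians all share the pooled sign."""
    extreme = block.loc[block["median"].abs().idxmax()]
    sign = np.sign(extreme["median"])
    if sign == 0:
        return False
    per_tissue = all_medians[
        (all_medians["gene"] == extreme["gene"]) & (all_medians["compartment"] == extreme["compartment"])
    ]
    return bool((np.sign(per_tissue["median"]) == sign).all())


def call_significant(results: pd.DataFrame, options: DifferentialOptions) -> pd.DataFrame:
    """Apply the significance gates to an annotated results frame.

    significant <=> p_bh < alpha AND effect_size > effect_threshold AND
    (cell-type mode) within-context delta >= delta_threshold, or
    (compartment mode) the consistency flag."""
    out = results.copy()
    gates = (out["p_bh"] < options.alpha) & (out["effect_size"] > options.effect_threshold)
    if options.grouping == "cell_type":
        gates &= out["within_context_delta"] >= options.delta_threshold
    else:
        gates &= out["consistent"].fillna(False)
    out["significant"] = gates.fillna(False)
    return out


def run_differential(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    options: DifferentialOptions | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Full differential-splicing calling pipeline for one score table.

    Returns one row per tested gene with group count, effect size, screen and
    permutation p-values, BH-adjusted p and the significance call.
    """
    options = options or DifferentialOptions(**kwargs)
    gm = group_medians(
        scores, annotations, grouping=options.grouping, min_cells=options.min_cells, value_col=options.value_col
    )
    if gm.empty:
        return pd.DataFrame(
            columns=[
                "gene", "n_groups", "effect_size", "within_context_delta", "consistent",
                "p_raw", "p_perm", "p_final", "p_bh", "significant",
            ]
        )
    praw = median_null_pvalue(gm).set_index("gene")["p_raw"]

    labels = group_labels(annotations, options.grouping)
    cells = scores.loc[scores["computable"], ["cell_id", "gene", options.value_col]].merge(labels, on="cell_id")

    per_tissue_medians = None
    if options.grouping == "compartment":
        # per-tissue medians inside each compartment, for the consistency gate
        pt = (
            cells.groupby(["gene", "compartment", "tissue"], sort=True)[options.value_col]
            .agg(n_cells="count", median="median")
            .reset_index()
        )
        per_tissue_medians = pt[pt["n_cells"] >= options.min_cells]

    rows = []
    for gene, block in gm.groupby("gene", sort=True):
        p_raw = float(praw[gene])
        p_perm = np.nan
        if p_raw < 0.05:
            sub = cells[(cells["gene"] == gene) & cells["group"].isin(block["group"])]
            p_perm = permutation_refine(
                sub[options.value_col].to_numpy(),
                sub["group"].to_numpy(),
                n_permutations=options.n_permutations,
                seed=options.seed,
            )
        effect = float(block["median"].abs().max())
        delta = _within_context_delta(block) if options.grouping == "cell_type" else np.nan
        consistent = (
            _compartment_consistent(block, per_tissue_medians)
            if options.grouping == "compartment"
            else np.nan
        )
        rows.append(
            {
                "gene": gene,
                "n_groups": len(block),
                "effect_size": effect,
                "within_context_delta": delta,
                "consistent": consistent,
                "p_raw": p_raw,
                "p_perm": p_perm,
                "p_final": p_perm if not math.isnan(p_perm) else p_raw,
            }
        )
    res = pd.DataFrame(rows)
    res["p_bh"] = bh_adjust(res["p_final"].to_numpy())
    return call_significant(res, options)


def replicate_concordance(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    medians_a: pd.DataFrame,
    medians_b: pd.DataFrame,
    min_pairs: int = 3,
) -> float:
    """Pearson r of matched (gene, group) medians over genes significant in both runs."""
    sig = set(results_a.loc[results_a["significant"], "gene"]) & set(
        results_b.loc[results_b["significant"], "gene"]
    )
    return _matched_median_correlation(medians_a, medians_b, sig, min_pairs)


def _matched_median_correlation(medians_a, medians_b, genes, min_pairs) -> float:
    a = medians_a[medians_a["gene"].isin(genes)][["gene", "group", "median"]]
    b = medians_b[medians_b["gene"].isin(genes)][["gene", "group", "median"]]
    merged = a.merge(b, on=["gene", "group"], suffixes=("_a", "_b"))
    if len(merged) < min_pairs:
        raise ValueError(f"only {len(merged)} matched (gene, group) pairs; need >= {min_pairs}")
    return float(stats.pearsonr(merged["median_a"], merged["median_b"])[0])


def effect_size_sweep(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    medians_a: pd.DataFrame,
    medians_b: pd.DataFrame,
    thresholds,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Concordance r as a function of the effect-size cutoff.

    At each threshold, genes with BH p < alpha and effect size above the
    threshold in both replicates enter the correlation; thresholds that leave
    fewer than ``min_pairs`` matched pairs are reported as NaN (undefined)."""
    rows = []
    for thr in thresholds:
        ga = set(results_a.loc[(results_a["p_bh"] < alpha) & (results_a["effect_size"] > thr), "gene"])
        gb = set(results_b.loc[(results_b["p_bh"] < alpha) & (results_b["effect_size"] > thr), "gene"])
        genes = ga & gb
        try:
            r = _matched_median_correlation(medians_a, medians_b, genes, min_pairs)
        except ValueError:
            r = np.nan
        rows.append({"threshold": float(thr), "r": r, "n_genes": len(genes)})
    return pd.DataFrame(rows, columns=["threshold", "r", "n_genes"])
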