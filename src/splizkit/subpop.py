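"""Splicing-defined subpopulations within a cell type.

Under within-type homogeneity the per-cell SpliZ of a gene is approximately a
single Gaussian; hidden subpopulations with distinct splice profiles make a
Gaussian mixture fit better.  The number of components is chosen by the knee
of the ICL curve (integrated complete-data likelihood: BIC-penalized
log-likelihood minus assignment entropy), and a candidate split is accepted
only when every pair of components is separated by a Bhattacharyya distance
above 0.5 — otherwise the component count is decremented and refit until
either the gate passes or a single component remains.

The two-read binomial consistency test guards against the stochastic
binary-inclusion artifact: among cells with exactly two reads at a
two-partner anchor, it computes the probability that *all* are pure
(both reads to the same partner) under independent Binomial(2, p) sampling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

BHATTACHARYYA_GATE = 0.5
MIN_CELLS_FIT = 20

__all__ = [
    "MixtureFit",
    "SubpopulationCall",
    "TwoReadTestResult",
    "fit_gmm_icl",
    "select_knee",
    "bhattacharyya",
    "call_subpopulations",
    "two_read_consistency_test",
    "all_pure_probability",
]


@dataclass
class MixtureFit:
    k: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray  # n x k
    assignments: np.ndarray
    log_likelihood: float
    icl: float


@dataclass
class SubpopulationCall:
    k: int
    accepted: bool
    assignments: np.ndarray
    min_distance: float  # min pairwise Bhattacharyya at the accepted/refused k
    distances: dict = field(default_factory=dict)
    selected_k_icl: int = 1


def _fit_single(values: np.ndarray, k: int, seed: int, reg: float) -> MixtureFit:
    x = values.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=1,
        random_state=seed,
        reg_covar=reg,
    ).fit(x)
    n = len(values)
    ll = float(gm.score(x) * n)
    tau = gm.predict_proba(x)
    entropy = float(-np.sum(tau * np.log(np.clip(tau, 1e-300, None))))
    n_params = 3 * k - 1  # k-1 weights, k means, k variances
    icl = ll - 0.5 * n_params * math.log(n) - entropy
    return MixtureFit(
        k=k,
        weights=gm.weights_.copy(),
        means=gm.means_.ravel().copy(),
        variances=gm.covariances_.reshape(k).copy(),
        responsibilities=tau,
        assignments=np.argmax(tau, axis=1),
        log_likelihood=ll,
        icl=icl,
    )


def fit_gmm_icl(
    values,
    k_max: int = 5,
    seed: int = 0,
    min_cells: int = MIN_CELLS_FIT,
    n_restarts: int = 10,
) -> tuple[list[MixtureFit], int]:
    """EM fits for k = 1..k_max (best ICL of seeded restarts) and the knee-selected k."""
    values = np.asarray(values, dtype=float)
    if len(values) < min_cells:
        raise ValueError(f"need >= {min_cells} values to fit a mixture, got {len(values)}")
    sample_var = float(np.var(values))
    reg = max(1e-6 * sample_var, 1e-10)  # variance floor against degenerate components
    fits = []
    for k in range(1, k_max + 1):
        best = None
        for r in range(n_restarts):
            fit = _fit_single(values, k, seed + 1000 * k + r, reg)
            if best is None or fit.icl > best.icl:
                best = fit
        fits.append(best)
    selected = select_knee([f.icl for f in fits])
    return fits, selected


def select_knee(icl_values) -> int:
    """Knee-based component choice on the ICL curve over k = 1..k_max.

    When the curve attains an interior (or initial) maximum, that maximizer
    is the choice (ties to the smaller k): past the peak, extra components
    only lose penalized likelihood, so the peak *is* the knee.  A knee search
    proper only applies to monotone increasing curves, where the k with the
    strongest downward curvature (most negative discrete second difference)
    is selected; if the increasing curve has no concave point, the first k
    whose marginal gain falls below 5% of the total gain is used.
    Deterministic throughout.
    """
    icl = np.asarray(icl_values, dtype=float)
    kmax = len(icl)
    if kmax == 1:
        return 1
    d = np.diff(icl)
    if np.all(d > 0):
        total = icl[-1] - icl[0]
        second = icl[2:] - 2.0 * icl[1:-1] + icl[:-2]  # curvature at k = 2..kmax-1
        if second.size and np.any(second < 0):
            return 2 + int(np.argmin(second))
        for k in range(1, kmax):
            if d[k - 1] < 0.05 * total:
                return k
        return kmax
    return 1 + int(np.argmax(icl))


def bhattacharyya(mean1: float, var1: float, mean2: float, var2: float) -> float:
    """Bhattacharyya distance between two univariate Gaussians.

    D = (mu1-mu2)^2 / (4 (s1^2+s2^2)) + 0.5 ln((s1^2+s2^2) / (2 s1 s2));
    zero iff the distributions are identical."""
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    return float(
        (mean1 - mean2) ** 2 / (4.0 * (var1 + var2))
        + 0.5 * math.log((var1 + var2) / (2.0 * math.sqrt(var1 * var2)))
    )


def _min_pairwise_distance(fit: MixtureFit, noise_floor: float) -> tuple[float, dict]:
    # The SpliZ carries unit read-sampling variance by construction, so a
    # fitted component narrower than the sampling noise is measuring count
    # quantization, not a distinct splicing state; separation is therefore
    # assessed with variances floored at the sampling width.
    dists = {}
    dmin = math.inf
    for i in range(fit.k):
        for j in range(i + 1, fit.k):
            d = bhattacharyya(
                fit.means[i], max(fit.variances[i], noise_floor),
                fit.means[j], max(fit.variances[j], noise_floor),
            )
            dists[(i, j)] = d
            dmin = min(dmin, d)
    return dmin, dists


def call_subpopulations(
    values,
    k_max: int = 5,
    seed: int = 0,
    min_cells: int = MIN_CELLS_FIT,
    gate: float = BHATTACHARYYA_GATE,
    noise_floor_variance: float = 1.0,
    min_component_cells: int = 3,
) -> SubpopulationCall:
    """ICL-selected mixture with the Bhattacharyya separation gate.

    Starting from the knee-selected k, components are merged down (k -> k-1,
    refit) until every pair of components is > ``gate`` apart, or k = 1
    (no subpopulations).  ``noise_floor_variance`` is the read-sampling
    variance of a single score (1 by the SpliZ scaling); component variances
    are floored there when measuring separation, so lattice-like clumps of a
    discrete low-depth score distribution do not masquerade as
    subpopulations.  A component with fewer than ``min_component_cells``
    hard-assigned cells is degenerate (its variance cannot be estimated and
    collapses to the regularization floor) and fails the gate outright."""
    values = np.asarray(values, dtype=float)
    fits, k0 = fit_gmm_icl(values, k_max=k_max, seed=seed, min_cells=min_cells)
    k = k0
    while k >= 2:
        fit = fits[k - 1]
        sizes = np.bincount(fit.assignments, minlength=k)
        dmin, dists = _min_pairwise_distance(fit, noise_floor_variance)
        if sizes.min() < min_component_cells:
            logger.info("k=%d rejected: component with %d cell(s) is degenerate", k, int(sizes.min()))
            k -= 1
            continue
        if dmin > gate:
            return SubpopulationCall(
                k=k, accepted=True, assignments=fit.assignments, min_distance=dmin,
                distances=dists, selected_k_icl=k0,
            )
        k -= 1
    return SubpopulationCall(
        k=1, accepted=False, assignments=np.zeros(len(values), dtype=int), min_distance=0.0,
        distances={}, selected_k_icl=k0,
    )


# ---------------------------------------------------------------------------
# Two-read binomial consistency test
# ---------------------------------------------------------------------------


@dataclass
class TwoReadTestResult:
    p_hat: float
    n_two_read_cells: int
    n_pure: int
    probability: float  # P(all two-read cells pure | independent Binomial(2, p_hat))
    designated_partner: int


def all_pure_probability(p_hat: float, n_cells: int) -> float:
    """(1 - 2 p (1-p))^n: chance that every two-read cell is pure under independence."""
    return float((1.0 - 2.0 * p_hat * (1.0 - p_hat)) ** n_cells)


def two_read_consistency_test(
    counts: pd.DataFrame,
    gene: str,
    anchor_pos: int,
    role: str = "donor",
    designated_partner: int | None = None,
) -> TwoReadTestResult:
    """Binomial purity test at a two-partner anchor.

    ``p_hat`` is the pooled fraction of the anchor's reads going to the
    designated partner (default: the majority partner); among cells with
    exactly two reads at the anchor, ``n_pure`` counts those with both reads
    to one partner, and ``probability`` is the chance that all of them would
    be pure if each cell drew its two reads independently with probability
    ``p_hat``."""
    anchor_col, partner_col = ("donor_pos", "acceptor_pos") if role == "donor" else ("acceptor_pos", "donor_pos")
    block = counts[(counts["gene"] == gene) & (counts[anchor_col] == int(anchor_pos))]
    if block.empty:
        raise ValueError(f"no reads at anchor {anchor_pos} of gene {gene}")
    per_partner = block.groupby(partner_col)["count"].sum().sort_values(ascending=False)
    if len(per_partner) != 2:
        raise ValueError(
            f"two-read test needs exactly 2 partners at the anchor, found {len(per_partner)}"
        )
    if designated_partner is None:
        designated_partner = int(per_partner.index[0])
    total = int(per_partner.sum())
    p_hat = float(per_partner.get(designated_partner, 0)) / total
    per_cell = block.pivot_table(index="cell_id", columns=partner_col, values="count", aggfunc="sum", fill_value=0)
    cell_totals = per_cell.sum(axis=1)
    two_read = per_cell[cell_totals == 2]
    if two_read.empty:
        raise ValueError("no cells with exactly two reads at the anchor")
    n_pure = int((two_read.max(axis=1) == 2).sum())
    return TwoReadTestResult(
        p_hat=p_hat,
        n_two_read_cells=len(two_read),
        n_pure=n_pure,
        probability=all_pure_probability(p_hat, len(two_read)),
        designated_partner=designated_partner,
    )
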