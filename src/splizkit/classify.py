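"""Compartment prediction from the SpliZ of a small gene panel via k-means.

Cells with computable SpliZ for every panel gene (and an allowed compartment
label) are clustered with seeded k-means; each cluster is then assigned to a
compartment by minimum-cost bipartite matching on the confusion matrix, which
is the exact optimum of "assign clusters to labels so as to minimize
classification error".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

DEFAULT_LABELS = ("immune", "epithelial", "stromal")

__all__ = ["ClassificationReport", "kmeans_compartment_classify"]


@dataclass
class ClassificationReport:
    n_cells: int
    labels: list[str]
    cluster_to_label: dict[int, str]
    per_label_accuracy: dict[str, float]
    overall_accuracy: float
    confusion: pd.DataFrame  # rows clusters, columns labels


def kmeans_compartment_classify(
    scores: pd.DataFrame,
    annotations: pd.DataFrame,
    genes,
    k: int = 3,
    seed: int = 0,
    labels=DEFAULT_LABELS,
    n_restarts: int = 10,
    value_col: str = "spliz",
) -> ClassificationReport:
    """Cluster cells on the panel genes' SpliZ values and score label recovery."""
    genes = list(genes)
    labels = list(labels)
    if k > len(labels):
        logger.warning("k=%d exceeds the number of labels (%d)", k, len(labels))
    wide = (
        scores.loc[scores["computable"] & scores["gene"].isin(genes)]
        .pivot(index="cell_id", columns="gene", values=value_col)
        .dropna()
    )
    missing = [g for g in genes if g not in wide.columns]
    if missing:
        raise ValueError(f"no computable scores for panel gene(s) {missing}")
    wide = wide[genes]
    ann = annotations.set_index("cell_id")["compartment"]
    wide = wide[wide.index.map(ann).isin(labels)]
    if len(wide) < k:
        raise ValueError(f"fewer cells ({len(wide)}) than clusters ({k})")
    wide = wide.sort_index()  # cell-order invariance
    true = wide.index.map(ann).to_numpy()
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    clusters = km.fit_predict(wide.to_numpy())

    confusion = np.zeros((k, len(labels)), dtype=int)
    label_index = {lab: j for j, lab in enumerate(labels)}
    for c, t in zip(clusters, true):
        confusion[c, label_index[t]] += 1

    # pad to square so the matching is a bijection where counts allow
    dim = max(k, len(labels))
    cost = np.zeros((dim, dim))
    cost[:k, : len(labels)] = -confusion
    row_ind, col_ind = linear_sum_assignment(cost)
    cluster_to_label = {
        int(r): labels[int(c)] for r, c in zip(row_ind, col_ind) if r < k and c < len(labels)
    }

    predicted = np.array([cluster_to_label.get(int(c), "") for c in clusters])
    correct = predicted == true
    per_label = {}
    for lab in labels:
        mask = true == lab
        per_label[lab] = float(correct[mask].mean()) if mask.any() else float("nan")
    return ClassificationReport(
        n_cells=len(wide),
        labels=labels,
        cluster_to_label=cluster_to_label,
        per_label_accuracy=per_label,
        overall_accuracy=float(correct.mean()),
        confusion=pd.DataFrame(confusion, index=[f"cluster{i}" for i in range(k)], columns=labels),
    )
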