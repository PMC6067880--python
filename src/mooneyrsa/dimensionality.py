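"""Representational dimensionality via progressively higher-dimensional MDS.

The dimensionality of an ROI's representational space in one condition is
estimated as the smallest embedding dimension (tested in ascending order,
2..10 by default) whose non-metric MDS solution reconstructs the
within-condition RDM with r^2 > 0.90, where r^2 is the squared Pearson
correlation between the embedded pairwise Euclidean distances and the
original dissimilarities over the strictly lower triangle.  If no tested
dimension reaches the threshold the estimate is flagged rather than silently
reported as the ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from . import stats_core
from .first_order_rsa import MDSSolution, mds_embed
from .rdm_core import RDM, CONDITIONS
from .stats_core import StatResult

__all__ = [
    "r_squared",
    "DimensionalityEstimate",
    "estimate_dimensionality",
    "dataset_dimensionality",
    "network_condition_anova",
]


def r_squared(solution: MDSSolution, original: np.ndarray) -> float:
    """Proportion of RDM variance captured by an MDS solution.

    Squared Pearson correlation between the embedded pairwise Euclidean
    distances and the original dissimilarities (strictly lower triangles).
    """
    original = np.asarray(original, dtype=float)
    if original.shape[0] != solution.coordinates.shape[0]:
        raise ValueError("point counts of solution and matrix differ")
    embedded = pdist(solution.coordinates)
    target = squareform(original, checks=False)
    if embedded.std() == 0 or target.std() == 0:
        raise ValueError("constant distance vector; r^2 undefined")
    return float(pearsonr(embedded, target)[0] ** 2)


@dataclass
class DimensionalityEstimate:
    k_hat: int | None          # None when no tested dimension reached threshold
    reached: bool
    r2_at_k: float             # r^2 at k_hat, or at the largest tested dim
    r2_by_dim: dict[int, float]
    threshold: float


def estimate_dimensionality(
    rdm_block: np.ndarray,
    threshold: float = 0.90,
    dims: range | tuple[int, ...] = range(2, 11),
    seed: int = 0,
    restarts: int = 1,
) -> DimensionalityEstimate:
    """Smallest tested dimension whose MDS fit exceeds the r^2 threshold.

    Dimensions are tested in ascending order and the search stops at the
    first success, so the estimate is the floor of the tested range whenever
    even the smallest dimension suffices.
    """
    r2_by_dim: dict[int, float] = {}
    for d in dims:
        sol = mds_embed(rdm_block, n_dims=d, seed=seed, restarts=restarts)
        r2_by_dim[d] = sol.r_squared
        if sol.r_squared > threshold:
            return DimensionalityEstimate(
                k_hat=d, reached=True, r2_at_k=sol.r_squared,
                r2_by_dim=r2_by_dim, threshold=threshold)
    last = max(r2_by_dim) if r2_by_dim else None
    return DimensionalityEstimate(
        k_hat=None, reached=False,
        r2_at_k=r2_by_dim.get(last, float("nan")) if last else float("nan"),
        r2_by_dim=r2_by_dim, threshold=threshold)


def dataset_dimensionality(
    rdms: dict[tuple[str, str], RDM],
    networks: dict[str, str],
    threshold: float = 0.90,
    dims: range | tuple[int, ...] = range(2, 11),
    seed: int = 0,
    restarts: int = 1,
) -> pd.DataFrame:
    """Estimate k per subject x ROI x condition.

    ``rdms`` maps (subject, roi) to the full condition-blocked RDM.  Returns
    a tidy frame (subject, roi, network, condition, k_hat, r2_at_k, reached);
    unreached estimates carry k_hat = NaN.
    """
    rows = []
    for (subject, roi), rdm in rdms.items():
        for cond in CONDITIONS:
            est = estimate_dimensionality(
                rdm.block(cond, cond), threshold=threshold, dims=dims,
                seed=seed, restarts=restarts)
            rows.append({
                "subject": subject, "roi": roi, "network": networks.get(roi, ""),
                "condition": cond,
                "k_hat": est.k_hat if est.reached else np.nan,
                "r2_at_k": est.r2_at_k, "reached": est.reached,
            })
    return pd.DataFrame(rows)


def network_condition_anova(results: pd.DataFrame) -> dict[str, object]:
    """Two-way repeated-measures ANOVA of dimensionality.

    Factors: network (ROIs averaged per network per subject) and perceptual
    condition.  "Not reached" estimates are excluded from the network means
    with a logged count.  Bonferroni post-hocs compare networks and
    conditions.
    """
    usable = results.dropna(subset=["k_hat"])
    n_dropped = len(results) - len(usable)
    cells = (
        usable.groupby(["subject", "network", "condition"])["k_hat"]
        .mean().rename("dimensionality").reset_index()
    )
    counts = cells.groupby("subject").size()
    n_net = cells["network"].nunique()
    n_cond = cells["condition"].nunique()
    complete = counts[counts == n_net * n_cond].index
    incomplete = sorted(set(cells["subject"]) - set(complete))
    if incomplete:
        cells = cells[cells["subject"].isin(complete)]
    if cells["subject"].nunique() < 2:
        raise ValueError("fewer than 2 subjects with complete network x condition cells")
    effects = stats_core.rm_anova(
        cells, dv="dimensionality", within=["network", "condition"],
        subject="subject", family="dimensionality_anova")
    posthoc: dict[str, list[StatResult]] = {
        "network": stats_core.pairwise_posthoc(
            cells.groupby(["subject", "network"])["dimensionality"].mean().reset_index(),
            dv="dimensionality", within="network", subject="subject",
            family="dimensionality_posthoc_network"),
        "condition": stats_core.pairwise_posthoc(
            cells.groupby(["subject", "condition"])["dimensionality"].mean().reset_index(),
            dv="dimensionality", within="condition", subject="subject",
            family="dimensionality_posthoc_condition"),
    }
    return {"effects": effects, "posthoc": posthoc, "cells": cells,
            "n_not_reached": n_dropped, "excluded_subjects": incomplete}
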