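"""Second-order RSA: how similarly do regions represent the stimulus set?

The first-order RDM of each ROI is itself a point in a space of
representational formats.  Averaging RDMs across subjects per ROI and taking
1 - Spearman rank correlation between the vectorized (strictly lower
triangle) group RDMs of every ROI pair yields a second-order RDM over ROIs.
Rank correlation makes the comparison invariant to any monotone transform of
either ROI's dissimilarities.  Embedding the second-order RDM with 2-D
non-metric MDS reveals the cortical hierarchy of representational format;
goodness-of-fit is reported as stress-1 (values < 0.1 indicate a good fit)
and r^2 (squared correlation between embedded and original distances).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .first_order_rsa import MDSSolution, mds_embed
from .rdm_core import RDM, CONDITIONS

SCOPES = ("across", *CONDITIONS)

__all__ = ["SecondOrderRDM", "second_order_rdm", "embed_hierarchy", "SCOPES"]


@dataclass
class SecondOrderRDM:
    """R x R matrix of 1 - Spearman rho between group-averaged first-order RDMs."""

    values: np.ndarray
    rois: list[str]
    networks: dict[str, str]
    scope: str  # "across" (full matrix) or one condition's within block

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rois, columns=self.rois)


def _scope_vector(rdm: RDM, scope: str, include_between: bool = True) -> np.ndarray:
    """Strictly-lower-triangle vector of the scoped part of the RDM.

    For the across-conditions scope the entire (3n x 3n) matrix is used,
    which includes the between-condition blocks; ``include_between=False``
    restricts to the concatenated within-condition triangles instead.
    """
    if scope == "across":
        if include_between:
            m = rdm.values
            return m[np.tril_indices(m.shape[0], k=-1)]
        parts = []
        for cond in CONDITIONS:
            blk = rdm.block(cond, cond)
            parts.append(blk[np.tril_indices(blk.shape[0], k=-1)])
        return np.concatenate(parts)
    if scope not in CONDITIONS:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    blk = rdm.block(scope, scope)
    return blk[np.tril_indices(blk.shape[0], k=-1)]


def second_order_rdm(
    group_rdms: dict[str, RDM],
    scope: str = "across",
    networks: dict[str, str] | None = None,
    include_between: bool = True,
) -> SecondOrderRDM:
    """Pairwise 1 - Spearman rho distances between ROI group-average RDMs."""
    rois = list(group_rdms)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    first = group_rdms[rois[0]]
    vectors = {}
    for roi, rdm in group_rdms.items():
        if rdm.image_ids != first.image_ids:
            raise ValueError(f"RDM labels of roi {roi!r} do not match")
        vec = _scope_vector(rdm, scope, include_between=include_between)
        if np.std(vec) == 0:
            raise ValueError(f"constant RDM vector for roi {roi!r}; rho undefined")
        vectors[roi] = vec
    n = len(rois)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rho = spearmanr(vectors[rois[i]], vectors[rois[j]]).statistic
            out[i, j] = out[j, i] = 1.0 - rho
    return SecondOrderRDM(values=out, rois=rois, networks=dict(networks or {}),
                          scope=scope)


def embed_hierarchy(so_rdm: SecondOrderRDM, seed: int = 0,
                    restarts: int = 1) -> MDSSolution:
    """2-D non-metric MDS of the ROI hierarchy with stress-1 and r^2."""
    if len(so_rdm.rois) < 3:
        raise ValueError("need at least 3 ROIs to embed")
    return mds_embed(so_rdm.values, n_dims=2, seed=seed, restarts=restarts)


def hierarchy_table(so_rdm: SecondOrderRDM, solution: MDSSolution) -> pd.DataFrame:
    """Tidy coordinates (roi, network, dim1, dim2, stress, r2)."""
    return pd.DataFrame({
        "roi": so_rdm.rois,
        "network": [so_rdm.networks.get(r, "") for r in so_rdm.rois],
        "dim1": solution.coordinates[:, 0],
        "dim2": solution.coordinates[:, 1],
        "stress": solution.stress,
        "r2": solution.r_squared,
    })
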