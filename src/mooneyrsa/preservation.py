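"""Preservation Index: how much of the pre-disambiguation code survives?

For each subject and ROI, the pre x post square of the similarity matrix is
restricted to that subject's disambiguation-set images (pre not-recognized
and post recognized), all r values are Fisher-z transformed, and

    PI = mean(z(diagonal)) - mean(z(off-diagonal))

A positive PI means a post-disambiguation Mooney image stays more similar to
its own pre-disambiguation pattern than to other images' patterns - i.e. the
old code is partially retained (interpretable as cross-condition decoding of
image identity).  The off-diagonal mean uses all n(n-1) off-diagonal cells of
the non-symmetric pre x post block, since s(pre_i, post_j) differs from
s(pre_j, post_i).  A normalized variant divides the PI by the mean
off-diagonal z.  Group tests: per-ROI one-sample t (PI) and one-sample
Wilcoxon (normalized PI) against 0, FDR-corrected across ROIs; network
comparisons use one-way repeated-measures ANOVAs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stats_core
from .rdm_core import RDM, fisher_z, rdm_to_rsm
from .stats_core import StatResult

logger = logging.getLogger(__name__)

__all__ = [
    "preservation_index",
    "normalized_pi",
    "dataset_pi",
    "pi_group_tests",
    "pi_network_anova",
]


def _z_means(block: np.ndarray) -> tuple[float, float]:
    block = np.asarray(block, dtype=float)
    n = block.shape[0]
    if block.ndim != 2 or block.shape[1] != n:
        raise ValueError(f"expected a square block, got {block.shape}")
    if n < 2:
        raise ValueError("need at least 2 images to compute a PI")
    z = fisher_z(block)
    off = ~np.eye(n, dtype=bool)
    return float(np.diag(z).mean()), float(z[off].mean())


def preservation_index(block: np.ndarray) -> float:
    """PI = mean diagonal z minus mean off-diagonal z of a pre x post block."""
    diag, off = _z_means(block)
    return diag - off


def normalized_pi(block: np.ndarray) -> float:
    """PI divided by the mean off-diagonal z; NaN if the denominator is 0."""
    diag, off = _z_means(block)
    if off == 0:
        return float("nan")
    return (diag - off) / off


def dataset_pi(
    rdms: dict[tuple[str, str], RDM],
    subsets: dict[str, list[str]],
    networks: dict[str, str],
    min_images: int = 2,
) -> pd.DataFrame:
    """PI and normalized PI per subject x ROI on disambiguation-set images.

    ``subsets`` maps subject -> image ids (typically the behavior module's
    disambiguation set; a verbal-identification-based set can be passed
    instead).  Subjects with fewer than ``min_images`` images are excluded
    with a log record.
    """
    rows = []
    for (subject, roi), rdm in rdms.items():
        images = subsets.get(subject, [])
        if len(images) < min_images:
            logger.info("PI: excluding (%s, %s): %d disambiguation-set images",
                        subject, roi, len(images))
            continue
        rsm = rdm_to_rsm(rdm)
        block = rsm.block("pre", "post", images=images)
        pi = preservation_index(block)
        npi = normalized_pi(block)
        if np.isnan(npi):
            logger.info("PI: zero off-diagonal z mean for (%s, %s); "
                        "normalized PI flagged missing", subject, roi)
        rows.append({"subject": subject, "roi": roi,
                     "network": networks.get(roi, ""),
                     "n_images": len(images), "pi": pi, "pi_norm": npi})
    return pd.DataFrame(rows)


def pi_group_tests(pis: pd.DataFrame, min_subjects: int = 6) -> pd.DataFrame:
    """Per-ROI one-sample tests of PI (t) and normalized PI (Wilcoxon) vs 0.

    BH-FDR is applied across ROIs separately within each test family.  The
    normalized PI uses a Wilcoxon signed-rank test because a ratio of
    normal variables is not itself normal.
    """
    t_results: list[StatResult] = []
    w_results: list[StatResult] = []
    for roi, grp in pis.groupby("roi", sort=False):
        if len(grp) < min_subjects:
            raise ValueError(f"roi {roi!r}: only {len(grp)} subjects "
                             f"(need >= {min_subjects})")
        pi_vals = grp["pi"].to_numpy()
        if (pi_vals == 0).all():
            # degenerate but well-defined: no preservation anywhere
            res_t = StatResult(name="t", statistic=0.0, df=(1, len(pi_vals) - 1),
                               p=1.0, effect_size=0.0, effect_size_name="cohen_d",
                               label=str(roi), n=len(pi_vals))
        else:
            res_t = stats_core.one_sample_t(pi_vals, label=str(roi))
        norm = grp["pi_norm"].dropna().to_numpy()
        if (norm == 0).all():
            res_w = StatResult(name="W", statistic=len(norm) * (len(norm) + 1) / 4,
                               df=None, p=1.0, label=str(roi), n=len(norm))
        else:
            res_w = stats_core.wilcoxon_signed_rank(norm, label=str(roi))
        res_w.effect_size = float(np.mean(norm))
        res_w.effect_size_name = "mean_pi_norm"
        t_results.append(res_t)
        w_results.append(res_w)
    t_results = stats_core.attach_fdr(t_results, family="pi_t")
    w_results = stats_core.attach_fdr(w_results, family="pi_norm_wilcoxon")
    frames = []
    for results, measure in ((t_results, "pi"), (w_results, "pi_norm")):
        frame = pd.DataFrame([r.to_dict() for r in results])
        frame.insert(0, "measure", measure)
        frame = frame.rename(columns={"label": "roi"})
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


_THREE_LEVEL = ("FPN-parietal", "FPN-frontal", "DMN")


def _collapse_network(network: str, grouping: str) -> str | None:
    if grouping == "5-level":
        if network in ("FPN-frontal", "FPN-parietal"):
            return "FPN"
        return network
    if grouping == "3-level":
        return network if network in _THREE_LEVEL else None
    raise ValueError(f"unknown grouping {grouping!r}")


def pi_network_anova(pis: pd.DataFrame, grouping: str = "5-level") -> dict[str, object]:
    """One-way repeated-measures ANOVA of per-network mean PI.

    ``grouping="5-level"`` compares Visual, LOC, FG, FPN (frontal+parietal
    collapsed) and DMN; ``"3-level"`` compares FPN-parietal, FPN-frontal and
    DMN only.  Bonferroni-corrected pairwise post-hocs included.
    """
    work = pis.copy()
    work["network_group"] = [
        _collapse_network(n, grouping) for n in work["network"]]
    work = work.dropna(subset=["network_group"])
    cells = (
        work.groupby(["subject", "network_group"])["pi"]
        .mean().rename("pi").reset_index()
    )
    n_groups = cells["network_group"].nunique()
    counts = cells.groupby("subject").size()
    incomplete = sorted(counts[counts != n_groups].index)
    if incomplete:
        raise ValueError(f"subjects with incomplete network cells: {incomplete}")
    effects = stats_core.rm_anova(cells, dv="pi", within="network_group",
                                  subject="subject", family=f"pi_anova_{grouping}")
    posthoc = stats_core.pairwise_posthoc(
        cells, dv="pi", within="network_group", subject="subject",
        family=f"pi_posthoc_{grouping}")
    return {"effects": effects, "posthoc": posthoc, "cells": cells}
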