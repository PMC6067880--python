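"""Condition-blocked representational dissimilarity/similarity matrices.

The experiment presents every image in three perceptual conditions: as a
two-tone Mooney image before disambiguation (``pre``), as the same Mooney
image after its gray-scale source has been seen (``post``), and as the
gray-scale source itself (``gray``).  Stacking the per-image multivoxel
response patterns of all three conditions and correlating every pair yields a
(3*n_images) x (3*n_images) matrix of correlation distances (1 - Pearson r),
the representational dissimilarity matrix (RDM).  Its elementwise complement
(Pearson r itself) is the representational similarity matrix (RSM).

Rows and columns follow a fixed block order [pre | post | gray]; within each
block, images are ordered natural category first, then manmade, ascending
image id within category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONDITIONS: tuple[str, ...] = ("pre", "post", "gray")
CATEGORY_ORDER: tuple[str, ...] = ("natural", "manmade")

__all__ = [
    "CONDITIONS",
    "ROIInfo",
    "PatternDataset",
    "RDM",
    "compute_rdm",
    "rdm_to_rsm",
    "rsm_to_rdm",
    "within_condition_mean",
    "between_condition_diagonal_mean",
    "group_average",
    "fisher_z",
    "subsample_voxels",
    "canonical_image_order",
    "write_rdm",
    "read_rdm",
]


@dataclass(frozen=True)
class ROIInfo:
    """Region of interest: name, network membership and voxel count."""

    name: str
    network: str  # Visual, LOC, FG, FPN-frontal, FPN-parietal, DMN
    n_voxels: int
    latent_dim: int | None = None  # known only for synthetic data


@dataclass
class PatternDataset:
    """Per subject x ROI activity patterns for the three conditions.

    ``patterns[(subject, roi)][condition]`` is an (n_images, n_voxels) array
    whose row order matches ``image_ids``.
    """

    subjects: list[str]
    rois: dict[str, ROIInfo]
    image_ids: list[str]
    categories: dict[str, str]  # image_id -> natural/manmade
    patterns: dict[tuple[str, str], dict[str, np.ndarray]]

    def validate(self) -> None:
        n = len(self.image_ids)
        for (subject, roi), conds in self.patterns.items():
            if roi not in self.rois:
                raise ValueError(f"unknown roi {roi!r} for subject {subject!r}")
            for cond in CONDITIONS:
                if cond not in conds:
                    raise ValueError(f"missing condition {cond!r} for ({subject}, {roi})")
                mat = conds[cond]
                if mat.shape != (n, self.rois[roi].n_voxels):
                    raise ValueError(
                        f"({subject}, {roi}, {cond}) has shape {mat.shape}, "
                        f"expected {(n, self.rois[roi].n_voxels)}"
                    )

    def networks(self) -> dict[str, str]:
        return {name: info.network for name, info in self.rois.items()}


def canonical_image_order(image_ids: Iterable[str], categories: Mapping[str, str]) -> list[str]:
    """Image ids sorted natural category first then manmade, ascending id."""
    rank = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    return sorted(image_ids, key=lambda i: (rank[categories[i]], i))


@dataclass
class RDM:
    """Square condition-blocked matrix of 1 - Pearson r (or r, for an RSM).

    ``values`` has shape (3n, 3n) with block order [pre | post | gray];
    ``image_ids`` gives the within-block row order.  ``kind`` distinguishes
    dissimilarity ("rdm") from similarity ("rsm") content.
    """

    values: np.ndarray
    image_ids: list[str]
    categories: dict[str, str] = field(default_factory=dict)
    kind: str = "rdm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = 3 * len(self.image_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match "
                             f"{len(self.image_ids)} images x 3 conditions")
        if self.kind not in ("rdm", "rsm"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n_images(self) -> int:
        return len(self.image_ids)

    def labels(self) -> list[tuple[str, str]]:
        return [(c, i) for c in CONDITIONS for i in self.image_ids]

    def _slice(self, cond: str) -> slice:
        if cond not in CONDITIONS:
            raise ValueError(f"unknown condition {cond!r}; expected one of {CONDITIONS}")
        i = CONDITIONS.index(cond)
        n = self.n_images
        return slice(i * n, (i + 1) * n)

    def block(self, cond_a: str, cond_b: str, images: Iterable[str] | None = None) -> np.ndarray:
        """Sub-matrix with rows from ``cond_a`` and columns from ``cond_b``.

        ``images`` optionally restricts both axes to a subset of image ids
        (order follows the block's canonical order).
        """
        sub = self.values[self._slice(cond_a), self._slice(cond_b)]
        if images is not None:
            idx = [self.image_ids.index(i) for i in images]
            missing = [i for i in images if i not in self.image_ids]
            if missing:
                raise ValueError(f"unknown image ids: {missing}")
            idx = sorted(idx)
            sub = sub[np.ix_(idx, idx)]
        return sub

    def validate(self, atol: float = 1e-10) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("matrix is not symmetric")
        diag_target = 0.0 if self.kind == "rdm" else 1.0
        if not np.allclose(np.diag(v), diag_target, atol=atol):
            raise ValueError(f"diagonal is not {diag_target}")
        lo, hi = (0.0, 2.0) if self.kind == "rdm" else (-1.0, 1.0)
        if v.min() < lo - atol or v.max() > hi + atol:
            raise ValueError(f"entries outside [{lo}, {hi}]")


def compute_rdm(
    patterns: Mapping[str, np.ndarray],
    image_ids: list[str],
    categories: Mapping[str, str] | None = None,
) -> RDM:
    """Build the condition-blocked RDM from the three pattern matrices.

    ``patterns`` maps condition -> (n_images, n_voxels) array with rows
    aligned to ``image_ids``.  Rows are re-sorted into the canonical block
    order (natural before manmade) when ``categories`` is given.  Pearson
    correlation across voxels is computed between every pair of rows from all
    conditions; the RDM entry is 1 - r.
    """
    for cond in CONDITIONS:
        if cond not in patterns:
            raise ValueError(f"missing condition {cond!r}")
    mats = [np.asarray(patterns[c], dtype=float) for c in CONDITIONS]
    n = len(image_ids)
    for cond, m in zip(CONDITIONS, mats):
        if m.ndim != 2 or m.shape[0] != n:
            raise ValueError(f"{cond}: expected ({n}, n_voxels) matrix, got {m.shape}")
        if m.shape[1] < 2:
            raise ValueError(f"{cond}: need at least 2 voxels")
        sd = m.std(axis=1)
        if (sd == 0).any():
            bad = [image_ids[i] for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance pattern rows in {cond}: {bad}")
    if categories is not None:
        order = canonical_image_order(image_ids, categories)
        idx = [image_ids.index(i) for i in order]
        mats = [m[idx] for m in mats]
        image_ids = order
        categories = dict(categories)
    else:
        categories = {}
    stacked = np.vstack(mats)
    r = np.corrcoef(stacked)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return RDM(values=d, image_ids=list(image_ids), categories=dict(categories), kind="rdm")


def rdm_to_rsm(rdm: RDM) -> RDM:
    """Elementwise 1 - d; turns a dissimilarity matrix into similarities."""
    if rdm.kind != "rdm":
        raise ValueError("input is not an RDM")
    return RDM(values=1.0 - rdm.values, image_ids=list(rdm.image_ids),
               categories=dict(rdm.categories), kind="rsm")


def rsm_to_rdm(rsm: RDM) -> RDM:
    if rsm.kind != "rsm":
        raise ValueError("input is not an RSM")
    return RDM(values=1.0 - rsm.values, image_ids=list(rsm.image_ids),
               categories=dict(rsm.categories), kind="rdm")


def within_condition_mean(rdm: RDM, cond: str, images: Iterable[str] | None = None) -> float:
    """Mean of the strictly-lower-triangle entries of one within-condition block."""
    blk = rdm.block(cond, cond, images=images)
    il = np.tril_indices(blk.shape[0], k=-1)
    return float(blk[il].mean())


def between_condition_diagonal_mean(
    rsm: RDM, cond_a: str, cond_b: str, images: Iterable[str] | None = None
) -> float:
    """Mean same-image similarity across two conditions (block diagonal)."""
    blk = rsm.block(cond_a, cond_b, images=images)
    return float(np.diag(blk).mean())


def group_average(rdms: list[RDM]) -> RDM:
    """Elementwise arithmetic mean of same-labelled RDMs (or RSMs)."""
    if not rdms:
        raise ValueError("no RDMs to average")
    first = rdms[0]
    for r in rdms[1:]:
        if r.image_ids != first.image_ids or r.kind != first.kind:
            raise ValueError("RDM labels/kinds do not match across inputs")
    mean = np.mean([r.values for r in rdms], axis=0)
    return RDM(values=mean, image_ids=list(first.image_ids),
               categories=dict(first.categories), kind=first.kind)


_CLIP = 1.0 - 1e-12


def fisher_z(r) -> np.ndarray | float:
    """Fisher's z-transform arctanh(r), clipping |r| to 1 - 1e-12 first.

    Same-image cross-condition correlations can reach 1 exactly in noise-free
    synthetic limits; clipping keeps the transform finite and emits a warning
    rather than failing.
    """
    arr = np.asarray(r, dtype=float)
    if (np.abs(arr) >= 1).any():
        warnings.warn("correlation magnitude >= 1 clipped before Fisher z",
                      RuntimeWarning, stacklevel=2)
    z = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return float(z) if np.isscalar(r) or np.ndim(r) == 0 else z


def subsample_voxels(dataset: PatternDataset, n: int, seed: int) -> PatternDataset:
    """Equate ROI sizes by sampling ``n`` voxels without replacement.

    The same voxel subset is applied to all three conditions within a
    subject x ROI, so correlation structure differences cannot arise from
    condition-specific voxel selections.
    """
    for roi, info in dataset.rois.items():
        if n > info.n_voxels:
            raise ValueError(f"n={n} exceeds voxel count {info.n_voxels} of roi {roi!r}")
    rng = np.random.default_rng(seed)
    new_patterns: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    choices: dict[tuple[str, str], np.ndarray] = {}
    for (subject, roi), conds in dataset.patterns.items():
        key = (subject, roi)
        if key not in choices:
            choices[key] = np.sort(rng.choice(dataset.rois[roi].n_voxels, size=n, replace=False))
        cols = choices[key]
        new_patterns[key] = {c: m[:, cols].copy() for c, m in conds.items()}
    new_rois = {name: ROIInfo(info.name, info.network, n, info.latent_dim)
                for name, info in dataset.rois.items()}
    return PatternDataset(
        subjects=list(dataset.subjects), rois=new_rois,
        image_ids=list(dataset.image_ids), categories=dict(dataset.categories),
        patterns=new_patterns,
    )


def write_rdm(rdm: RDM, path: str | Path) -> None:
    """Write as TSV with ``cond:image_id`` column labels."""
    labels = [f"{c}:{i}" for c, i in rdm.labels()]
    df = pd.DataFrame(rdm.values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_rdm(path: str | Path, categories: Mapping[str, str] | None = None,
             kind: str = "rdm") -> RDM:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = [tuple(c.split(":", 1)) for c in df.columns]
    n = len(labels) // 3
    image_ids = [i for _, i in labels[:n]]
    return RDM(values=df.to_numpy(), image_ids=image_ids,
               categories=dict(categories or {}), kind=kind)
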