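"""First-order representational contrasts and non-metric MDS embedding.

Three families of contrasts probe how disambiguation reshapes the neural
code, all computed per subject on the condition-blocked RDM/RSM and tested
across subjects with paired Wilcoxon signed-rank tests:

* within-condition distinctness: mean lower-triangle dissimilarity of the
  post-post block vs the pre-pre block (are images encoded more distinctly
  after disambiguation?);
* shift toward the prior: mean same-image post-gray similarity vs pre-gray
  similarity (block diagonals of the RSM);
* prior vs sensory input: mean same-image post-gray vs pre-post similarity
  (is the disambiguated Mooney closer to its gray-scale source than to its
  physically identical pre-disambiguation self?).

A category-information statistic (between-category minus within-category mean
dissimilarity) and the disambiguation-vs-repetition control (2x2
condition x set repeated-measures interaction) complete the module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.manifold import MDS

from . import stats_core
from .rdm_core import (
    RDM,
    between_condition_diagonal_mean,
    rdm_to_rsm,
    within_condition_mean,
)
from .stats_core import StatResult

logger = logging.getLogger(__name__)

__all__ = [
    "ContrastSpec",
    "MDSSolution",
    "subject_summaries",
    "run_contrast",
    "category_information",
    "disambiguation_vs_repetition",
    "mds_embed",
    "DEFAULT_CONTRASTS",
]


@dataclass(frozen=True)
class ContrastSpec:
    """A paired contrast between two scalar RDM/RSM summaries.

    ``kind`` selects the summary: "within" compares mean lower-triangle
    dissimilarities of two within-condition blocks (comparands are condition
    names); "between-diagonal" compares mean same-image similarities of two
    between-condition block diagonals (comparands are condition pairs).
    ``subset`` restricts images per subject: None (all images),
    "disambiguation" or "repetition".
    """

    name: str
    kind: str  # "within" | "between-diagonal"
    comparand_a: tuple[str, ...] | str
    comparand_b: tuple[str, ...] | str
    subset: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("within", "between-diagonal"):
            raise ValueError(f"unknown contrast kind {self.kind!r}")


DEFAULT_CONTRASTS: tuple[ContrastSpec, ...] = (
    ContrastSpec("post_vs_pre_distinctness", "within", "post", "pre"),
    ContrastSpec("postgray_vs_pregray_similarity", "between-diagonal",
                 ("post", "gray"), ("pre", "gray")),
    ContrastSpec("postgray_vs_prepost_similarity", "between-diagonal",
                 ("post", "gray"), ("pre", "post")),
)


def _summary(rdm: RDM, kind: str, comparand, images=None) -> float:
    if kind == "within":
        return within_condition_mean(rdm, comparand, images=images)
    rsm = rdm_to_rsm(rdm)
    return between_condition_diagonal_mean(rsm, *comparand, images=images)


def subject_summaries(
    rdms: dict[str, RDM],
    spec: ContrastSpec,
    subsets: dict[str, list[str]] | None = None,
    min_images: int = 2,
) -> pd.DataFrame:
    """The two scalar summaries of a contrast, one row per usable subject.

    Subjects whose image subset has fewer than ``min_images`` entries are
    excluded with a log record (they cannot contribute a within-block mean).
    """
    rows = []
    for subject, rdm in rdms.items():
        images = None
        if spec.subset is not None:
            images = (subsets or {}).get(subject, [])
            if len(images) < min_images:
                logger.info("contrast %s: excluding %s (only %d images in %s set)",
                            spec.name, subject, len(images), spec.subset)
                continue
        rows.append({
            "subject": subject,
            "a": _summary(rdm, spec.kind, spec.comparand_a, images),
            "b": _summary(rdm, spec.kind, spec.comparand_b, images),
            "n_images": len(images) if images is not None else rdm.n_images,
        })
    return pd.DataFrame(rows)


def run_contrast(
    rdms: dict[str, RDM],
    spec: ContrastSpec,
    subsets: dict[str, list[str]] | None = None,
) -> tuple[StatResult, pd.DataFrame]:
    """Paired Wilcoxon signed-rank test of a contrast across subjects.

    Returns the raw (uncorrected) test result plus the per-subject summary
    table; FDR across the ROI family is applied by the caller.
    """
    table = subject_summaries(rdms, spec, subsets=subsets)
    if table.empty:
        raise ValueError(f"contrast {spec.name}: no usable subjects")
    diffs = table["a"].to_numpy() - table["b"].to_numpy()
    if (diffs == 0).all():
        # no subject shows any difference: report the null-centered statistic
        n = diffs.size
        res = StatResult(name="W", statistic=n * (n + 1) / 4, df=None, p=1.0,
                         label=spec.name, n=n)
    else:
        res = stats_core.wilcoxon_signed_rank(
            table["a"].to_numpy(), table["b"].to_numpy(), label=spec.name)
    res.effect_size = float((table["a"] - table["b"]).mean())
    res.effect_size_name = "mean_difference"
    return res, table


def category_information(rdm: RDM, cond: str,
                         categories: dict[str, str] | None = None) -> float:
    """Signed category-information score for one within-condition block.

    Mean dissimilarity of different-category image pairs minus mean
    dissimilarity of same-category non-identical pairs; positive values mean
    the two categories occupy separable regions of pattern space.
    """
    categories = categories or rdm.categories
    if not categories:
        raise ValueError("no category labels available")
    labels = np.array([categories[i] for i in rdm.image_ids])
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 categories, got {list(uniq)}")
    counts = {c: int((labels == c).sum()) for c in uniq}
    small = [c for c, k in counts.items() if k < 2]
    if small:
        raise ValueError(f"category with fewer than 2 images: {small}")
    blk = rdm.block(cond, cond)
    same = labels[:, None] == labels[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    within = blk[same & off].mean()
    between = blk[~same].mean()
    return float(between - within)


def category_information_test(
    rdms: dict[str, RDM], cond: str,
    categories: dict[str, str] | None = None,
) -> tuple[StatResult, pd.DataFrame]:
    """Group-level one-sample Wilcoxon test of the category score against 0."""
    rows = [{"subject": s, "score": category_information(r, cond, categories)}
            for s, r in rdms.items()]
    table = pd.DataFrame(rows)
    res = stats_core.wilcoxon_signed_rank(
        table["score"].to_numpy(), label=f"category_information_{cond}")
    res.effect_size = float(table["score"].mean())
    res.effect_size_name = "mean_score"
    return res, table


def disambiguation_vs_repetition(
    rdms: dict[str, RDM],
    subsets: dict[str, dict[str, list[str]]],
    min_images: int = 2,
) -> dict[str, dict[str, object]]:
    """Condition x set interaction controlling for repetition.

    For each of the three contrast families, each subject contributes four
    cells: the two comparand summaries evaluated on the disambiguation-set
    images and on the repetition-set images.  A 2x2 repeated-measures ANOVA
    (condition x set) tests whether the disambiguation effect exceeds what
    mere repetition produces.  Subjects lacking ``min_images`` images in
    either set are excluded and logged.
    """
    usable = [s for s in rdms
              if len(subsets.get("disambiguation", {}).get(s, [])) >= min_images
              and len(subsets.get("repetition", {}).get(s, [])) >= min_images]
    excluded = sorted(set(rdms) - set(usable))
    if excluded:
        logger.info("disambiguation_vs_repetition: excluding %d subjects "
                    "with too few images in a set: %s", len(excluded), excluded)
    if len(usable) < 2:
        raise ValueError("fewer than 2 subjects with enough images in both sets")
    out: dict[str, dict[str, object]] = {}
    for spec in DEFAULT_CONTRASTS:
        rows = []
        for subject in usable:
            for set_name in ("disambiguation", "repetition"):
                images = subsets[set_name][subject]
                for level, comparand in (("a", spec.comparand_a), ("b", spec.comparand_b)):
                    rows.append({
                        "subject": subject, "set": set_name, "condition": level,
                        "value": _summary(rdms[subject], spec.kind, comparand, images),
                    })
        table = pd.DataFrame(rows)
        effects = stats_core.rm_anova(table, dv="value", within=["condition", "set"],
                                      subject="subject", family=spec.name)
        interaction = next(e for e in effects if "*" in e.label)
        out[spec.name] = {"effects": effects, "interaction": interaction,
                          "table": table, "n_subjects": len(usable)}
    return out


@dataclass
class MDSSolution:
    """A non-metric MDS embedding with its goodness-of-fit."""

    coordinates: np.ndarray  # (n_points, n_dims)
    stress: float            # stress-1 (normalized Kruskal stress)
    r_squared: float         # squared Pearson r of embedded vs original distances
    n_dims: int
    seed: int | None
    restarts: int


def _embedding_r_squared(coords: np.ndarray, dissim: np.ndarray) -> float:
    embedded = pdist(coords)
    original = squareform(dissim, checks=False)
    if original.std() == 0:
        # equidistant input: exactly embeddable iff the embedding is
        # (numerically) equidistant too, in which case the fit is perfect
        rel_spread = embedded.std() / max(embedded.mean(), 1e-300)
        return 1.0 if rel_spread < 1e-3 else 0.0
    if embedded.std() == 0:
        return 0.0
    return float(pearsonr(embedded, original)[0] ** 2)


def mds_embed(dissim: np.ndarray, n_dims: int, seed: int | None = 0,
              restarts: int = 1, max_iter: int = 300, eps: float = 1e-6) -> MDSSolution:
    """Non-metric MDS (stress-1 criterion) of a symmetric dissimilarity matrix.

    The first start initializes from classical (Torgerson) scaling, which for
    near-Euclidean inputs converges almost immediately to a low-stress
    solution; the remaining ``restarts - 1`` starts use seeded random
    configurations as insurance against local minima.  The lowest-stress
    solution is kept.  Deterministic given ``seed``.
    """
    dissim = np.asarray(dissim, dtype=float)
    if dissim.ndim != 2 or dissim.shape[0] != dissim.shape[1]:
        raise ValueError(f"dissimilarity matrix must be square, got {dissim.shape}")
    if not np.allclose(dissim, dissim.T, atol=1e-8):
        raise ValueError("dissimilarity matrix is not symmetric")
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    best: MDSSolution | None = None
    for start in range(max(1, restarts)):
        kwargs = dict(
            n_components=n_dims, metric_mds=False, n_init=1,
            max_iter=max_iter, eps=eps, metric="precomputed",
            normalized_stress=True,
        )
        if start == 0:
            model = MDS(init="classical_mds", **kwargs)
        else:
            rs = None if seed is None else (seed * 1000 + start) % (2 ** 31)
            model = MDS(init="random", random_state=rs, **kwargs)
        coords = model.fit_transform(dissim)
        stress = float(model.stress_)
        if best is None or stress < best.stress:
            best = MDSSolution(
                coordinates=coords, stress=stress,
                r_squared=_embedding_r_squared(coords, dissim),
                n_dims=n_dims, seed=seed, restarts=max(1, restarts),
            )
    assert best is not None
    return best
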