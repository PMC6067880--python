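"""Synthetic voxel patterns and behavior for the Mooney disambiguation design.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any neuroimaging data:

* 19 subjects x 33 images (17 natural, 16 manmade) x 3 conditions.
* Gray-scale patterns are noisy reads of image-specific prototypes that live
  in a low-dimensional latent subspace per ROI (exact control of
  representational dimensionality), mapped to voxel space by a random
  orthonormal map.
* Pre-disambiguation Mooney patterns mix a weak image-specific component with
  a shared component (weight ``pre_clustering``) that collapses pre patterns
  together, reproducing the clustered pre-disambiguation geometry.
* Post-disambiguation patterns are pulled toward the gray prototype with
  weight ``prior_shift`` and retain the pre-disambiguation component
  otherwise, so the prior's impact and the preservation of the old code are
  both tunable.
* ROIs within a network share leading latent dimensions, giving networks a
  similar representational format (second-order structure).
* Recognition behavior is a two-component easy/hard mixture over images,
  reproducing the bimodal pre-disambiguation recognition-rate distribution.

Pattern units are arbitrary: correlation distance is scale invariant, so no
calibration to BOLD units is attempted.  Everything is deterministic given
``SimulationConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import expit, logit

from .rdm_core import CONDITIONS, PatternDataset, ROIInfo, canonical_image_order

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_rois",
    "generate_patterns",
    "generate_behavior",
    "generate_latent_rdm",
    "write_dataset",
]


# Position of each network along the macroscale cortical hierarchy, from
# early visual cortex (0) to the default-mode network (1).
NETWORK_HIERARCHY: dict[str, float] = {
    "Visual": 0.0,
    "LOC": 0.2,
    "FG": 0.4,
    "FPN-parietal": 0.6,
    "FPN-frontal": 0.8,
    "DMN": 1.0,
}


def default_rois() -> list[ROIInfo]:
    """The default ROI set: one entry per region the analyses compare.

    Latent dimensionality rises from early visual cortex toward FG, the
    frontoparietal network and the DMN, mirroring the hierarchy the
    dimensionality analysis is designed to detect.
    """
    return [
        ROIInfo("V1", "Visual", 250, 3),
        ROIInfo("V2", "Visual", 220, 3),
        ROIInfo("V3", "Visual", 200, 3),
        ROIInfo("LOC", "LOC", 180, 3),
        ROIInfo("FG", "FG", 160, 5),
        ROIInfo("FPN_frontal", "FPN-frontal", 150, 5),
        ROIInfo("FPN_parietal", "FPN-parietal", 150, 5),
        ROIInfo("MPFC", "DMN", 140, 5),
        ROIInfo("PCC", "DMN", 140, 5),
        ROIInfo("ParLat", "DMN", 140, 4),
    ]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    The sample sizes (19 subjects, 33 images with 17 natural, 6 presentations
    per stage) match the study design; the generative weights are the
    simulator's own knobs, with defaults chosen so the cohort shows the
    qualitative effects the analyses test for: a strong prior shift, clustered
    pre-disambiguation patterns, and bimodal pre-disambiguation recognition
    averaging ~43% pre and ~86% post.
    """

    n_subjects: int = 19
    n_images: int = 33
    n_natural: int = 17
    rois: list[ROIInfo] = field(default_factory=default_rois)
    prior_shift: float = 0.8        # lambda: weight pulling post toward gray prototype
    prior_shift_easy: float | None = 0.4  # lambda for pre-recognizable images (None -> same)
    pre_clustering: float = 0.6     # gamma: shared-component weight in pre patterns
    noise_sd: float = 0.5           # sigma, in (arbitrary) pattern units
    category_separation: float = 0.5  # kappa: latent distance between category centroids
    mooney_gray_overlap: float = 0.3  # latent correlation of Mooney component with prototype
    network_coupling: float = 0.6   # shared latent weight for ROIs of the same network
    network_distinctness: float = 0.45  # network-specific latent weight vs hierarchy gradient
    preserve_pre_in_post: bool = True  # False regenerates the post residual independently
    p_recognize_pre_hard: float = 0.12
    p_recognize_pre_easy: float = 0.85
    p_recognize_post: float = 0.86
    frac_pre_easy: float = 0.42
    subject_sd: float = 0.5         # per-subject recognition jitter (logit scale)
    verbal_scale_pre: float = 0.8   # verbal-correct probability = scale * recognition prob
    verbal_scale_post: float = 1.0
    n_presentations: int = 6
    seed: int = 0

    def validate(self) -> None:
        def _prob(name: str) -> None:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

        for name in ("prior_shift", "pre_clustering", "frac_pre_easy",
                     "p_recognize_pre_hard", "p_recognize_pre_easy",
                     "p_recognize_post", "mooney_gray_overlap",
                     "network_coupling", "network_distinctness",
                     "verbal_scale_pre", "verbal_scale_post"):
            _prob(name)
        if self.prior_shift_easy is not None and not 0 <= self.prior_shift_easy <= 1:
            raise ValueError(f"prior_shift_easy must lie in [0, 1], got {self.prior_shift_easy}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.category_separation < 0:
            raise ValueError(f"category_separation must be >= 0, got {self.category_separation}")
        if self.subject_sd < 0:
            raise ValueError(f"subject_sd must be >= 0, got {self.subject_sd}")
        if not 0 < self.n_natural <= self.n_images:
            raise ValueError(f"n_natural must lie in 1..n_images, got {self.n_natural}")
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.n_presentations < 1:
            raise ValueError(f"n_presentations must be >= 1, got {self.n_presentations}")
        if not self.rois:
            raise ValueError("rois must be non-empty")
        for roi in self.rois:
            k = roi.latent_dim
            if k is None or not 1 <= k <= self.n_images - 1:
                raise ValueError(
                    f"rois: latent_dim of {roi.name!r} must lie in 1..n_images-1, got {k}")
            if roi.n_voxels < max(2, k):
                raise ValueError(f"rois: n_voxels of {roi.name!r} too small ({roi.n_voxels})")

    def image_table(self) -> pd.DataFrame:
        ids = [f"img{i:02d}" for i in range(1, self.n_images + 1)]
        cats = ["natural"] * self.n_natural + ["manmade"] * (self.n_images - self.n_natural)
        return pd.DataFrame({"image_id": ids, "category": cats})


@dataclass
class GroundTruth:
    """Latent quantities the generator drew; reproducible from (config, seed)."""

    config: SimulationConfig
    gray_prototypes: dict[str, np.ndarray]      # roi -> (n_images, n_voxels)
    mooney_components: dict[str, np.ndarray]    # roi -> (n_images, n_voxels)
    shared_components: dict[str, np.ndarray]    # roi -> (n_voxels,)
    image_easy: np.ndarray                      # (n_images,) bool, easy pre-recognition
    p_recognize_pre: np.ndarray                 # (n_images,) realized pre probabilities
    p_recognize_post: np.ndarray                # (n_images,) realized post probabilities

    def summary(self) -> dict:
        return {
            "n_images": int(self.image_easy.size),
            "n_easy_pre": int(self.image_easy.sum()),
            "mean_p_pre": float(self.p_recognize_pre.mean()),
            "mean_p_post": float(self.p_recognize_post.mean()),
            "rois": [asdict(r) for r in self.config.rois],
            "seed": self.config.seed,
        }


def _orthonormal_map(rng: np.random.Generator, k: int, n_voxels: int) -> np.ndarray:
    """Random k x n_voxels map with orthonormal rows (QR of a Gaussian)."""
    q, _ = np.linalg.qr(rng.standard_normal((n_voxels, k)))
    return q[:, :k].T


def generate_patterns(config: SimulationConfig) -> tuple[PatternDataset, GroundTruth]:
    """Draw the full synthetic cohort of voxel patterns.

    Per ROI, gray prototypes are latent points in a ``latent_dim``-dimensional
    subspace (leading dimensions shared within a network) with category
    centroids separated by ``category_separation``, mapped to voxel space by a
    random orthonormal map.  Then per subject:

    * ``gray = prototype + noise``
    * ``pre  = (1-gamma) * mooney_component + gamma * shared + noise``
    * ``post = lambda_i * prototype + (1-lambda_i) * pre_component + noise``

    where the Mooney component correlates ``mooney_gray_overlap`` with the
    prototype in latent space, and ``lambda_i`` is ``prior_shift`` for
    pre-hard images and ``prior_shift_easy`` for pre-easy ones.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    images = config.image_table()
    order = canonical_image_order(images["image_id"], dict(zip(images["image_id"], images["category"])))
    categories = dict(zip(images["image_id"], images["category"]))
    cat_sign = np.array([1.0 if categories[i] == "natural" else -1.0 for i in order])
    n_img = config.n_images

    # Easy/hard mixture over images drives both behavior and the per-image
    # prior-shift weight (hard images are the ones disambiguation rescues).
    n_easy = int(round(config.frac_pre_easy * n_img))
    easy_idx = rng.choice(n_img, size=n_easy, replace=False)
    image_easy = np.zeros(n_img, dtype=bool)
    image_easy[easy_idx] = True

    lam_easy = config.prior_shift if config.prior_shift_easy is None else config.prior_shift_easy
    lam = np.where(image_easy, lam_easy, config.prior_shift)

    k_max = max(r.latent_dim for r in config.rois)
    networks = sorted({r.network for r in config.rois})
    # Shared latent geometry per network.  Networks sit on a 1-D cortical
    # hierarchy; their latent configurations are mixtures of two common
    # geometries with smoothly varying weights, so representational-format
    # distance grows with hierarchy separation and the second-order geometry
    # is close to planar, plus a network-specific part.
    delta = config.network_distinctness
    def _net_latents() -> dict[str, np.ndarray]:
        common_a = rng.standard_normal((n_img, k_max))
        common_b = rng.standard_normal((n_img, k_max))
        out = {}
        for net in networks:
            theta = NETWORK_HIERARCHY.get(net, 0.5) * np.pi / 2
            shared = np.cos(theta) * common_a + np.sin(theta) * common_b
            out[net] = (np.sqrt(1 - delta ** 2) * shared
                        + delta * rng.standard_normal((n_img, k_max)))
        return out
    net_latent = _net_latents()
    net_latent_mooney = _net_latents()

    gray_prototypes: dict[str, np.ndarray] = {}
    mooney_components: dict[str, np.ndarray] = {}
    shared_components: dict[str, np.ndarray] = {}
    roi_maps: dict[str, np.ndarray] = {}
    for roi in config.rois:
        k, v = roi.latent_dim, roi.n_voxels
        c = config.network_coupling
        own = rng.standard_normal((n_img, k))
        latent = np.sqrt(c) * net_latent[roi.network][:, :k] + np.sqrt(1 - c) * own
        latent = latent.copy()
        latent[:, 0] += cat_sign * config.category_separation / 2.0
        own_m = rng.standard_normal((n_img, k))
        latent_m = np.sqrt(c) * net_latent_mooney[roi.network][:, :k] + np.sqrt(1 - c) * own_m
        a = config.mooney_gray_overlap
        mooney_latent = a * latent + np.sqrt(1 - a ** 2) * latent_m
        # Unrecognized two-tone images span fewer feature axes than recognized
        # ones: restrict the pre component to the leading ceil(k/2) latent
        # dimensions (rescaled to keep per-voxel variance), so estimated
        # dimensionality rises after disambiguation.
        k_pre = max(1, -(-k // 2))
        mooney_latent = mooney_latent.copy()
        mooney_latent[:, k_pre:] = 0.0
        mooney_latent *= np.sqrt(k / k_pre)
        # scale so each component has ~unit per-voxel variance regardless of k
        Q = _orthonormal_map(rng, k, v) * np.sqrt(v / k)
        gray_prototypes[roi.name] = latent @ Q
        mooney_components[roi.name] = mooney_latent @ Q
        shared_components[roi.name] = rng.standard_normal(v)
        roi_maps[roi.name] = Q

    subjects = [f"sub{i:02d}" for i in range(1, config.n_subjects + 1)]
    gamma = config.pre_clustering
    patterns: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for subject in subjects:
        for roi in config.rois:
            proto = gray_prototypes[roi.name]
            mooney = mooney_components[roi.name]
            shared = shared_components[roi.name]
            pre_clean = (1 - gamma) * mooney + gamma * shared[None, :]
            if config.preserve_pre_in_post:
                post_residual = pre_clean
            else:
                k, v = roi.latent_dim, roi.n_voxels
                indep = rng.standard_normal((n_img, k)) @ roi_maps[roi.name]
                post_residual = (1 - gamma) * indep + gamma * shared[None, :]
            post_clean = lam[:, None] * proto + (1 - lam[:, None]) * post_residual
            noise = lambda: config.noise_sd * rng.standard_normal(proto.shape)  # noqa: E731
            patterns[(subject, roi.name)] = {
                "gray": proto + noise(),
                "pre": pre_clean + noise(),
                "post": post_clean + noise(),
            }

    p_pre = np.where(image_easy, config.p_recognize_pre_easy, config.p_recognize_pre_hard)
    p_post = np.full(n_img, config.p_recognize_post)
    dataset = PatternDataset(
        subjects=subjects,
        rois={r.name: r for r in config.rois},
        image_ids=order,
        categories=categories,
        patterns=patterns,
    )
    dataset.validate()
    truth = GroundTruth(
        config=config, gray_prototypes=gray_prototypes,
        mooney_components=mooney_components, shared_components=shared_components,
        image_easy=image_easy, p_recognize_pre=p_pre, p_recognize_post=p_post,
    )
    return dataset, truth


def _clip_prob(p: np.ndarray) -> np.ndarray:
    return np.clip(p, 1e-9, 1 - 1e-9)


def generate_behavior(config: SimulationConfig, truth: GroundTruth) -> pd.DataFrame:
    """Simulate per-presentation recognition and per-stage verbal reports.

    Per subject x image: ``n_presentations`` Bernoulli recognition responses
    per stage at the image's realized probability shifted by a per-subject
    logit offset, and one verbal outcome per stage whose success probability
    is the stage recognition probability scaled by ``verbal_scale_*``.
    Returns a tidy table (subject, image_id, stage, presentation, recognized,
    verbal_correct), with verbal_correct recorded on presentation 1 only.
    """
    if truth.config is not config and truth.config != config:
        raise ValueError("truth was generated from a different config")
    if truth.p_recognize_pre.size != config.n_images:
        raise ValueError(
            f"truth has {truth.p_recognize_pre.size} images, config expects {config.n_images}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    images = config.image_table()
    ids = images["image_id"].tolist()
    subjects = [f"sub{i:02d}" for i in range(1, config.n_subjects + 1)]
    offsets = config.subject_sd * rng.standard_normal(config.n_subjects)
    rows = []
    for s_i, subject in enumerate(subjects):
        p_pre = _clip_prob(expit(logit(_clip_prob(truth.p_recognize_pre)) + offsets[s_i]))
        p_post = _clip_prob(expit(logit(_clip_prob(truth.p_recognize_post)) + offsets[s_i]))
        for stage, p_stage, v_scale in (
            ("pre", p_pre, config.verbal_scale_pre),
            ("post", p_post, config.verbal_scale_post),
        ):
            resp = rng.random((config.n_images, config.n_presentations)) < p_stage[:, None]
            verbal = rng.random(config.n_images) < v_scale * p_stage
            for i_i, image_id in enumerate(ids):
                for pres in range(1, config.n_presentations + 1):
                    rows.append({
                        "subject": subject, "image_id": image_id, "stage": stage,
                        "presentation": pres, "recognized": bool(resp[i_i, pres - 1]),
                        "verbal_correct": bool(verbal[i_i]) if pres == 1 else None,
                    })
    return pd.DataFrame(rows)


def generate_latent_rdm(n_points: int, k: int, seed: int,
                        scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean distances among points drawn in exactly k dimensions.

    Returns ``(points, matrix)``; the matrix is symmetric with zero diagonal.
    Used as a fixture with known intrinsic dimensionality for the MDS-based
    dimensionality estimator.
    """
    if not 1 <= k <= n_points - 1:
        raise ValueError(f"k must lie in 1..n_points-1, got {k}")
    rng = np.random.default_rng(seed)
    points = scale * rng.standard_normal((n_points, k))
    return points, squareform(pdist(points))


def write_dataset(dataset: PatternDataset, truth: GroundTruth,
                  behavior: pd.DataFrame, outdir: str | Path) -> None:
    """Write the canonical on-disk layout consumed by the pipeline.

    ``patterns/<subject>/<roi>/<condition>.tsv`` (rows keyed by image_id,
    columns are voxel indices), ``images.csv``, ``behavior.csv`` and a
    ``truth.json`` summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (subject, roi), conds in dataset.patterns.items():
        d = outdir / "patterns" / subject / roi
        d.mkdir(parents=True, exist_ok=True)
        for cond in CONDITIONS:
            df = pd.DataFrame(conds[cond], index=dataset.image_ids)
            df.index.name = "image_id"
            df.to_csv(d / f"{cond}.tsv", sep="\t", float_format="%.8g")
    images = pd.DataFrame({
        "image_id": dataset.image_ids,
        "category": [dataset.categories[i] for i in dataset.image_ids],
    })
    rois = pd.DataFrame([asdict(info) for info in dataset.rois.values()])
    images.to_csv(outdir / "images.csv", index=False)
    rois.to_csv(outdir / "rois.csv", index=False)
    behavior.to_csv(outdir / "behavior.csv", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.summary(), fh, indent=2)
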