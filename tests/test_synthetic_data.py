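import dataclasses

import numpy as np
import pytest

from mooneyrsa import (
    ROIInfo,
    SimulationConfig,
    classify_images,
    compute_rdm,
    generate_behavior,
    generate_latent_rdm,
    generate_patterns,
    rdm_to_rsm,
    between_condition_diagonal_mean,
    within_condition_mean,
)
from mooneyrsa.first_order_rsa import category_information


def one_roi_config(**overrides):
    defaults = dict(
        n_subjects=4,
        rois=[ROIInfo("roi", "Visual", 100, 4)],
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestGeneratePatterns:
    def test_shape_contract(self):
        cfg = SimulationConfig(n_subjects=19, n_images=33,
                               rois=[ROIInfo("roi", "Visual", 200, 4)], seed=0)
        dataset, _ = generate_patterns(cfg)
        assert len(dataset.subjects) == 19
        assert len(dataset.patterns) == 19
        for conds in dataset.patterns.values():
            for cond in ("pre", "post", "gray"):
                assert conds[cond].shape == (33, 200)

    def test_seed_determinism_is_bit_identical(self):
        cfg = one_roi_config()
        ds1, t1 = generate_patterns(cfg)
        ds2, t2 = generate_patterns(one_roi_config())
        for key in ds1.patterns:
            for cond in ("pre", "post", "gray"):
                assert np.array_equal(ds1.patterns[key][cond], ds2.patterns[key][cond])
        assert np.array_equal(t1.image_easy, t2.image_easy)

    def test_noise_free_full_prior_shift_copies_gray(self):
        cfg = one_roi_config(prior_shift=1.0, prior_shift_easy=1.0, noise_sd=0.0)
        dataset, _ = generate_patterns(cfg)
        for conds in dataset.patterns.values():
            assert np.allclose(conds["post"], conds["gray"])
            rdm = compute_rdm(conds, dataset.image_ids, dataset.categories)
            rsm = rdm_to_rsm(rdm)
            assert np.allclose(np.diag(rsm.block("post", "gray")), 1.0)

    @pytest.mark.parametrize("field,value", [
        ("prior_shift", 1.5),
        ("noise_sd", -0.1),
        ("frac_pre_easy", -0.2),
        ("n_natural", 40),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = one_roi_config()
        with pytest.raises(ValueError, match=field):
            dataclasses.replace(cfg, **{field: value}).validate()

    def test_latent_dim_out_of_range_rejected(self):
        cfg = one_roi_config(rois=[ROIInfo("roi", "Visual", 100, 40)])
        with pytest.raises(ValueError, match="latent_dim"):
            cfg.validate()

    def test_prior_shift_monotonically_increases_post_gray_similarity(self):
        means = []
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            vals = []
            for seed in (1, 2, 3):
                cfg = one_roi_config(prior_shift=lam, prior_shift_easy=lam, seed=seed)
                dataset, _ = generate_patterns(cfg)
                for conds in dataset.patterns.values():
                    rsm = rdm_to_rsm(compute_rdm(conds, dataset.image_ids,
                                                 dataset.categories))
                    vals.append(between_condition_diagonal_mean(rsm, "post", "gray"))
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))

    def test_pre_clustering_monotonically_reduces_pre_distinctness(self):
        means = []
        for gamma in (0.0, 0.3, 0.6, 0.9):
            vals = []
            for seed in (1, 2, 3):
                cfg = one_roi_config(pre_clustering=gamma, seed=seed)
                dataset, _ = generate_patterns(cfg)
                for conds in dataset.patterns.values():
                    rdm = compute_rdm(conds, dataset.image_ids, dataset.categories)
                    vals.append(within_condition_mean(rdm, "pre"))
            means.append(np.mean(vals))
        assert all(b < a for a, b in zip(means, means[1:]))

    def test_zero_category_separation_gives_no_category_information(self):
        scores = []
        for seed in range(6):
            cfg = one_roi_config(category_separation=0.0, n_subjects=3, seed=seed)
            dataset, _ = generate_patterns(cfg)
            for conds in dataset.patterns.values():
                rdm = compute_rdm(conds, dataset.image_ids, dataset.categories)
                scores.append(category_information(rdm, "gray"))
        scores = np.asarray(scores)
        sem = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * sem + 1e-9


class TestGenerateBehavior:
    def test_degenerate_post_probability(self):
        cfg = one_roi_config(p_recognize_post=1.0, subject_sd=0.0)
        _, truth = generate_patterns(cfg)
        table = generate_behavior(cfg, truth)
        assert table.loc[table.stage == "post", "recognized"].all()

    def test_all_hard_images_classified_pre_not_recognized(self):
        cfg = one_roi_config(frac_pre_easy=0.0, p_recognize_pre_hard=0.0,
                             subject_sd=0.0)
        _, truth = generate_patterns(cfg)
        table = generate_behavior(cfg, truth)
        cls = classify_images(table)
        assert (cls["pre_status"] == "not-recognized").all()

    def test_empirical_rate_matches_mixture_mean(self):
        # >10k pre trials; binomial oracle for the configured mixture mean
        cfg = one_roi_config(n_subjects=60, subject_sd=0.0, seed=21)
        _, truth = generate_patterns(cfg)
        table = generate_behavior(cfg, truth)
        pre = table[table.stage == "pre"]["recognized"]
        p_mix = truth.p_recognize_pre.mean()
        se = np.sqrt(p_mix * (1 - p_mix) / len(pre))
        assert abs(pre.mean() - p_mix) < 3 * se

    def test_mismatched_truth_rejected(self):
        cfg = one_roi_config()
        _, truth = generate_patterns(cfg)
        other = one_roi_config(n_images=20, n_natural=10)
        with pytest.raises(ValueError, match="config|images"):
            generate_behavior(other, truth)


class TestGenerateLatentRdm:
    def test_symmetry_zero_diagonal(self):
        _, mat = generate_latent_rdm(10, 3, seed=0)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 0.0)

    def test_one_dimensional_points_are_collinear(self):
        _, mat = generate_latent_rdm(3, 1, seed=4)
        d = sorted([mat[0, 1], mat[0, 2], mat[1, 2]])
        assert d[2] == pytest.approx(d[0] + d[1], abs=1e-10)

    def test_classical_scaling_rank_recovers_k(self):
        _, mat = generate_latent_rdm(33, 5, seed=2)
        d2 = mat ** 2
        J = np.eye(33) - np.ones((33, 33)) / 33
        B = -0.5 * J @ d2 @ J
        eigvals = np.sort(np.linalg.eigvalsh(B))[::-1]
        assert (eigvals[:5] > 1e-8).all()
        assert np.allclose(eigvals[5:], 0.0, atol=1e-8)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError, match="k"):
            generate_latent_rdm(5, 5, seed=0)
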