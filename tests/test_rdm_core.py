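import numpy as np
import pytest
from scipy.stats import pearsonr

from mooneyrsa import rdm_core
from mooneyrsa.rdm_core import (
    RDM,
    between_condition_diagonal_mean,
    compute_rdm,
    fisher_z,
    group_average,
    rdm_to_rsm,
    rsm_to_rdm,
    subsample_voxels,
    within_condition_mean,
)


def _toy_patterns(rng, n_images=3, n_voxels=4):
    ids = [f"img{i}" for i in range(n_images)]
    cats = {i: ("natural" if k < 2 else "manmade") for k, i in enumerate(ids)}
    patterns = {c: rng.normal(size=(n_images, n_voxels)) for c in rdm_core.CONDITIONS}
    return patterns, ids, cats


class TestComputeRDM:
    def test_perfectly_correlated_rows_have_zero_distance(self):
        patterns = {
            "pre": np.array([[1.0, 2, 3], [2, 4, 6]]),
            "post": np.array([[1.0, 2, 3], [3, 2, 1]]),
            "gray": np.array([[1.0, 5, 3], [2, 2, 9]]),
        }
        rdm = compute_rdm(patterns, ["a", "b"])
        # pre image a vs pre image b: r = 1 -> d = 0
        assert rdm.block("pre", "pre")[0, 1] == pytest.approx(0.0, abs=1e-12)
        # post a vs post b: r = -1 -> d = 2
        assert rdm.block("post", "post")[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_elementwise_correlation_oracle(self, rng):
        patterns, ids, cats = _toy_patterns(rng)
        rdm = compute_rdm(patterns, ids, cats)
        order = rdm.image_ids
        stacked = np.vstack([
            np.array([patterns[c][ids.index(i)] for i in order])
            for c in rdm_core.CONDITIONS
        ])
        for i in range(9):
            for j in range(9):
                expected = 0.0 if i == j else 1 - pearsonr(stacked[i], stacked[j])[0]
                assert rdm.values[i, j] == pytest.approx(expected, abs=1e-10)
        rdm.validate()

    def test_zero_variance_row_names_condition_and_image(self, rng):
        patterns, ids, cats = _toy_patterns(rng)
        patterns["post"][1] = 7.0
        with pytest.raises(ValueError, match="post.*img1"):
            compute_rdm(patterns, ids, cats)

    def test_correlation_invariance_to_shift_and_scale(self, rng):
        patterns, ids, cats = _toy_patterns(rng)
        base = compute_rdm(patterns, ids, cats)
        patterns["gray"] = patterns["gray"] * 3.5 + 10.0
        assert np.allclose(compute_rdm(patterns, ids, cats).values, base.values)

    def test_natural_images_come_first(self, rng):
        patterns, ids, cats = _toy_patterns(rng)
        cats = {"img0": "manmade", "img1": "natural", "img2": "natural"}
        rdm = compute_rdm(patterns, ids, cats)
        assert rdm.image_ids == ["img1", "img2", "img0"]


class TestBlocks:
    def test_within_block_diagonal_is_zero(self, small_rdms):
        rdm = next(iter(small_rdms.values()))
        assert np.allclose(np.diag(rdm.block("pre", "pre")), 0.0)

    def test_between_block_diagonal_is_same_image_correlation(self, rng):
        patterns, ids, cats = _toy_patterns(rng)
        rsm = rdm_to_rsm(compute_rdm(patterns, ids, cats))
        blk = rsm.block("pre", "gray")
        for row, image in enumerate(rsm.image_ids):
            r = pearsonr(patterns["pre"][ids.index(image)],
                         patterns["gray"][ids.index(image)])[0]
            assert blk[row, row] == pytest.approx(r, abs=1e-10)

    def test_unknown_condition_rejected(self, small_rdms):
        rdm = next(iter(small_rdms.values()))
        with pytest.raises(ValueError, match="unknown condition"):
            rdm.block("pre", "mooney")


class TestSummaries:
    def _manual_rdm(self, block_values):
        n = block_values.shape[0]
        values = np.zeros((3 * n, 3 * n))
        values[:n, :n] = block_values
        return RDM(values=values, image_ids=[f"i{k}" for k in range(n)])

    def test_within_mean_constant_off_diagonal(self):
        blk = np.full((4, 4), 0.8)
        np.fill_diagonal(blk, 0)
        assert within_condition_mean(self._manual_rdm(blk), "pre") == pytest.approx(0.8)

    def test_within_mean_uses_only_lower_triangle(self):
        blk = np.zeros((3, 3))
        blk[np.tril_indices(3, k=-1)] = [0.2, 0.4, 0.6]
        blk[np.triu_indices(3, k=1)] = 99.0  # ignored by the lower-triangle contract
        assert within_condition_mean(self._manual_rdm(blk), "pre") == pytest.approx(0.4)

    def test_between_diagonal_mean_hand_value(self):
        n = 3
        values = np.ones((3 * n, 3 * n))
        blk = np.zeros((n, n))
        np.fill_diagonal(blk, [0.1, 0.2, 0.3])
        values[:n, n:2 * n] = blk
        rsm = RDM(values=values, image_ids=["a", "b", "c"], kind="rsm")
        assert between_condition_diagonal_mean(rsm, "pre", "post") == pytest.approx(0.2)

    def test_image_subset_restriction(self, rng):
        patterns, ids, cats = _toy_patterns(rng, n_images=4)
        rdm = compute_rdm(patterns, ids, cats)
        subset = rdm.image_ids[:2]
        full = rdm.block("pre", "pre")
        sub = rdm.block("pre", "pre", images=subset)
        assert sub.shape == (2, 2)
        assert np.allclose(sub, full[:2, :2])


class TestConversions:
    def test_involution(self, small_rdms):
        rdm = next(iter(small_rdms.values()))
        assert np.allclose(rsm_to_rdm(rdm_to_rsm(rdm)).values, rdm.values)

    def test_rsm_diagonal_is_one(self, small_rdms):
        rsm = rdm_to_rsm(next(iter(small_rdms.values())))
        rsm.validate()
        assert np.allclose(np.diag(rsm.values), 1.0)

    def test_group_average_elementwise_oracle(self, small_rdms):
        rdms = list(small_rdms.values())[:5]
        avg = group_average(rdms)
        assert np.allclose(avg.values, np.mean([r.values for r in rdms], axis=0))


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == pytest.approx(0.0)
        assert fisher_z(0.5) == pytest.approx(0.5493061443, abs=1e-9)
        assert fisher_z(-0.5) == pytest.approx(-0.5493061443, abs=1e-9)

    def test_clipping_warns_but_stays_finite(self):
        with pytest.warns(RuntimeWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestSubsampleVoxels:
    def test_full_size_is_identity_up_to_voxel_set(self, small_cohort):
        dataset, _, _ = small_cohort
        sub = subsample_voxels(dataset, 60, seed=0)
        assert all(info.n_voxels == 60 for info in sub.rois.values())
        key = ("sub01", "PCC")  # PCC already has 60 voxels: subset must be all of them
        assert np.allclose(
            np.sort(sub.patterns[key]["pre"], axis=1),
            np.sort(dataset.patterns[key]["pre"], axis=1),
        )

    def test_seeded_determinism(self, small_cohort):
        dataset, _, _ = small_cohort
        a = subsample_voxels(dataset, 50, seed=9)
        b = subsample_voxels(dataset, 50, seed=9)
        key = ("sub02", "V1")
        assert np.array_equal(a.patterns[key]["post"], b.patterns[key]["post"])

    def test_same_subset_across_conditions(self, small_cohort):
        # duplicated-column oracle: duplicating every voxel then subsampling
        # back to the original count with the full set leaves the RDM unchanged
        dataset, _, _ = small_cohort
        sub = subsample_voxels(dataset, 50, seed=3)
        key = ("sub03", "FG")
        cols_pre = sub.patterns[key]["pre"]
        full = dataset.patterns[key]["pre"]
        # every subsampled column must exist in the original matrix
        for col in cols_pre.T:
            assert any(np.allclose(col, c) for c in full.T)

    def test_too_large_request_rejected(self, small_cohort):
        dataset, _, _ = small_cohort
        with pytest.raises(ValueError, match="exceeds"):
            subsample_voxels(dataset, 10_000, seed=0)
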