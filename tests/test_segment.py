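"""Bayesian segmentation: EM for GMM + bias, deformation updates, the full
loop, the registration baseline and Dice."""

import numpy as np
import pytest

from histoatlas import atlas, deform, phantom, segment
from histoatlas.core import LabelVolume, Volume
from histoatlas.segment import (
    GMMParams,
    RegistrationSegParams,
    SegmentOptions,
    TissueClustering,
    dice,
    em_fit,
    polynomial_basis,
)


class TestTissueClustering:
    def test_identity_covers_labels(self):
        cl = TissueClustering.identity([0, 3, 7])
        assert cl.n_classes == 3
        assert cl.class_of(7) == 2

    def test_missing_label_named(self):
        cl = TissueClustering({0: 0}, ("bg",))
        with pytest.raises(KeyError, match="5"):
            cl.class_of(5)

    def test_default_class_list_has_fifteen_types(self):
        assert len(segment.DEFAULT_TISSUE_CLASS_NAMES) == 15


class TestGMMParams:
    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GMMParams([[0.5, 0.4]], [[0, 1]], [[1, 1]])

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            GMMParams([[1.0]], [[0.0]], [[0.0]])


class TestEMFit:
    def test_two_class_mean_recovery(self):
        """50k voxels, log-means 2 and 4, variance 0.01: means within 2%."""
        rng = np.random.default_rng(0)
        n = 50_000
        z = rng.random(n) < 0.4
        y = np.where(z, 4.0, 2.0) + rng.normal(0, 0.1, n)
        priors = np.stack([np.where(z, 0.2, 0.8), np.where(z, 0.8, 0.2)], axis=1)
        res = em_fit(y, priors, np.zeros((n, 0)), tol=1e-9, max_iters=200)
        assert abs(res.gmm.means[0][0] - 2.0) / 2.0 < 0.02
        assert abs(res.gmm.means[1][0] - 4.0) / 4.0 < 0.02

    def test_log_likelihood_monotone(self):
        rng = np.random.default_rng(1)
        n = 5000
        z = rng.random(n) < 0.5
        y = np.where(z, 3.0, 1.0) + rng.normal(0, 0.3, n)
        priors = np.stack([np.where(z, 0.3, 0.7), np.where(z, 0.7, 0.3)], axis=1)
        res = em_fit(y, priors, np.zeros((n, 0)), tol=0.0, max_iters=40)
        assert np.all(np.diff(res.log_likelihoods) >= -1e-8)

    def test_bias_field_recovered(self):
        """Planted log-bias correlates >= 0.95 with the estimate."""
        rng = np.random.default_rng(2)
        shape = (40, 40, 30)
        n = int(np.prod(shape))
        z = rng.random(n) < 0.4
        y = np.where(z, 4.0, 2.0) + rng.normal(0, 0.1, n)
        priors = np.stack([np.where(z, 0.2, 0.8), np.where(z, 0.8, 0.2)], axis=1)
        bias = phantom.sample_bias(shape, 2, 0.08, seed=3)
        yb = y + np.log(bias).ravel()
        basis = polynomial_basis(shape, 2)
        res = em_fit(yb, priors, basis, tol=1e-9, max_iters=200, bias_order=2)
        est = basis @ res.bias.coefficients
        assert np.corrcoef(est, np.log(bias).ravel())[0, 1] >= 0.95

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            em_fit(np.array([]), np.zeros((0, 2)), np.zeros((0, 0)))


@pytest.fixture(scope="module")
def seg_setup(big_roi_template):
    lab = big_roi_template.data
    lab_list = np.unique(lab)
    ohs = [
        atlas.onehot(
            deform.warp(
                lab,
                deform.exp_svf(phantom.sample_svf((36, 36, 36), 8, 1.5, seed=200 + k)),
                mode="nearest",
            ).astype(np.int32),
            lab_list,
        )
        for k in range(5)
    ]
    at = atlas.update_atlas(ohs, lab_list)
    truth = deform.warp(
        lab, deform.exp_svf(phantom.sample_svf((36, 36, 36), 8, 1.5, seed=300)),
        mode="nearest",
    ).astype(np.int32)
    cl = TissueClustering.identity(lab_list)
    model = phantom.ClassIntensityModel.from_means(
        [20, 60, 100, 140, 180], [2, 2, 2, 2, 2]
    )
    img = phantom.sample_intensity(LabelVolume(truth), model, cl, seed=7)
    return at, truth, cl, img


class TestOptimizeDeformation:
    def test_shift_recovered(self, seg_setup):
        at, truth, cl, img = seg_setup
        shifted_probs = np.roll(at.probs, 3, axis=0)
        from histoatlas.core import ProbAtlas

        at_shifted = ProbAtlas(shifted_probs, at.labels)
        logy = np.log(np.maximum(img.data, 1e-6))
        gmm = GMMParams(
            [[1.0]] * 5,
            [[np.log(m)] for m in (20, 60, 100, 140, 180)],
            [[0.01]] * 5,
        )
        res = segment.optimize_deformation(
            logy, at_shifted, cl, gmm, np.zeros_like(logy),
            np.ones_like(logy, bool), n_iters=60,
        )
        fg = truth > 0
        assert abs(res.displacement[fg].mean(axis=0)[0] - 3.0) < 0.5

    def test_objective_never_decreases(self, seg_setup):
        at, truth, cl, img = seg_setup
        logy = np.log(np.maximum(img.data, 1e-6))
        gmm = GMMParams(
            [[1.0]] * 5,
            [[np.log(m)] for m in (20, 60, 100, 140, 180)],
            [[0.05]] * 5,
        )
        res = segment.optimize_deformation(
            logy, at, cl, gmm, np.zeros_like(logy), np.ones_like(logy, bool),
            n_iters=15,
        )
        assert res.history[-1] >= res.history[0]


class TestSegmentBayes:
    def test_phantom_recovery_and_normalisation(self, seg_setup):
        at, truth, cl, img = seg_setup
        post, seg, vols, em = segment.segment_bayes(
            Volume(img.data), at, cl, np.ones(truth.shape, bool),
            SegmentOptions(outer_iters=2),
        )
        post.check_normalised(1e-6)
        dd = dice(seg.data, truth)
        sizes = {int(l): int((truth == l).sum()) for l in np.unique(truth) if l > 0}
        big = [l for l, s in sizes.items() if s > 500]
        assert big, "phantom must contain ROIs above 500 voxels"
        assert (dd.loc[big, "dice"] >= 0.95).all()
        assert np.all(np.diff(em.log_likelihoods) >= -1e-8)

    def test_onehot_posterior_volumes_exact(self, big_roi_template):
        lab = big_roi_template.data
        lab_list = np.unique(lab)
        post = atlas.onehot(lab, lab_list)
        voxvol = 1.0
        expected = post.reshape(-1, len(lab_list)).sum(axis=0) * voxvol
        counts = np.array([(lab == l).sum() for l in lab_list], float)
        assert np.array_equal(expected, counts)

    def test_bias_invariance_of_volumes(self, seg_setup):
        """Multiplicative bias changes expected ROI volumes by < 5%."""
        at, truth, cl, img = seg_setup
        opts = SegmentOptions(outer_iters=1, bias_order=2)
        mask = np.ones(truth.shape, bool)
        _, _, v_clean, _ = segment.segment_bayes(
            Volume(img.data), at, cl, mask, opts
        )
        bias = phantom.sample_bias(truth.shape, 2, 0.1, seed=9)
        _, _, v_bias, _ = segment.segment_bayes(
            Volume(img.data * bias), at, cl, mask, opts
        )
        big = v_clean.index[v_clean["expected_volume_mm3"] > 500]
        rel = np.abs(
            v_bias.loc[big, "expected_volume_mm3"]
            / v_clean.loc[big, "expected_volume_mm3"]
            - 1.0
        )
        assert (rel < 0.05).all()

    def test_uniform_atlas_degrades_dice(self, seg_setup):
        """The atlas prior demonstrably informs the solution."""
        at, truth, cl, img = seg_setup
        from histoatlas.core import ProbAtlas

        mask = np.ones(truth.shape, bool)
        opts = SegmentOptions(outer_iters=1, deform_iters=5)
        _, seg_true, _, _ = segment.segment_bayes(Volume(img.data), at, cl, mask, opts)
        uni = ProbAtlas(
            np.full(truth.shape + (len(at.labels),), 1.0 / len(at.labels)),
            at.labels,
        )
        _, seg_uni, _, _ = segment.segment_bayes(Volume(img.data), uni, cl, mask, opts)
        d_true = dice(seg_true.data, truth)["dice"].mean()
        d_uni = dice(seg_uni.data, truth)["dice"].mean()
        assert d_uni < d_true

    def test_unmapped_label_rejected(self, seg_setup):
        at, truth, cl, img = seg_setup
        bad = TissueClustering({0: 0}, ("bg",))
        with pytest.raises(ValueError):
            segment.segment_bayes(
                Volume(img.data), at, bad, np.ones(truth.shape, bool)
            )


class TestRegistrationBaseline:
    def test_printed_default_parameters(self):
        p = RegistrationSegParams()
        assert (p.cp_spacing_voxels, p.lncc_sigma_mm, p.bending_weight) == (
            5.0, 2.5, 0.001,
        )

    def test_self_registration_identity(self, curved_stack):
        img = curved_stack.images["reference"][1]
        lab = (img > img.mean()).astype(np.int32)
        out = segment.segment_by_registration(img, img, lab, n_iters=10)
        assert np.array_equal(out, lab)

    def test_translated_template_recovered(self, seg_setup):
        at, truth, cl, img = seg_setup
        target = img.data
        template = np.roll(target, 2, axis=1)
        template_labels = np.roll(truth, 2, axis=1)
        out = segment.segment_by_registration(
            target, template, template_labels, voxel_size_mm=0.5, n_iters=50
        )
        dd = dice(out, truth)
        sizes = {int(l): int((truth == l).sum()) for l in np.unique(truth) if l > 0}
        big = [l for l, s in sizes.items() if s > 500]
        assert (dd.loc[big, "dice"] >= 0.95).all()


class TestDice:
    def test_identical_volumes_all_one(self, big_roi_template):
        dd = dice(big_roi_template.data, big_roi_template.data)
        assert (dd["dice"] == 1.0).all()

    def test_disjoint_foregrounds_zero(self):
        a = np.zeros((8, 8), np.int32)
        b = np.zeros((8, 8), np.int32)
        a[:2, :2] = 1
        b[5:, 5:] = 1
        assert dice(a, b).loc[1, "dice"] == 0.0

    def test_half_overlapping_cubes(self):
        """8-voxel cubes overlapping in 4 voxels: Dice = 2·4/(8+8) = 0.5."""
        a = np.zeros((4, 4, 4), np.int32)
        b = np.zeros((4, 4, 4), np.int32)
        a[0:2, 0:2, 0:2] = 1
        b[1:3, 0:2, 0:2] = 1
        assert dice(a, b).loc[1, "dice"] == 0.5

    def test_empty_in_both_is_nan(self):
        a = np.zeros((4, 4), np.int32)
        a[0, 0] = 2
        dd = dice(a, a, label_mapping={2: 2, 1: 1})
        assert 1 not in dd.index or np.isnan(dd.loc[1, "dice"])

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dice(np.zeros((4, 4), np.int32), np.zeros((5, 5), np.int32))

    def test_label_merging(self):
        a = np.zeros((4, 4), np.int32)
        b = np.zeros((4, 4), np.int32)
        a[0, :] = 1
        b[0, :] = 2
        dd = dice(a, b, label_mapping={1: 1, 2: 1})
        assert dd.loc[1, "dice"] == 1.0
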