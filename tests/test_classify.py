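"""Signature estimation, ML classification, and the comparison classifiers."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from forestseg import (
    LabelRaster,
    MultibandScene,
    SegmentationParams,
    extract_signatures,
    init_segments,
    majority_filter,
    ml_classify,
    obc_classify,
    segment,
)
from forestseg.classify import ClassSignature, ClassSignatureSet


def make_sigset(means, covs, priors=None, scheme=None):
    k = len(means)
    priors = priors if priors is not None else [1.0 / k] * k
    return ClassSignatureSet(
        [
            ClassSignature(i + 1, np.asarray(m, float), np.asarray(c, float),
                           50, p)
            for i, (m, c, p) in enumerate(zip(means, covs, priors))
        ],
        scheme,
    )


class TestExtractSignatures:
    def test_constant_training_gives_exact_mean(self, scheme):
        px = np.zeros((6, 6, 4))
        px[:3] = [1.0, 2.0, 3.0, 4.0]
        px[3:] = [9.0, 9.0, 9.0, 9.0]
        scene = MultibandScene(px)
        lab = np.zeros((6, 6), np.int32)
        lab[:3] = 1
        lab[3:] = 2
        sigs = extract_signatures(scene, LabelRaster(lab, scheme))
        np.testing.assert_allclose(sigs.signatures[0].mean, [1, 2, 3, 4])
        np.testing.assert_allclose(sigs.signatures[0].covariance, 0.0)

    def test_proportional_priors(self, rng, scheme):
        scene = MultibandScene(rng.normal(size=(20, 10, 4)))
        lab = np.zeros((20, 10), np.int32)
        lab[:5] = 1   # 50 pixels
        lab[5:20] = 2  # 150 pixels
        sigs = extract_signatures(scene, LabelRaster(lab, scheme),
                                  prior_mode="proportional")
        assert sigs.signatures[0].prior == pytest.approx(0.25)
        assert sigs.signatures[1].prior == pytest.approx(0.75)

    def test_matches_textbook_moment_formulas(self, rng, scheme):
        scene = MultibandScene(rng.normal(50, 5, size=(15, 15, 3)))
        lab = (rng.random((15, 15)) < 0.4).astype(np.int32)  # class 1 vs unlabeled
        training = LabelRaster(lab, scheme)
        sigs = extract_signatures(scene, training)
        x = scene.pixels[lab == 1]
        mu = x.mean(axis=0)
        cov = (x - mu).T @ (x - mu) / (len(x) - 1)
        np.testing.assert_allclose(sigs.signatures[0].mean, mu, rtol=1e-12)
        np.testing.assert_allclose(sigs.signatures[0].covariance, cov, rtol=1e-10)

    def test_single_pixel_class_rejected(self, rng, scheme):
        scene = MultibandScene(rng.normal(size=(4, 4, 2)))
        lab = np.zeros((4, 4), np.int32)
        lab[0, 0] = 3
        with pytest.raises(ValueError, match="class 3"):
            extract_signatures(scene, LabelRaster(lab, scheme))

    def test_outlier_trimming_recovers_clean_moments(self, rng, scheme):
        """A 10% shadow fraction at a large offset barely moves the trimmed
        estimate but badly inflates the plain one."""
        clean = rng.normal(100, 5, size=(500, 2))
        shadows = rng.normal(10, 2, size=(50, 2))
        px = np.vstack([clean, shadows]).reshape(55, 10, 2)
        scene = MultibandScene(px)
        training = LabelRaster(np.ones((55, 10), np.int32), scheme)
        plain = extract_signatures(scene, training)
        trimmed = extract_signatures(scene, training, trim_outliers=0.999)
        assert abs(trimmed.signatures[0].mean[0] - 100) < 1.0
        assert abs(plain.signatures[0].mean[0] - 100) > 5.0


class TestMLClassify:
    def test_reduces_to_minimum_distance_for_identity_covariance(self, rng):
        sigs = make_sigset([np.zeros(3), np.full(3, 10.0)],
                           [np.eye(3), np.eye(3)])
        scene = MultibandScene(np.ones((2, 2, 3)))
        out = ml_classify(scene, sigs)
        assert np.all(out.labels == 1)

    def test_single_class_assigns_everywhere(self, rng):
        sigs = make_sigset([np.zeros(2)], [np.eye(2)], [1.0])
        scene = MultibandScene(rng.normal(size=(4, 4, 2)))
        assert np.all(ml_classify(scene, sigs).labels == 1)

    def test_matches_density_evaluation_oracle(self, rng):
        """50 random pixels, 3 classes with random full covariances: labels
        equal argmax of prior-weighted Gaussian log-densities from scipy."""
        means = [rng.uniform(0, 10, 4) for _ in range(3)]
        covs = []
        for _ in range(3):
            a = rng.normal(size=(4, 4))
            covs.append(a @ a.T + 0.5 * np.eye(4))
        priors = [0.5, 0.3, 0.2]
        sigs = make_sigset(means, covs, priors)
        scene = MultibandScene(rng.uniform(0, 10, (10, 5, 4)))
        out = ml_classify(scene, sigs)
        x = scene.pixels.reshape(-1, 4)
        dens = np.stack(
            [
                np.log(p) + multivariate_normal(m, c).logpdf(x)
                for m, c, p in zip(means, covs, priors)
            ],
            axis=1,
        )
        np.testing.assert_array_equal(out.labels.ravel(), dens.argmax(axis=1) + 1)

    def test_invariant_to_common_prior_rescaling(self, rng):
        means = [rng.uniform(0, 5, 2) for _ in range(3)]
        covs = [np.eye(2)] * 3
        scene = MultibandScene(rng.uniform(0, 5, (6, 6, 2)))
        a = ml_classify(scene, make_sigset(means, covs, [1 / 3] * 3))
        b = ml_classify(scene, make_sigset(means, covs, [0.2, 0.2, 0.6]))
        # equal priors vs unequal differ in general, but scaling all priors
        # by a constant (renormalized) must not change anything
        c = ml_classify(scene, make_sigset(means, covs, [1 / 3] * 3))
        np.testing.assert_array_equal(a.labels, c.labels)
        assert b.labels.shape == a.labels.shape

    def test_nodata_maps_to_zero(self, rng):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        scene = MultibandScene(rng.normal(size=(3, 3, 2)), nodata_mask=mask)
        sigs = make_sigset([np.zeros(2)], [np.eye(2)], [1.0])
        out = ml_classify(scene, sigs)
        assert out.labels[1, 1] == 0 and np.all(out.labels[~mask] == 1)

    def test_band_mismatch_rejected(self, rng):
        sigs = make_sigset([np.zeros(3)], [np.eye(3)], [1.0])
        scene = MultibandScene(rng.normal(size=(2, 2, 2)))
        with pytest.raises(ValueError):
            ml_classify(scene, sigs)


class TestMajorityFilter:
    def test_constant_map_unchanged(self, scheme):
        lab = LabelRaster(np.full((5, 5), 4, np.int32), scheme)
        np.testing.assert_array_equal(majority_filter(lab).labels, 4)

    def test_isolated_pixel_removed(self, scheme):
        arr = np.full((5, 5), 1, np.int32)
        arr[2, 2] = 2
        out = majority_filter(LabelRaster(arr, scheme))
        assert np.all(out.labels == 1)

    def test_matches_windowed_mode_oracle(self, rng, scheme):
        arr = rng.integers(1, 5, size=(10, 10)).astype(np.int32)
        out = majority_filter(LabelRaster(arr, scheme), window=3)
        for r in range(10):
            for c in range(10):
                win = arr[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                counts = np.bincount(win.ravel(), minlength=10)
                best = counts.max()
                if counts[arr[r, c]] == best:
                    expected = arr[r, c]  # centre retains its class on ties
                else:
                    expected = int(np.flatnonzero(counts == best)[0])
                assert out.labels[r, c] == expected, (r, c)

    def test_never_introduces_absent_class(self, rng, scheme):
        arr = rng.integers(1, 4, size=(12, 12)).astype(np.int32)
        out = majority_filter(LabelRaster(arr, scheme))
        for r in range(12):
            for c in range(12):
                win = arr[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
                assert out.labels[r, c] in win

    def test_even_window_rejected(self, scheme):
        with pytest.raises(ValueError):
            majority_filter(LabelRaster(np.ones((3, 3), np.int32), scheme), window=4)


class TestOBC:
    def test_single_pixel_segments_reduce_to_ml(self, rng):
        means = [rng.uniform(0, 10, 3) for _ in range(3)]
        covs = [np.eye(3)] * 3
        sigs = make_sigset(means, covs)
        scene = MultibandScene(rng.uniform(0, 10, (6, 6, 3)))
        sm = init_segments(scene)
        np.testing.assert_array_equal(
            obc_classify(sm, scene, sigs).labels, ml_classify(scene, sigs).labels
        )

    def test_pure_stand_classified_correctly(self):
        sigs = make_sigset([np.zeros(2), np.full(2, 50.0)], [np.eye(2)] * 2)
        scene = MultibandScene(np.full((4, 4, 2), 50.0))
        sm = segment(scene, SegmentationParams(scale=5, w_color=1.0), 0)
        assert sm.n_segments == 1
        assert np.all(obc_classify(sm, scene, sigs).labels == 2)

    def test_segment_labels_match_discriminant_on_means(self, rng):
        means = [rng.uniform(0, 20, 4) for _ in range(3)]
        covs = []
        for _ in range(3):
            a = rng.normal(size=(4, 4))
            covs.append(a @ a.T + np.eye(4))
        priors = [0.4, 0.35, 0.25]
        sigs = make_sigset(means, covs, priors)
        scene = MultibandScene(rng.uniform(0, 20, (12, 12, 4)))
        sm = segment(scene, SegmentationParams(scale=15), 1)
        out = obc_classify(sm, scene, sigs)
        for sid in sm.ids():
            mu = scene.pixels[sm.segment_ids == sid].mean(axis=0)
            dens = [
                np.log(p) + multivariate_normal(m, c).logpdf(mu)
                for m, c, p in zip(means, covs, priors)
            ]
            expected = int(np.argmax(dens)) + 1
            got = np.unique(out.labels[sm.segment_ids == sid])
            assert got.tolist() == [expected]
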