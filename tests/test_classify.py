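import numpy as np
import pytest
from scipy.stats import multivariate_normal

from icseg import (
    InsufficientTrainingError,
    InvalidParameterError,
    LuvImage,
    fit_gaussian_classifier,
    gaussian_posterior,
    hybrid_posterior,
    select_lambda,
)
from icseg.classify import CLASSES, posterior_for_samples
from icseg.seeds import LESION, SKIN, TrainingSplit


def _gaussian_samples(rng, n, mean, cov):
    return rng.multivariate_normal(mean, cov, size=n)


def _two_class(rng, n=200, shift=(3.0, 0.0, 0.0), cov_skin=None, cov_lesion=None):
    cov_skin = np.eye(3) if cov_skin is None else np.asarray(cov_skin)
    cov_lesion = np.eye(3) if cov_lesion is None else np.asarray(cov_lesion)
    return {
        SKIN: _gaussian_samples(rng, n, np.zeros(3), cov_skin),
        LESION: _gaussian_samples(rng, n, np.asarray(shift, float), cov_lesion),
    }


class TestFit:
    def test_pooled_covariance_formula(self, rng):
        samples = {
            SKIN: _gaussian_samples(rng, 60, np.zeros(3), np.eye(3)),
            LESION: _gaussian_samples(rng, 40, np.ones(3), np.eye(3)),
        }
        params = fit_gaussian_classifier(samples, "lda")
        # hand-computed size-weighted within-class (ML) covariance
        want = np.zeros((3, 3))
        for cls in CLASSES:
            x = samples[cls] - samples[cls].mean(axis=0)
            want += x.T @ x
        want /= 100
        assert np.allclose(params.covariances[SKIN], want, atol=1e-12)
        assert np.allclose(params.covariances[SKIN], params.covariances[LESION])
        assert params.ridge == 0.0

    def test_identical_classes_give_half_posteriors(self, rng):
        x = _gaussian_samples(rng, 50, np.zeros(3), np.eye(3))
        params = fit_gaussian_classifier({SKIN: x, LESION: x.copy()}, "qda")
        p = posterior_for_samples(params, rng.standard_normal((20, 3)))
        assert np.allclose(p, 0.5, atol=1e-12)

    def test_constant_feature_fits_with_recorded_ridge(self, rng):
        samples = _two_class(rng, n=30)
        samples[SKIN][:, 2] = 5.0  # zero-variance feature
        params = fit_gaussian_classifier(samples, "qda")
        assert params.ridge > 0.0
        assert np.all(np.linalg.eigvalsh(params.covariances[SKIN]) > 0)

    def test_too_few_samples_rejected(self, rng):
        samples = _two_class(rng, n=10)
        samples[LESION] = samples[LESION][:3]
        with pytest.raises(InsufficientTrainingError):
            fit_gaussian_classifier(samples, "lda")


class TestPosterior:
    def test_matches_multivariate_normal_oracle(self, rng):
        samples = _two_class(
            rng, n=150, cov_skin=np.eye(3), cov_lesion=np.diag([2.0, 0.5, 1.0])
        )
        for mode in ("lda", "qda"):
            params = fit_gaussian_classifier(samples, mode)
            x = rng.standard_normal((40, 3)) * 2
            got = posterior_for_samples(params, x)
            dens = np.stack(
                [
                    multivariate_normal(
                        params.class_means[cls], params.covariances[cls]
                    ).pdf(x)
                    for cls in CLASSES
                ],
                axis=1,
            )
            want = dens * 0.5
            want /= want.sum(axis=1, keepdims=True)
            assert np.allclose(got, want, atol=1e-10)

    def test_symmetry_point_is_half(self, rng):
        samples = _two_class(rng, n=100, shift=(2.0, 0.0, 0.0))
        params = fit_gaussian_classifier(samples, "lda")
        mid = (params.class_means[SKIN] + params.class_means[LESION]) / 2.0
        p = posterior_for_samples(params, mid[None, :])
        assert np.allclose(p, 0.5, atol=1e-9)

    def test_one_dimensional_closed_form(self):
        """Means 0 and 2, unit variance, x=0: p(skin) = e^2 / (1 + e^2)."""
        base = np.array([[-1.0], [1.0], [-1.0], [1.0]])  # ML variance exactly 1
        skin = np.hstack([base + 0.0, np.full((4, 1), 7.0), np.full((4, 1), 3.0)])
        lesion = np.hstack([base + 2.0, np.full((4, 1), 7.0), np.full((4, 1), 3.0)])
        params = fit_gaussian_classifier({SKIN: skin, LESION: lesion}, "lda")
        x = np.array([[0.0, 7.0, 3.0]])
        p = posterior_for_samples(params, x)
        want = np.e**2 / (1.0 + np.e**2)
        # the tiny diagonal loading on the degenerate dims shifts this by ~1e-7
        assert p[0, 0] == pytest.approx(want, abs=1e-6)
        assert p[0, 0] == pytest.approx(0.8808, abs=1e-4)

    def test_map_normalizes_inside_field(self, rng):
        samples = _two_class(rng, n=100)
        params = fit_gaussian_classifier(samples, "qda")
        L = rng.normal(50, 10, (32, 32))
        field = np.hypot(*np.mgrid[-16:16, -16:16]) <= 14
        luv = LuvImage(L=L, u=rng.normal(0, 5, (32, 32)), v=rng.normal(0, 5, (32, 32)),
                       field_mask=field)
        post = gaussian_posterior(params, luv)
        total = post.p_skin + post.p_lesion
        assert np.allclose(total[field], 1.0, atol=1e-9)
        assert np.all(total[~field] == 0.0)


class TestHybrid:
    def _maps(self, rng):
        shape = (8, 8)
        a = rng.random(shape)
        b = rng.random(shape)
        from icseg.classify import PosteriorMap

        return (
            PosteriorMap(p_skin=1 - a, p_lesion=a),
            PosteriorMap(p_skin=1 - b, p_lesion=b),
        )

    def test_endpoints_recover_base_maps(self, rng):
        qda, lda = self._maps(rng)
        assert np.array_equal(hybrid_posterior(qda, lda, 0.0).p_lesion, lda.p_lesion)
        assert np.array_equal(hybrid_posterior(qda, lda, 1.0).p_lesion, qda.p_lesion)

    def test_midpoint_arithmetic(self, rng):
        qda, lda = self._maps(rng)
        qda.p_lesion[0, 0], lda.p_lesion[0, 0] = 0.9, 0.7
        assert hybrid_posterior(qda, lda, 0.5).p_lesion[0, 0] == pytest.approx(0.8)

    def test_monotone_in_lambda(self, rng):
        qda, lda = self._maps(rng)
        lams = np.linspace(0, 1, 11)
        stack = np.stack([hybrid_posterior(qda, lda, l).p_lesion for l in lams])
        grows = qda.p_lesion > lda.p_lesion
        diffs = np.diff(stack, axis=0)
        assert np.all(diffs[:, grows] >= -1e-12)
        assert np.all(diffs[:, ~grows] <= 1e-12)

    def test_invalid_lambda_rejected(self, rng):
        qda, lda = self._maps(rng)
        with pytest.raises(InvalidParameterError):
            hybrid_posterior(qda, lda, 1.5)


def _split_from(samples_lda, samples_qda):
    return TrainingSplit(
        lda_samples=samples_lda,
        qda_samples=samples_qda,
        origin_counts={c: samples_lda[c].shape[0] + samples_qda[c].shape[0] for c in samples_lda},
    )


class TestSelectLambda:
    def test_separable_data_selects_zero(self, rng):
        """Perfect accuracy at every lambda: the tie goes to the linear model."""
        a = _two_class(rng, n=50, shift=(30.0, 0.0, 0.0))
        b = _two_class(rng, n=50, shift=(30.0, 0.0, 0.0))
        split = _split_from(a, b)
        lda = fit_gaussian_classifier(split.lda_samples, "lda")
        qda = fit_gaussian_classifier(split.qda_samples, "qda")
        assert select_lambda(split, lda, qda) == 0.0

    def test_unequal_covariances_prefer_qda(self):
        """An LDA that is confidently wrong on part of the lesion class can only
        be outvoted by the quadratic posterior at lambda > 0.5."""
        from icseg.classify import GaussianClassParams

        priors = {SKIN: 0.5, LESION: 0.5}
        lda = GaussianClassParams(
            mode="lda",
            class_means={SKIN: np.zeros(3), LESION: np.array([4.0, 0.0, 0.0])},
            covariances={SKIN: np.eye(3), LESION: np.eye(3)},
            priors=priors,
        )
        qda = GaussianClassParams(
            mode="qda",
            class_means={SKIN: np.zeros(3), LESION: np.zeros(3)},
            covariances={SKIN: np.eye(3) * 0.05, LESION: np.eye(3) * 25.0},
            priors=priors,
        )
        skin_eval = np.random.default_rng(0).normal(0, 0.1, (60, 3))
        lesion_eval = np.vstack(
            [
                # LDA is confidently wrong here while QDA is ~94% right, so the
                # argmax flips only once lambda exceeds roughly 0.5/0.94
                np.tile([-1.1, 0.0, 0.0], (20, 1)),
                np.tile([4.0, 0.0, 0.0], (40, 1)),
            ]
        )
        half_s, half_l = {SKIN: skin_eval[:30], LESION: lesion_eval[:30]}, {
            SKIN: skin_eval[30:],
            LESION: lesion_eval[30:],
        }
        split = _split_from(half_s, half_l)
        lam = select_lambda(split, lda, qda)
        assert lam > 0.5
        # independent grid evaluation with the scipy density oracle
        pooled = split.pooled()
        dens = {}
        for mode, params in (("lda", lda), ("qda", qda)):
            for cls_fit in (SKIN, LESION):
                mvn = multivariate_normal(
                    params.class_means[cls_fit], params.covariances[cls_fit]
                )
                for cls_data in (SKIN, LESION):
                    dens[(mode, cls_fit, cls_data)] = mvn.pdf(pooled[cls_data])
        best_score, best_lam = -1.0, None
        for lam_g in np.round(np.arange(0, 101) / 100.0, 2):
            accs = []
            for cls_data in (SKIN, LESION):
                p = {}
                for mode in ("lda", "qda"):
                    d_skin = dens[(mode, SKIN, cls_data)]
                    d_les = dens[(mode, LESION, cls_data)]
                    p[mode] = d_les / (d_skin + d_les)
                mix = lam_g * p["qda"] + (1 - lam_g) * p["lda"]
                pred_lesion = mix > 0.5
                correct = pred_lesion if cls_data == LESION else ~pred_lesion
                accs.append(correct.mean())
            score = min(accs)
            if score > best_score:
                best_score, best_lam = score, lam_g
        assert lam == pytest.approx(best_lam, abs=1e-12)

    def test_grid_membership_and_determinism(self, rng):
        samples = _two_class(rng, n=80, shift=(1.0, 0.5, 0.0))
        split = _split_from(samples, _two_class(rng, n=80, shift=(1.0, 0.5, 0.0)))
        lda = fit_gaussian_classifier(split.lda_samples, "lda")
        qda = fit_gaussian_classifier(split.qda_samples, "qda")
        lam1 = select_lambda(split, lda, qda)
        lam2 = select_lambda(split, lda, qda)
        assert lam1 == lam2
        assert np.isclose((lam1 / 0.01) % 1.0, 0.0, atol=1e-9) or lam1 in (0.0, 1.0)
        assert 0.0 <= lam1 <= 1.0

    def test_score_is_min_of_class_accuracies(self, rng):
        """With a tight skin class and an overlapping lesion class the binding
        constraint is the worse class; moving the lesion away improves the
        selected score monotonically (sanity of the min rule)."""
        def best_score(shift):
            a = _two_class(rng, n=100, shift=(shift, 0, 0))
            split = _split_from(a, _two_class(rng, n=100, shift=(shift, 0, 0)))
            lda = fit_gaussian_classifier(split.lda_samples, "lda")
            qda = fit_gaussian_classifier(split.qda_samples, "qda")
            lam = select_lambda(split, lda, qda)
            pooled = split.pooled()
            accs = []
            for cls in (SKIN, LESION):
                p = (
                    lam * posterior_for_samples(qda, pooled[cls])[:, 1]
                    + (1 - lam) * posterior_for_samples(lda, pooled[cls])[:, 1]
                )
                pred = p > 0.5
                accs.append((pred if cls == LESION else ~pred).mean())
            return min(accs)

        assert best_score(0.5) <= best_score(6.0) == 1.0
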