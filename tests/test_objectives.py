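"""Loss closed forms, metric identities, and independent-oracle agreement."""

import numpy as np
import pytest
from scipy.signal import fftconvolve
from skimage.metrics import structural_similarity

import fringeoct as fo
from fringeoct.objectives import BCE_EPS, MS_SSIM_WEIGHTS, _gaussian_window

LN2 = float(np.log(2.0))


class TestAscanLosses:
    def test_identical_profiles_give_zero_everywhere(self):
        a = np.linspace(-1.0, 1.0, 64)
        assert fo.l1_a(a, a) == 0.0
        assert fo.l2_a(a, a) == 0.0
        assert fo.grad_a(a, a) == 0.0

    def test_hand_worked_two_point_case(self):
        out, gt = np.array([2.0, 0.0]), np.array([0.0, 0.0])
        assert fo.l1_a(out, gt) == pytest.approx(1.0, abs=1e-6)
        assert fo.l2_a(out, gt) == pytest.approx(2.0, abs=1e-6)

    def test_gradient_loss_kills_constant_offsets(self):
        a = np.sin(np.linspace(0.0, 6.0, 128))
        assert fo.grad_a(a + 3.0, a) == pytest.approx(0.0, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(fo.InvalidSpecError):
            fo.l1_a(np.zeros(3), np.zeros(4))


class TestBce:
    def test_confident_correct_prediction_is_near_zero(self):
        assert fo.bce(np.array(1.0 - BCE_EPS), np.array(1.0)) < 1e-6

    def test_uniform_prediction_gives_ln2_both_labels(self):
        assert fo.bce(np.array(0.5), np.array(1.0)) == pytest.approx(LN2, abs=1e-6)
        assert fo.bce(np.array(0.5), np.array(0.0)) == pytest.approx(LN2, abs=1e-6)

    def test_worst_case_is_clamped_and_large(self):
        worst = fo.loss_discriminator(np.array([BCE_EPS]), np.array([1.0 - BCE_EPS]))
        assert worst >= 2.0 * np.log(1.0 / BCE_EPS) * 0.99


class TestGeneratorLosses:
    def test_generator_a_zero_at_perfect_output_and_fooled_discriminator(self):
        a = np.linspace(-1.0, 1.0, 64)
        assert fo.loss_generator_a(a, a, np.array(1.0 - BCE_EPS)) < 1e-6

    def test_generator_a_only_adversarial_term_survives(self):
        a = np.zeros(64)
        val = fo.loss_generator_a(a, a, np.array(0.5))
        assert val == pytest.approx(1.0e-4 * LN2, abs=1e-9)

    def test_generator_a_is_linear_in_the_weights(self):
        rng = np.random.default_rng(0)
        out, gt = rng.random(64), rng.random(64)
        w1 = fo.LossWeights()
        w3 = fo.LossWeights(net_a=tuple(3.0 * np.array(w1.net_a)))
        v1 = fo.loss_generator_a(out, gt, np.array(0.5), w1)
        v3 = fo.loss_generator_a(out, gt, np.array(0.5), w3)
        assert v3 == pytest.approx(3.0 * v1, rel=1e-9)

    def test_generator_b_trio(self):
        img = np.tile(np.linspace(-1.0, 1.0, 352), (352, 1))
        assert fo.loss_generator_b(img, img, np.array(1.0 - BCE_EPS)) < 1e-6
        only_adv = fo.loss_generator_b(img, img, np.array(0.5))
        assert only_adv == pytest.approx(1.0e-4 * LN2, abs=1e-9)
        w5 = fo.LossWeights(net_b=tuple(5.0 * np.array(fo.LossWeights().net_b)))
        rng = np.random.default_rng(1)
        out = np.clip(img + rng.normal(0, 0.05, img.shape), -1, 1)
        v1 = fo.loss_generator_b(out, img, np.array(0.5))
        v5 = fo.loss_generator_b(out, img, np.array(0.5), w5)
        assert v5 == pytest.approx(5.0 * v1, rel=1e-9)

    def test_discriminator_loss_closed_forms(self):
        eps = BCE_EPS
        assert fo.loss_discriminator(np.array([1.0 - eps]), np.array([eps])) < 1e-6
        assert fo.loss_discriminator(np.array([0.5]), np.array([0.5])) == \
            pytest.approx(2.0 * LN2, abs=1e-6)

    def test_gradient_loss_b_hand_worked_case(self):
        out = np.array([[0.0, 1.0], [0.0, 1.0]])
        gt = np.zeros((2, 2))
        assert fo.grad_b(out, gt) == pytest.approx(1.0, abs=1e-12)
        assert fo.grad_b(gt + 2.0, gt) == pytest.approx(0.0, abs=1e-12)


# -- independent oracles ---------------------------------------------------

def ssim_oracle(x, y, data_range):
    return structural_similarity(x, y, data_range=data_range,
                                 gaussian_weights=True, sigma=1.5,
                                 use_sample_covariance=False)


def ms_ssim_oracle(x, y, data_range, n_scales=5):
    """FFT-convolution MS-SSIM, written independently of the package path."""
    w = _gaussian_window(11, 1.5)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    weights = np.asarray(MS_SSIM_WEIGHTS[:n_scales])
    weights = weights / weights.sum()
    vals = []
    for level in range(n_scales):
        mu_x = fftconvolve(x, w, mode="valid")
        mu_y = fftconvolve(y, w, mode="valid")
        sxx = fftconvolve(x * x, w, mode="valid") - mu_x**2
        syy = fftconvolve(y * y, w, mode="valid") - mu_y**2
        sxy = fftconvolve(x * y, w, mode="valid") - mu_x * mu_y
        cs = (2 * sxy + c2) / (sxx + syy + c2)
        lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
        vals.append((lum * cs).mean() if level == n_scales - 1 else cs.mean())
        h, ww = x.shape
        x = x[: h // 2 * 2, : ww // 2 * 2].reshape(h // 2, 2, ww // 2, 2).mean(axis=(1, 3))
        y = y[: h // 2 * 2, : ww // 2 * 2].reshape(h // 2, 2, ww // 2, 2).mean(axis=(1, 3))
    return float(np.prod(np.maximum(vals, 0.0) ** weights))


def _seeded_pairs(n, size=192):
    rng = np.random.default_rng(2024)
    for _ in range(n):
        base = rng.random((size, size))
        noisy = np.clip(base + rng.normal(0.0, rng.uniform(0.02, 0.3),
                                          (size, size)), 0.0, 1.0)
        yield base, noisy


class TestSimilarityOracles:
    def test_ssim_matches_reference_implementation(self):
        for x, y in _seeded_pairs(20):
            assert abs(fo.ssim(x, y, 1.0) - ssim_oracle(x, y, 1.0)) < 1e-4

    def test_ms_ssim_matches_independent_implementation(self):
        for x, y in _seeded_pairs(20):
            assert abs(fo.ms_ssim(x, y, 1.0) - ms_ssim_oracle(x, y, 1.0)) < 1e-4

    def test_similarity_metrics_are_symmetric(self):
        x, y = next(_seeded_pairs(1))
        assert fo.ssim(x, y, 1.0) == pytest.approx(fo.ssim(y, x, 1.0), abs=1e-12)
        assert fo.ms_ssim(x, y, 1.0) == pytest.approx(fo.ms_ssim(y, x, 1.0),
                                                      abs=1e-12)

    def test_joint_affine_rescaling_preserves_ssim(self):
        x, y = next(_seeded_pairs(1))
        s0 = fo.ssim(x, y, 1.0)
        # pure rescaling (with data_range scaled along) is exact
        assert fo.ssim(2.0 * x, 2.0 * y, 2.0) == pytest.approx(s0, abs=1e-12)
        # an added joint shift perturbs only the stabilized luminance term
        assert fo.ssim(2.0 * x - 0.5, 2.0 * y - 0.5, 2.0) == \
            pytest.approx(s0, abs=0.01)


class TestMsSsimLoss:
    def test_identical_images_give_zero(self):
        x = np.random.default_rng(3).random((192, 192))
        assert fo.ms_ssim_loss(x, x, 1.0) == 0.0

    def test_loss_is_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            a, b = rng.random((192, 192)), rng.random((192, 192))
            loss = fo.ms_ssim_loss(a, b, 1.0)
            assert 0.0 <= loss <= 1.0

    def test_independent_noise_pair_has_large_loss(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((256, 256))
        b = rng.standard_normal((256, 256))
        mine = fo.ms_ssim_loss(a, b, float(np.ptp(b)))
        oracle = (1.0 - ms_ssim_oracle(a, b, float(np.ptp(b)))) / 2.0
        assert mine == pytest.approx(oracle, abs=1e-4)
        assert mine > 0.3


class TestMetricsReport:
    def test_identical_pair_hits_all_fixed_points(self):
        x = np.random.default_rng(6).random((192, 192))
        rep = fo.metrics(x, x)
        assert rep.mse == 0.0
        assert rep.ssim == pytest.approx(1.0)
        assert rep.ms_ssim == pytest.approx(1.0)
        assert rep.psnr_db == float("inf")
        assert rep.beta == pytest.approx(1.0)
        assert rep.epf == pytest.approx(1.0)

    def test_psnr_closed_form(self):
        ref = np.zeros((100, 100))
        ref[0, 0] = 1.0  # peak of the reference
        out = ref + 0.1  # MSE = 0.01
        assert fo.psnr(out, ref) == pytest.approx(20.0, abs=1e-9)

    def test_beta_decorrelates_for_independent_noise(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal((2048, 1024))
        b = rng.standard_normal((2048, 1024))
        assert abs(fo.beta_parameter(a, b)) < 0.1

    def test_mode_flag_is_recorded_and_validated(self):
        x = np.random.default_rng(8).random((32, 32))
        assert fo.metrics(x, x, mode="vs_input").mode == "vs_input"
        with pytest.raises(fo.InvalidSpecError):
            fo.metrics(x, x, mode="nonsense")
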