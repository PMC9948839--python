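import numpy as np
import pytest

from segsense.augmentation import (
    DEFAULT_LANDMARK_FRACTIONS,
    RotationAugConfig,
    TransferFunctionModel,
    build_transfer_model,
    extract_landmarks,
    fit_transfer_function,
    sample_intensity_augmentation,
    sample_rotation_augmentation,
)
from segsense.transforms import polynomial_intensity_transform
from segsense.volumes import DegenerateInputError, LabeledVolume


class TestLandmarks:
    def test_default_fractions_give_seven_landmarks(self, rng):
        lm = extract_landmarks(rng.normal(size=(16, 16, 16)))
        assert len(DEFAULT_LANDMARK_FRACTIONS) == 7
        assert lm.shape == (7,)
        assert np.all(np.diff(lm) >= 0)

    def test_midpoint_quantile_convention(self):
        # values 1..8 once each: the median interpolates to 4.5
        image = np.arange(1, 9, dtype=float)
        lm = extract_landmarks(image, [0.5])
        assert lm[0] == pytest.approx(4.5)

    def test_uniform_landmarks_match_fractions(self, rng):
        image = rng.random(10**6)
        lm = extract_landmarks(image, DEFAULT_LANDMARK_FRACTIONS)
        np.testing.assert_allclose(lm, DEFAULT_LANDMARK_FRACTIONS, atol=0.01)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            extract_landmarks(np.ones((8, 8, 8)))


class TestTransferFunctionFit:
    base = np.array([0.1, 0.4, 0.9, 1.4, 2.0, 2.7, 3.5])

    @pytest.mark.parametrize(
        "target, expected",
        [
            ("identity", (0, 1, 0)),
            ("affine", (0, 2, 1)),
            ("square", (1, 0, 0)),
        ],
    )
    def test_exact_quadratic_recovery(self, target, expected):
        b = {
            "identity": self.base,
            "affine": 2 * self.base + 1,
            "square": self.base**2,
        }[target]
        c = fit_transfer_function(self.base, b)
        np.testing.assert_allclose(c, expected, atol=1e-9)

    def test_identical_source_landmarks_singular(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_transfer_function(np.ones(7), np.arange(7.0))

    def test_short_lists_rejected(self):
        with pytest.raises(ValueError):
            fit_transfer_function([1, 2], [3, 4])


class TestTransferModel:
    def test_identical_sets_collapse_to_identity(self):
        sets = [TestTransferFunctionFit.base] * 4
        model = build_transfer_model(sets)
        np.testing.assert_allclose(model.mean_c, (0, 1, 0), atol=1e-9)
        np.testing.assert_allclose(model.std_c, (0, 0, 0), atol=1e-9)
        assert model.n_pairs == 12  # ordered pairs: 4 * 3

    def test_three_sets_give_six_ordered_pairs(self):
        sets = [
            TestTransferFunctionFit.base,
            TestTransferFunctionFit.base * 1.5,
            TestTransferFunctionFit.base + 0.3,
        ]
        assert build_transfer_model(sets).n_pairs == 6

    def test_order_invariance(self, rng):
        sets = [
            TestTransferFunctionFit.base * rng.uniform(0.7, 1.3) + rng.normal(0, 0.2)
            for _ in range(4)
        ]
        a = build_transfer_model(sets)
        b = build_transfer_model(sets[::-1])
        np.testing.assert_allclose(a.mean_c, b.mean_c, atol=1e-12)
        np.testing.assert_allclose(a.std_c, b.std_c, atol=1e-12)

    def test_affine_generator_recovered(self, rng):
        # sets are random affine distortions a*x + b of a base set: the fitted
        # pairwise transfer functions are exact affines, so the mean linear
        # coefficient is near E[a_j / a_i] and the quadratic term stays 0
        n = 30
        slopes = rng.uniform(0.9, 1.1, size=n)
        inters = rng.normal(0, 0.05, size=n)
        sets = [s * TestTransferFunctionFit.base + i for s, i in zip(slopes, inters)]
        model = build_transfer_model(sets)
        assert abs(model.mean_c[0]) < 1e-9
        expected_slope = np.mean(
            [slopes[j] / slopes[i] for i in range(n) for j in range(n) if i != j]
        )
        se = model.std_c[1] / np.sqrt(model.n_pairs)
        assert abs(model.mean_c[1] - expected_slope) <= 3 * se + 1e-12

    def test_json_round_trip(self):
        model = build_transfer_model([TestTransferFunctionFit.base] * 3)
        back = TransferFunctionModel.from_json(model.to_json())
        assert back == model

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            build_transfer_model([TestTransferFunctionFit.base])


class TestIntensitySampler:
    def test_zero_std_returns_mean_exactly(self):
        model = TransferFunctionModel(mean_c=(0.1, 0.9, 0.02), std_c=(0, 0, 0), n_pairs=2)
        assert sample_intensity_augmentation(model, 0) == (0.1, 0.9, 0.02)

    def test_sample_mean_within_clt_bound(self):
        model = TransferFunctionModel(
            mean_c=(0.05, 1.1, -0.2), std_c=(0.02, 0.1, 0.05), n_pairs=6
        )
        rng = np.random.default_rng(42)
        draws = np.array([sample_intensity_augmentation(model, rng) for _ in range(10**5)])
        for k in range(3):
            bound = 4 * model.std_c[k] / np.sqrt(len(draws))
            assert abs(draws[:, k].mean() - model.mean_c[k]) < bound

    def test_seed_determinism(self):
        model = TransferFunctionModel(mean_c=(0, 1, 0), std_c=(0.1, 0.1, 0.1), n_pairs=2)
        assert sample_intensity_augmentation(model, 7) == sample_intensity_augmentation(model, 7)

    def test_identity_model_applies_as_identity_map(self, rng):
        model = build_transfer_model([TestTransferFunctionFit.base] * 3)
        c = sample_intensity_augmentation(model, 0)
        v = LabeledVolume(
            image=rng.normal(size=(8, 8, 8)), labels=np.zeros((8, 8, 8), dtype=int)
        )
        out = polynomial_intensity_transform(v, c)
        np.testing.assert_allclose(out.image, v.image, atol=1e-8)


class TestRotationSampler:
    def test_type1_mirror_frequency(self):
        cfg = RotationAugConfig(aug_type="type1", mirror_probability=0.5)
        rng = np.random.default_rng(1)
        n = 10**4
        counts = {"x": 0, "y": 0, "z": 0}
        for _ in range(n):
            axes, angle = sample_rotation_augmentation(cfg, rng)
            assert angle == 0.0
            for a in axes:
                counts[a] += 1
        bound = 4 * np.sqrt(0.25 / n)  # binomial 4-sigma
        for a in "xyz":
            assert abs(counts[a] / n - 0.5) < bound

    def test_type2_angles_from_discrete_set(self):
        cfg = RotationAugConfig(aug_type="type2")
        rng = np.random.default_rng(2)
        angles = {sample_rotation_augmentation(cfg, rng)[1] for _ in range(500)}
        assert angles == {0.0, 30.0, 50.0}

    def test_zero_probability_never_mirrors(self):
        cfg = RotationAugConfig(aug_type="type1", mirror_probability=0.0)
        for seed in range(20):
            axes, angle = sample_rotation_augmentation(cfg, seed)
            assert axes == frozenset() and angle == 0.0

    def test_type2_requires_angles(self):
        with pytest.raises(ValueError):
            RotationAugConfig(aug_type="type2", discrete_x_angles_deg=())
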