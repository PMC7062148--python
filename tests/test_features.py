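"""Color spaces, MLE PDF fits, and the feature-vector layout law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from skimage import color as skcolor

from wcemlda import (
    LabeledImage,
    LDAModel,
    ModelBank,
    convert_colorspace,
    count_features,
    extract_features,
    fit_pdf,
    peripheral_mask,
    stat_features,
    whole_image_features,
)
from wcemlda.features import COLOR_SPACES, FAMILIES, params_per_fit
from wcemlda.synthetic import generate_image


def _single_pixel_image(rgb):
    return LabeledImage(raster=np.full((2, 2, 3), rgb, dtype=np.uint8), id="px")


def _all_pass_model():
    """Degenerate LDA whose ROI is every valid pixel (score = +1)."""
    return LDAModel(
        mean_diseased=np.zeros(3),
        mean_normal=np.zeros(3),
        pooled_covariance=np.eye(3),
        weight=np.zeros(3),
        threshold=-1.0,
        prior_diseased=0.5,
    )


def _none_pass_model():
    """Degenerate LDA whose ROI is empty (score = -1 everywhere)."""
    m = _all_pass_model()
    m.threshold = 1.0
    return m


# ---------------------------------------------------------------- border


def test_valid_field_matches_the_generator_circle(default_config):
    from scipy import ndimage as ndi

    img = generate_image("N", default_config, seed=2)
    valid = peripheral_mask(img)
    field = default_config.field_mask()
    # agreement to within a 2-pixel boundary band
    inner = ndi.binary_erosion(field, iterations=2)
    outer = ndi.binary_dilation(field, iterations=2)
    assert np.all(valid[inner])
    assert not valid[~outer].any()


def test_all_black_image_has_no_valid_pixels():
    img = LabeledImage(raster=np.zeros((32, 32, 3), dtype=np.uint8), id="black")
    assert not peripheral_mask(img).any()


def test_bright_image_is_fully_valid():
    img = LabeledImage(raster=np.full((32, 32, 3), 120, dtype=np.uint8), id="bright")
    assert peripheral_mask(img).all()


def test_interior_dark_pixels_stay_valid():
    raster = np.full((32, 32, 3), 120, dtype=np.uint8)
    raster[14:18, 14:18] = 0  # lumen shadow, not border-connected
    img = LabeledImage(raster=raster, id="shadow")
    assert peripheral_mask(img).all()


# ---------------------------------------------------------------- color


def test_pure_red_maps_to_hsv_origin():
    out, channels = convert_colorspace(_single_pixel_image((255, 0, 0)), "HSV")
    assert channels == ("H", "S", "V")
    np.testing.assert_allclose(out[0, 0], [0.0, 1.0, 1.0], atol=1e-12)


def test_white_is_achromatic_in_yiq():
    out, _ = convert_colorspace(_single_pixel_image((255, 255, 255)), "YIQ")
    np.testing.assert_allclose(out[0, 0, 1:], [0.0, 0.0], atol=1e-7)


def test_lab_roundtrip_error_below_one_8bit_unit(rng):
    pixels = rng.integers(0, 256, size=(1000, 1, 3)).astype(np.uint8)
    img = LabeledImage(raster=pixels, id="rand")
    lab, _ = convert_colorspace(img, "LAB")
    back = np.clip(skcolor.lab2rgb(lab) * 255.0, 0, 255)
    assert np.max(np.abs(back - pixels[..., :3].astype(float))) <= 1.0


def test_cmyk_has_four_channels_and_black_maps_to_k_one():
    out, channels = convert_colorspace(_single_pixel_image((0, 0, 0)), "CMYK")
    assert channels == ("C", "M", "Y", "K")
    np.testing.assert_allclose(out[0, 0], [0.0, 0.0, 0.0, 1.0], atol=1e-12)


def test_unknown_space_error_lists_valid_names():
    with pytest.raises(ValueError, match="XYZ"):
        convert_colorspace(_single_pixel_image((1, 2, 3)), "XYZ")


# ---------------------------------------------------------------- MLE fits


@pytest.mark.parametrize(
    "family, samples, expected",
    [
        ("normal", [0.0, 2.0], (1.0, 1.0)),
        ("rayleigh", [2.0, 2.0], (np.sqrt(2.0),)),
        ("exponential", [1.0, 2.0, 3.0], (2.0,)),
    ],
)
def test_closed_form_mle_hand_examples(family, samples, expected):
    fit = fit_pdf(np.array(samples), family)
    np.testing.assert_allclose(fit.params, expected, rtol=0, atol=1e-12)


@pytest.mark.parametrize("family", FAMILIES)
def test_empty_samples_yield_the_zero_sentinel(family):
    fit = fit_pdf(np.array([]), family)
    assert fit.params == (0.0,) * params_per_fit(family)


def test_rayleigh_parameter_recovery_by_simulation(rng):
    x = stats.rayleigh.rvs(scale=3.0, size=100_000, random_state=rng)
    fit = fit_pdf(x, "rayleigh")
    assert abs(fit.params[0] - 3.0) < 0.02


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.5, 200.0), min_size=2, max_size=50))
def test_mle_agrees_with_scipy_fit(values):
    """Dual route: closed forms vs scipy's numeric MLE (location fixed at 0)."""
    x = np.array(values)
    mu, sigma = fit_pdf(x, "normal").params
    s_mu, s_sigma = stats.norm.fit(x)
    np.testing.assert_allclose((mu, sigma), (s_mu, s_sigma), rtol=1e-6, atol=1e-6)
    (ray,) = fit_pdf(x, "rayleigh").params
    _, s_ray = stats.rayleigh.fit(x, floc=0)
    np.testing.assert_allclose(ray, s_ray, rtol=1e-4)
    (expo,) = fit_pdf(x, "exponential").params
    _, s_expo = stats.expon.fit(x, floc=0)
    np.testing.assert_allclose(expo, s_expo, rtol=1e-6)


# ---------------------------------------------------------------- features


@pytest.mark.parametrize("space", COLOR_SPACES)
@pytest.mark.parametrize("family", FAMILIES)
def test_feature_length_law(small_bank, small_config, space, family):
    """length = M x C x p for every space and family."""
    img = generate_image("U", small_config, seed=4)
    fv = extract_features(img, small_bank, family, space)
    n_channels = 4 if space == "CMYK" else 3
    assert len(fv) == small_bank.M * n_channels * params_per_fit(family)
    # scale parameters are never negative
    scale_entries = [v for v, (_, _, name) in zip(fv.values, fv.layout) if name != "mu"]
    assert np.all(np.asarray(scale_entries) >= 0)


def test_empty_roi_contributes_an_all_zero_block(small_config):
    img = generate_image("N", small_config, seed=6)
    bank = ModelBank([_none_pass_model(), _all_pass_model()])
    fv = extract_features(img, bank, "normal", "RGB")
    assert np.all(fv.values[:6] == 0.0)
    assert np.any(fv.values[6:] != 0.0)


def test_constant_roi_yields_mu_c_sigma_zero():
    img = LabeledImage(raster=np.full((16, 16, 3), 77, dtype=np.uint8), id="c")
    bank = ModelBank([_all_pass_model()])
    fv = extract_features(img, bank, "normal", "RGB")
    np.testing.assert_allclose(fv.values, [77.0, 0.0] * 3, atol=1e-12)


def test_count_features_agree_with_brute_force(small_bank, small_config):
    from wcemlda import predict_pixels

    img = generate_image("B", small_config, seed=8)
    valid = peripheral_mask(img)
    fv = count_features(img, small_bank, valid)
    assert len(fv) == small_bank.M
    for k, model in enumerate(small_bank):
        expected = sum(
            1
            for i in range(img.shape[0])
            for j in range(img.shape[1])
            if valid[i, j]
            and float(model.weight @ img.raster[i, j].astype(float)) > model.threshold
        )
        assert fv.values[k] == expected


def test_same_class_count_tracks_true_lesion_size(small_config, small_bank):
    """In the separable regime a same-class model count is within 10% of
    the true mask size (the model may also respond to other diseases'
    pixels, so the check uses a normal background-only image plus lesion)."""
    img = generate_image("B", small_config, seed=12)
    fv = count_features(img, small_bank)
    b_indices = [k for k, m in enumerate(small_bank) if m.source_class == "B"]
    best = max(fv.values[k] for k in b_indices)
    truth = img.mask.sum()
    assert abs(best - truth) <= 0.10 * truth


def test_stat_features_hand_example():
    raster = np.zeros((1, 3, 3), dtype=np.uint8)
    raster[0, :, 0] = [1, 2, 2]  # R channel samples {1, 2, 2}
    img = LabeledImage(raster=raster, id="s")
    bank = ModelBank([_all_pass_model()])
    fv = stat_features(img, bank, "RGB", valid=np.ones((1, 3), dtype=bool))
    r_stats = fv.values[:4]  # mean, median, mode, sd of R
    np.testing.assert_allclose(
        r_stats, [5 / 3, 2.0, 2.0, np.sqrt(2 / 9)], atol=1e-12
    )


def test_stat_features_match_numpy_oracle(rng, small_config, small_bank):
    img = generate_image("T", small_config, seed=9)
    valid = peripheral_mask(img)
    fv = stat_features(img, small_bank, "RGB", valid)
    from wcemlda import predict_pixels

    for k, model in enumerate(small_bank):
        roi = predict_pixels(model, img, valid).mask
        for c in range(3):
            x = img.raster[..., c][roi].astype(float)
            got = fv.values[k * 12 + c * 4 : k * 12 + c * 4 + 4]
            if x.size == 0:
                np.testing.assert_array_equal(got, 0.0)
                continue
            vals, counts = np.unique(x, return_counts=True)
            expected = [x.mean(), np.median(x), vals[np.argmax(counts)], x.std()]
            np.testing.assert_allclose(got, expected, atol=1e-12)


def test_whole_image_features_equal_full_field_roi_fit(small_config):
    img = generate_image("U", small_config, seed=10)
    bank = ModelBank([_all_pass_model()])
    via_roi = extract_features(img, bank, "normal", "RGB")
    direct = whole_image_features(img, "normal", "RGB")
    np.testing.assert_allclose(direct.values, via_roi.values, atol=1e-12)


def test_permuting_bank_order_permutes_feature_blocks(small_bank, small_config):
    img = generate_image("B", small_config, seed=13)
    fv = extract_features(img, small_bank, "normal", "RGB")
    perm = list(reversed(range(small_bank.M)))
    permuted_bank = ModelBank([small_bank[k] for k in perm])
    fv_perm = extract_features(img, permuted_bank, "normal", "RGB")
    p = 6  # 3 channels x 2 params per model block
    for new_pos, old_pos in enumerate(perm):
        np.testing.assert_array_equal(
            fv_perm.values[new_pos * p : (new_pos + 1) * p],
            fv.values[old_pos * p : (old_pos + 1) * p],
        )


def test_mle_bias_below_one_percent_at_large_n():
    """Consistency: mean fitted parameter over 100 replicates of n = 1e4."""
    rng = np.random.default_rng(314)
    n, reps = 10_000, 100
    est = {"normal_mu": [], "normal_sigma": [], "rayleigh": [], "exponential": []}
    for _ in range(reps):
        x = rng.normal(50.0, 12.0, n)
        mu, sigma = fit_pdf(x, "normal").params
        est["normal_mu"].append(mu)
        est["normal_sigma"].append(sigma)
        est["rayleigh"].append(fit_pdf(stats.rayleigh.rvs(scale=3.0, size=n, random_state=rng), "rayleigh").params[0])
        est["exponential"].append(fit_pdf(rng.exponential(7.0, n), "exponential").params[0])
    truth = {"normal_mu": 50.0, "normal_sigma": 12.0, "rayleigh": 3.0, "exponential": 7.0}
    for key, values in est.items():
        bias = abs(np.mean(values) - truth[key]) / truth[key]
        assert bias < 0.01, key
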