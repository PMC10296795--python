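"""Contrast-spatial-frequency decision pipeline versus brute-force oracles."""

import math

import numpy as np
import pytest

from ffoafuse.bandpass_fusion import (
    consistency_verify,
    csf_decision_map,
    fuse_bandpass_subband,
    remove_small_regions,
    spatial_frequency,
)
from ffoafuse.exceptions import ConfigurationError, DimensionError, ValidationError

from _oracles import (
    area_open_bruteforce,
    local_mean_bruteforce,
    majority_bruteforce,
    sf_bruteforce,
)


# ------------------------------------------------------- spatial frequency
def test_sf_constant_subband_is_zero():
    sal = spatial_frequency(np.full((20, 20), 0.7), 7, 7)
    assert np.abs(sal.S).max() == 0.0
    assert np.abs(sal.RF).max() == 0.0 and np.abs(sal.CF).max() == 0.0


def test_sf_vertical_stripes_have_no_column_gradient():
    H = np.tile(np.sin(np.arange(24) * 0.7), (24, 1))  # varies along columns only
    sal = spatial_frequency(H, 5, 5)
    assert np.abs(sal.CF).max() == 0.0
    np.testing.assert_allclose(sal.S, sal.RF, atol=1e-15)


@pytest.mark.parametrize("literal", [True, False])
def test_sf_matches_double_loop_oracle(literal):
    H = np.random.default_rng(0).random((9, 9))
    sal = spatial_frequency(H, 7, 7, literal_formulas=literal)
    S_ref, RF_ref, CF_ref = sf_bruteforce(H, 7, 7, literal=literal)
    np.testing.assert_allclose(sal.RF, RF_ref, atol=1e-12)
    np.testing.assert_allclose(sal.CF, CF_ref, atol=1e-12)
    np.testing.assert_allclose(sal.S, S_ref, atol=1e-12)


def test_sf_invariant_s_combines_components():
    H = np.random.default_rng(1).random((16, 16))
    sal = spatial_frequency(H, 5, 3)
    np.testing.assert_allclose(sal.S, np.sqrt(sal.RF**2 + sal.CF**2), atol=1e-15)
    assert (sal.S >= 0).all()


def test_sf_window_validation():
    with pytest.raises(ConfigurationError):
        spatial_frequency(np.zeros((16, 16)), 4, 7)
    with pytest.raises(DimensionError):
        spatial_frequency(np.zeros((5, 5)), 7, 7)
    with pytest.raises(ValidationError):
        spatial_frequency(np.full((16, 16), np.nan), 7, 7)


# --------------------------------------------------------------- CSF map
def test_csf_trivial_cases():
    ones = np.ones((12, 12))
    zeros = np.zeros((12, 12))
    np.testing.assert_array_equal(csf_decision_map(ones, zeros, 3, 3), np.ones((12, 12)))
    # ties (identical constants) fail the strict inequality
    np.testing.assert_array_equal(
        csf_decision_map(0.5 * ones, 0.5 * ones, 3, 3), np.zeros((12, 12))
    )


def test_csf_impulse_against_neighbourhood_mean_oracle():
    SA = np.zeros((11, 11))
    SA[5, 5] = 1.0
    SB = np.full((11, 11), 0.5)
    got = csf_decision_map(SA, SB, 3, 3)
    expected = (SA > local_mean_bruteforce(SB, 3, 3)).astype(np.uint8)
    np.testing.assert_array_equal(got, expected)
    assert got.sum() == 1 and got[5, 5] == 1


@pytest.mark.parametrize("seed", range(3))
def test_csf_random_fields_match_oracle(seed):
    rng = np.random.default_rng(seed)
    SA = rng.random((15, 13))
    SB = rng.random((15, 13))
    got = csf_decision_map(SA, SB, 5, 3)
    expected = (SA > local_mean_bruteforce(SB, 5, 3)).astype(np.uint8)
    np.testing.assert_array_equal(got, expected)


# ----------------------------------------------------------- area opening
def test_area_threshold_is_strictly_smaller_than():
    m = np.zeros((40, 40), dtype=np.uint8)
    thr = math.ceil(0.05 * m.size)  # 80
    m[:8, :10] = 1  # area exactly 80: preserved
    np.testing.assert_array_equal(remove_small_regions(m, 0.05), m)
    m2 = np.zeros((40, 40), dtype=np.uint8)
    m2[:8, :10] = 1
    m2[0, 9] = 0  # area 79: removed
    assert remove_small_regions(m2, 0.05, fill_background=False).sum() == 0


def test_blobs_and_hole_against_labelling_oracle():
    m = np.zeros((100, 100), dtype=np.uint8)  # C = 10000, r=0.05 -> threshold 500
    m[5:25, 5:25] = 1  # 400-px blob: removed
    m[40:70, 40:60] = 1  # 600-px blob: kept
    m[45:65, 45:60] = 1  # grow it so a hole fits inside
    m[50:60, 48:58] = 0  # 100-px hole: filled
    got = remove_small_regions(m, 0.05)
    expected = area_open_bruteforce(m, 0.05, m.size)
    np.testing.assert_array_equal(got, expected)
    assert got[10, 10] == 0 and got[55, 50] == 1


@pytest.mark.parametrize("seed", range(3))
def test_area_opening_random_maps_match_oracle(seed):
    rng = np.random.default_rng(seed)
    m = (rng.random((60, 60)) < 0.5).astype(np.uint8)
    for fill in (True, False):
        got = remove_small_regions(m, 0.01, fill_background=fill)
        np.testing.assert_array_equal(got, area_open_bruteforce(m, 0.01, m.size, fill))


def test_area_opening_validation():
    with pytest.raises(ConfigurationError):
        remove_small_regions(np.zeros((10, 10), dtype=np.uint8), r=1.5)
    with pytest.raises(ValidationError):
        remove_small_regions(np.full((10, 10), 2.0), r=0.05)


# -------------------------------------------------- consistency verification
def test_majority_trivial_cases():
    ones = np.ones((70, 70), dtype=np.uint8)
    np.testing.assert_array_equal(consistency_verify(ones, 59), ones)
    speck = np.zeros((70, 70), dtype=np.uint8)
    speck[35, 35] = 1
    assert consistency_verify(speck, 59).sum() == 0


def test_majority_half_plane_boundary_stability():
    m = np.zeros((30, 30), dtype=np.uint8)
    m[:, :15] = 1
    got = consistency_verify(m, 5)
    expected = majority_bruteforce(m, 5)
    np.testing.assert_array_equal(got, expected)
    # interior columns unchanged; boundary shifts by at most 2 pixels
    np.testing.assert_array_equal(got[:, :13], 1)
    np.testing.assert_array_equal(got[:, 17:], 0)


@pytest.mark.parametrize("seed", range(3))
def test_majority_random_maps_match_box_sum_oracle(seed):
    m = (np.random.default_rng(seed).random((25, 25)) < 0.5).astype(np.uint8)
    np.testing.assert_array_equal(consistency_verify(m, 7), majority_bruteforce(m, 7))


def test_majority_even_window_rejected():
    with pytest.raises(ConfigurationError):
        consistency_verify(np.zeros((10, 10), dtype=np.uint8), 6)


# --------------------------------------------------------- masked combination
def test_masked_combination_cases():
    rng = np.random.default_rng(9)
    HA = rng.random((12, 12))
    HB = rng.random((12, 12))
    np.testing.assert_array_equal(fuse_bandpass_subband(HA, HB, np.ones_like(HA)), HA)
    np.testing.assert_array_equal(fuse_bandpass_subband(HA, HB, np.zeros_like(HA)), HB)
    checker = np.indices(HA.shape).sum(axis=0) % 2
    got = fuse_bandpass_subband(HA, HB, checker)
    np.testing.assert_array_equal(got, np.where(checker == 1, HA, HB))
    # selectivity: every pixel equals exactly one source pixel
    assert np.all((got == HA) | (got == HB))
    with pytest.raises(ValidationError):
        fuse_bandpass_subband(HA, HB, np.full_like(HA, 0.5))
    with pytest.raises(DimensionError):
        fuse_bandpass_subband(HA, HB[:6], np.ones((6, 12)))


# ------------------------------------------------------------ pipeline props
def test_cleanup_pipeline_idempotent_on_clean_maps():
    for m in (
        np.ones((40, 40), dtype=np.uint8),
        np.zeros((40, 40), dtype=np.uint8),
        np.concatenate([np.ones((40, 20), np.uint8), np.zeros((40, 20), np.uint8)], axis=1),
    ):
        once = consistency_verify(remove_small_regions(m, 0.05), 9)
        twice = consistency_verify(remove_small_regions(once, 0.05), 9)
        np.testing.assert_array_equal(once, twice)


def test_cleaned_maps_have_no_small_components():
    from scipy import ndimage

    rng = np.random.default_rng(11)
    m = (rng.random((50, 50)) < 0.5).astype(np.uint8)
    out = remove_small_regions(m, 0.02, fill_background=False)
    thr = math.ceil(0.02 * m.size)
    lab, n = ndimage.label(out, structure=np.ones((3, 3)))
    sizes = np.bincount(lab.ravel())[1:]
    assert np.all(sizes >= thr)
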