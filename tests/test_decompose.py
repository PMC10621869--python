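"""Wavelet sub-band split and empirical mode decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wemd_apnea.decompose import (NotEnoughExtrema, dwt_subbands, emd,
                                  find_extrema, idwt_reconstruct, sift,
                                  spline_envelopes)


def _sine(f, fs, n):
    return np.sin(2 * np.pi * f * np.arange(n) / fs)


def _zero_crossings(z):
    s = np.sign(z[z != 0])
    return int(np.count_nonzero(np.diff(s) != 0))


# ---------------------------------------------------------------- DWT

def test_constant_input_goes_to_approximation_band():
    sb = dwt_subbands(np.full(512, 3.0))
    for d in (sb.d4, sb.d3, sb.d2, sb.d1):
        assert np.max(np.abs(d)) < 1e-10
    assert np.max(np.abs(sb.a4)) > 1.0


def test_round_trip_reconstruction(rng):
    x = rng.normal(size=777)
    sb = dwt_subbands(x)
    np.testing.assert_allclose(idwt_reconstruct(sb), x, atol=1e-8)


def test_12hz_tone_energy_concentrates_in_alpha_band():
    x = _sine(12.0, 64.0, 3840)
    sb = dwt_subbands(x)
    energy = sb.band_energy()
    assert energy["d3"] / sum(energy.values()) >= 0.8


def test_too_short_input_raises_with_minimum_length():
    with pytest.raises(ValueError, match="minimum"):
        dwt_subbands(np.zeros(64))


def test_band_lengths_follow_dyadic_halving():
    sb = dwt_subbands(np.zeros(3840))
    assert len(sb.d1) > len(sb.d2) > len(sb.d3) > len(sb.d4)
    assert len(sb.a4) == len(sb.d4)


# ---------------------------------------------------------------- extrema

def test_monotone_vector_has_no_interior_extrema():
    minima, maxima = find_extrema(np.arange(50.0))
    assert len(minima) == 0 and len(maxima) == 0


def test_single_period_sine_has_one_max_one_min():
    z = _sine(1.0, 100.0, 100)
    minima, maxima = find_extrema(z)
    assert len(maxima) == 1 and len(minima) == 1


def test_plateau_center_counted_once():
    z = np.array([0.0, 1.0, 1.0, 1.0, 0.0, -1.0, -1.0, 0.0])
    minima, maxima = find_extrema(z)
    assert list(maxima) == [2]
    assert len(minima) == 1


def _brute_force_extrema(z):
    """Independent exhaustive scan (plateaus collapsed to run centers)."""
    runs = []
    start = 0
    for i in range(1, len(z)):
        if z[i] != z[start]:
            runs.append((start, i - 1))
            start = i
    runs.append((start, len(z) - 1))
    minima, maxima = [], []
    for j in range(1, len(runs) - 1):
        prev_v = z[runs[j - 1][0]]
        cur_v = z[runs[j][0]]
        next_v = z[runs[j + 1][0]]
        center = (runs[j][0] + runs[j][1]) // 2
        if cur_v > prev_v and cur_v > next_v:
            maxima.append(center)
        elif cur_v < prev_v and cur_v < next_v:
            minima.append(center)
    return np.array(minima), np.array(maxima)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_find_extrema_matches_brute_force(seed):
    z = np.random.default_rng(seed).normal(size=100)
    got_min, got_max = find_extrema(z)
    exp_min, exp_max = _brute_force_extrema(z)
    np.testing.assert_array_equal(got_min, exp_min)
    np.testing.assert_array_equal(got_max, exp_max)


# ---------------------------------------------------------------- envelopes

def test_envelopes_interpolate_signal_at_their_knots(rng):
    z = rng.normal(size=200)
    minima, maxima = find_extrema(z)
    env = spline_envelopes(z, (minima, maxima))
    np.testing.assert_allclose(env.upper[maxima], z[maxima], atol=1e-9)
    np.testing.assert_allclose(env.lower[minima], z[minima], atol=1e-9)


def test_sinusoid_mean_envelope_near_zero():
    z = _sine(4.0, 64.0, 640)          # 40 periods
    env = spline_envelopes(z)
    interior = slice(32, -32)
    assert np.max(np.abs(env.mean[interior])) < 0.05


def test_insufficient_extrema_signals_caller():
    with pytest.raises(NotEnoughExtrema):
        spline_envelopes(np.arange(30.0))


# ---------------------------------------------------------------- sifting/EMD

def test_sift_fixed_point_for_clean_imf():
    z = _sine(8.0, 64.0, 640)
    imf, n_sifts, ok = sift(z)
    assert ok
    interior = slice(32, -32)
    np.testing.assert_allclose(imf[interior], z[interior], atol=0.05)


def test_first_imf_captures_fastest_tone():
    n, fs = 1280, 64.0
    fast = _sine(16.0, fs, n)
    z = _sine(2.0, fs, n) + fast
    imf, _, ok = sift(z)
    assert ok
    r = np.corrcoef(imf, fast)[0, 1]
    assert abs(r) > 0.95


def test_monotone_input_flagged_as_residue():
    z = np.linspace(0.0, 1.0, 100)
    out, n_sifts, ok = sift(z)
    assert not ok
    np.testing.assert_array_equal(out, z)


def test_emd_reconstruction_identity(rng):
    z = rng.normal(size=600)
    dec = emd(z)
    err = np.abs(dec.reconstruct() - z).max() / np.abs(z).max()
    assert err < 1e-9


def test_emd_returns_five_imf_slots(rng):
    dec = emd(rng.normal(size=400))
    assert len(dec.imfs) == 5
    assert all(len(i) == 400 for i in dec.imfs)


def test_emd_constant_input_warns_and_pads():
    with pytest.warns(UserWarning):
        dec = emd(np.full(300, 2.0))
    assert dec.padded
    assert all(np.all(i == 0) for i in dec.imfs)
    np.testing.assert_array_equal(dec.residue, np.full(300, 2.0))


def test_imfs_ordered_fine_to_coarse(rng):
    dec = emd(rng.normal(size=1000))
    zc = [_zero_crossings(i) for i in dec.imfs[:3]]
    assert zc[0] > zc[1] > zc[2]


def test_emd_early_stop_pads_with_zeros():
    # two tones only: expect <=3 meaningful IMFs, the rest zero-padded
    z = _sine(16.0, 64.0, 640) + _sine(2.0, 64.0, 640)
    dec = emd(z)
    assert len(dec.imfs) == 5
    np.testing.assert_allclose(dec.reconstruct(), z, atol=1e-9)


def test_emd_deterministic(rng):
    z = rng.normal(size=500)
    a = emd(z.copy())
    b = emd(z.copy())
    for x, y in zip(a.imfs, b.imfs):
        np.testing.assert_array_equal(x, y)
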