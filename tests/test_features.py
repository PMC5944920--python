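"""Laplacian, Welch band power, Fisher score, discriminancy and CVA."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sp_signal

from bciloop import (DiscriminancyMap, EEGRecording, cva_rank_features,
                     discriminancy_map, fisher_score, laplacian_filter,
                     region_discriminancy, welch_band_power)
from bciloop.features import (LATERAL_BETA, MEDIAL_BETA, MEDIAL_MU,
                              n_windows)
from bciloop.montage import DEFAULT_CHANNELS, default_laplacian_map

from conftest import make_feature_matrix

FS = 512.0


def _rec(samples, channels):
    return EEGRecording(samples, FS, channels)


# ---------------------------------------------------------------- Laplacian

def test_laplacian_common_mode_removal():
    """Identical constant on all channels zeroes fully-neighbored sites and,
    in general, adding a common offset leaves the output unchanged."""
    n = len(DEFAULT_CHANNELS)
    rec = _rec(np.full((100, n), 7.3), DEFAULT_CHANNELS)
    out = laplacian_filter(rec)
    lap = default_laplacian_map(DEFAULT_CHANNELS)
    for ch in DEFAULT_CHANNELS:
        col = out.channel(ch)
        expected = 0.0 if lap[ch] else 7.3
        np.testing.assert_allclose(col, expected)

    rng = np.random.default_rng(0)
    x = rng.standard_normal((50, n))
    shifted = laplacian_filter(_rec(x + 3.3, DEFAULT_CHANNELS))
    base = laplacian_filter(_rec(x, DEFAULT_CHANNELS))
    neighbored = [i for i, ch in enumerate(DEFAULT_CHANNELS) if lap[ch]]
    np.testing.assert_allclose(shifted.samples[:, neighbored],
                               base.samples[:, neighbored], atol=1e-12)


def test_laplacian_single_source_toy_montage():
    """A lone source keeps its value; neighbors subtract their share."""
    channels = ("Cz", "FCz", "CPz")
    lap = {"Cz": ("FCz", "CPz"), "FCz": ("Cz",), "CPz": ("Cz",)}
    x = np.zeros((10, 3))
    x[:, 0] = 2.0  # only Cz active
    out = laplacian_filter(_rec(x, channels), lap)
    np.testing.assert_allclose(out.channel("Cz"), 2.0)
    np.testing.assert_allclose(out.channel("FCz"), -2.0)
    np.testing.assert_allclose(out.channel("CPz"), -2.0)


def test_laplacian_empty_map_identity_and_errors():
    channels = ("Cz", "FCz")
    x = np.random.default_rng(1).standard_normal((20, 2))
    out = laplacian_filter(_rec(x, channels), {})
    np.testing.assert_array_equal(out.samples, x)
    with pytest.raises(ValueError):
        laplacian_filter(_rec(x, channels), {"C3": ("Cz",)})
    with pytest.raises(ValueError):
        laplacian_filter(_rec(x, channels), {"Cz": ("Cz",)})


# ------------------------------------------------------------------- Welch

@pytest.mark.parametrize("t_s,expected", [(10.0, 145), (1.0, 1), (2.0, 17)])
def test_window_count_formula(t_s, expected):
    assert n_windows(int(t_s * FS), FS) == expected
    rec = _rec(np.zeros((int(t_s * FS), 1)), ("Cz",))
    fm = welch_band_power(rec)
    assert fm.n_windows == expected


def test_too_short_recording_warns_empty():
    rec = _rec(np.zeros((100, 1)), ("Cz",))
    with pytest.warns(UserWarning):
        fm = welch_band_power(rec)
    assert fm.n_windows == 0


def test_pure_tone_peaks_in_its_bin():
    t = np.arange(int(3 * FS)) / FS
    rec = _rec(np.sin(2 * np.pi * 24.0 * t)[:, None] * 40, ("Cz",))
    fm = welch_band_power(rec)
    band_of_max = [fm.feature_index[i][1]
                   for i in np.argmax(fm.values, axis=1)]
    assert all(b == 24.0 for b in band_of_max)


def test_white_noise_spectrum_is_flat():
    rng = np.random.default_rng(7)
    rec = _rec(rng.standard_normal((int(60 * FS), 1)), ("Cz",))
    fm = welch_band_power(rec, log=False)
    p1 = fm.column("Cz", 20.0).mean()
    p2 = fm.column("Cz", 36.0).mean()
    assert abs(p1 / p2 - 1.0) < 0.05


def test_welch_matches_scipy_reference():
    """One full window reproduces scipy's Welch estimate bin for bin."""
    rng = np.random.default_rng(3)
    x = rng.standard_normal(512)
    fm = welch_band_power(_rec(x[:, None], ("Cz",)), log=False)
    f_ref, p_ref = sp_signal.welch(x, fs=FS, window="hann", nperseg=256,
                                   noverlap=128, detrend=False)
    for ch, band in fm.feature_index:
        k = int(band / 2.0)
        np.testing.assert_allclose(fm.values[0, fm.feature_index.index(
            (ch, band))], p_ref[k], rtol=1e-10)


# ------------------------------------------------------------ Fisher score

def test_fisher_score_hand_computed_values():
    assert fisher_score([1, 2, 3], [1, 2, 3]) == 0.0
    # mu1=1, mu2=0, s1=s2=1 -> 1/sqrt(2)
    h = np.sqrt(2) / 2
    np.testing.assert_allclose(
        fisher_score([1 - h, 1 + h], [-h, h]), 1 / np.sqrt(2), rtol=1e-12
    )
    # sample-variance (n-1) convention
    np.testing.assert_allclose(
        fisher_score([1, 2, 3, 4], [3, 4, 5, 6]),
        2.0 / np.sqrt(10.0 / 3.0), rtol=1e-12,
    )


def test_fisher_score_degenerate_inputs():
    assert fisher_score([2.0, 2.0], [2.0, 2.0]) == 0.0
    with pytest.warns(UserWarning):
        assert fisher_score([1.0, 1.0], [2.0, 2.0]) == np.inf
    with pytest.raises(ValueError):
        fisher_score([1.0], [1.0, 2.0])


@given(
    a=st.floats(min_value=0.1, max_value=50).flatmap(
        lambda v: st.sampled_from([v, -v])),
    b=st.floats(min_value=-100, max_value=100),
    seed=st.integers(0, 100),
)
def test_fisher_score_affine_invariance_and_symmetry(a, b, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(20) + 1.0
    y = rng.standard_normal(20)
    base = fisher_score(x, y)
    np.testing.assert_allclose(fisher_score(a * x + b, a * y + b), base,
                               rtol=1e-9)
    np.testing.assert_allclose(fisher_score(y, x), base, rtol=1e-12)


# ------------------------------------------------------- Discriminancy map

def test_discriminancy_map_localizes_planted_effect(mi_run_strong):
    cfg, (eeg, _, labels) = mi_run_strong
    dm = discriminancy_map(welch_band_power(eeg, labels=labels))
    beta_cols = [dm.bands.index(b) for b in dm.bands if 22 <= b <= 32]
    per_channel = dm.scores[:, beta_cols].max(axis=1)
    assert dm.channels[int(np.argmax(per_channel))] == "Cz"


def test_discriminancy_map_label_shuffle_collapses(mi_run_strong):
    cfg, (eeg, _, labels) = mi_run_strong
    fm = welch_band_power(eeg, labels=labels)
    rng = np.random.default_rng(0)
    shuffled = fm.labels.copy()
    rng.shuffle(shuffled)
    from bciloop import FeatureMatrix

    fm_sh = FeatureMatrix(fm.values, fm.window_times, fm.feature_index,
                          labels=shuffled)
    true_max = discriminancy_map(fm).scores.max()
    null_max = discriminancy_map(fm_sh).scores.max()
    assert null_max < true_max / 3


def test_discriminancy_map_symmetry_and_identical_classes():
    from bciloop import FeatureMatrix

    rng = np.random.default_rng(5)
    block = rng.standard_normal((40, 4))
    values = np.vstack([block, block])
    labels = np.array(["both_hands"] * 40 + ["both_feet"] * 40, dtype=object)
    index = [("cA", 20.0), ("cA", 22.0), ("cB", 20.0), ("cB", 22.0)]
    fm = FeatureMatrix(values, np.arange(80) * 0.0625, index, labels=labels)
    dm = discriminancy_map(fm)
    np.testing.assert_allclose(dm.scores, 0.0, atol=1e-12)
    swapped = discriminancy_map(fm, classes=("both_feet", "both_hands"))
    np.testing.assert_array_equal(dm.scores, swapped.scores)


def test_discriminancy_map_missing_class():
    fm = make_feature_matrix(np.zeros((4, 2)), ["both_hands"] * 4)
    with pytest.raises(ValueError):
        discriminancy_map(fm)


# ----------------------------------------------------------------- Regions

def _map_from_grid(channels, bands, scores):
    return DiscriminancyMap(tuple(channels), tuple(bands),
                            np.asarray(scores, dtype=float),
                            ("both_hands", "both_feet"), (10, 10))


def test_region_mean_constant_map():
    bands = tuple(float(b) for b in range(4, 50, 2))
    dm = _map_from_grid(DEFAULT_CHANNELS, bands,
                        np.full((len(DEFAULT_CHANNELS), len(bands)), 0.37))
    for region in (MEDIAL_MU, MEDIAL_BETA, LATERAL_BETA):
        np.testing.assert_allclose(region_discriminancy(dm, region), 0.37)


def test_region_cell_enumeration():
    """Medial beta averages exactly 3 channels x 6 bins (22..32 inclusive)."""
    bands = tuple(float(b) for b in range(4, 50, 2))
    scores = np.zeros((len(DEFAULT_CHANNELS), len(bands)))
    cells = [(c, b) for c in ("FCz", "Cz", "CPz")
             for b in (22.0, 24.0, 26.0, 28.0, 30.0, 32.0)]
    for k, (c, b) in enumerate(cells):
        scores[DEFAULT_CHANNELS.index(c), bands.index(b)] = 0.2 + 0.2 * k
    dm = _map_from_grid(DEFAULT_CHANNELS, bands, scores)
    expected = np.mean([0.2 + 0.2 * k for k in range(18)])
    np.testing.assert_allclose(region_discriminancy(dm, MEDIAL_BETA),
                               expected, rtol=1e-12)
    # mu region: 8-14 Hz inclusive = 4 bins
    assert len([b for b in bands if 8 <= b <= 14]) == 4


def test_region_empty_raises():
    dm = _map_from_grid(("Cz",), (24.0,), [[1.0]])
    from bciloop import RegionSpec

    with pytest.raises(ValueError):
        region_discriminancy(dm, RegionSpec("x", ("C3",), (22.0, 32.0)))


# --------------------------------------------------------------------- CVA

def test_cva_top_ranks_planted_feature():
    rng = np.random.default_rng(11)
    x1 = rng.standard_normal((100, 8))
    x2 = rng.standard_normal((100, 8))
    x1[:, 3] += 2.0
    fm = make_feature_matrix(np.vstack([x1, x2]),
                             ["both_hands"] * 100 + ["both_feet"] * 100)
    ranking = cva_rank_features(fm)
    assert ranking.order[0] == 3


def test_cva_agrees_with_fisher_on_uncorrelated_features():
    rng = np.random.default_rng(13)
    shifts = [0.0, 1.5, 0.5, 3.0, 0.1]
    x1 = rng.standard_normal((400, 5)) + np.asarray(shifts)
    x2 = rng.standard_normal((400, 5))
    fm = make_feature_matrix(np.vstack([x1, x2]),
                             ["both_hands"] * 400 + ["both_feet"] * 400)
    ranking = cva_rank_features(fm)
    fisher_order = np.argsort(-np.asarray(shifts), kind="stable")
    np.testing.assert_array_equal(ranking.order[:3], fisher_order[:3])


def test_cva_duplicate_column_tie_break():
    rng = np.random.default_rng(17)
    base = rng.standard_normal((60, 1))
    noise = rng.standard_normal((60, 1))
    values = np.hstack([base, base, noise])
    values[:30, :2] += 1.5
    fm = make_feature_matrix(values, ["both_hands"] * 30 + ["both_feet"] * 30)
    ranking = cva_rank_features(fm)
    # duplicated informative columns tie; lower index ranks first
    assert list(ranking.order[:2]) == [0, 1]
    np.testing.assert_allclose(ranking.scores[0], ranking.scores[1],
                               rtol=1e-8)
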