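"""Band-profile and correlation-map feature extraction and normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preictal.features import (
    BANDS,
    BandProfile,
    CorrelationMap,
    StftConfig,
    band_profile,
    build_baseline_profiles,
    correlation_map,
    normalize,
    validate_bands,
)
from preictal.synthetic import SynthSpec, generate_recording

from conftest import make_epoch

FS = 256.0


def tone_epoch(freqs, amps=None, duration=10.0, channels=3):
    t = np.arange(0, duration, 1 / FS)
    amps = amps or [1.0] * len(freqs)
    sig = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
    return make_epoch(np.tile(sig, (channels, 1)))


def direct_dft_band_profile(epoch, cfg=None):
    """Independent oracle: windowed DFT frame by frame, no scipy.signal.stft.

    Matches the production path's frame layout (no boundary padding, hop =
    nperseg - noverlap) and scaling (magnitude normalized by the window sum).
    """
    cfg = cfg or StftConfig()
    from scipy.signal.windows import hann

    win = hann(cfg.nperseg, sym=False)
    hop = cfg.nperseg - cfg.noverlap
    x = epoch.data
    n_frames = (x.shape[1] - cfg.nperseg) // hop + 1
    freqs = np.fft.rfftfreq(cfg.nperseg, d=1 / epoch.fs)
    rows = {name: np.zeros(n_frames) for name in BANDS}
    for t in range(n_frames):
        seg = x[:, t * hop : t * hop + cfg.nperseg] * win
        mag = np.abs(np.fft.rfft(seg, axis=1)) / win.sum()
        for name, (lo, hi) in BANDS.items():
            mask = (freqs >= lo) & (freqs < hi)
            rows[name][t] = mag[:, mask].mean()
    return np.array([rows[name] for name in BANDS])


def test_pure_alpha_tone_dominates_alpha_row():
    """A 10 Hz tone lands in the alpha row at every time step."""
    bp = band_profile(tone_epoch([10.0]))
    assert bp.values.shape == (5, 19)
    alpha = bp.values[list(BANDS).index("alpha")]
    for i, name in enumerate(BANDS):
        if name != "alpha":
            assert (alpha > bp.values[i]).all()


def test_zero_signal_gives_zero_profile():
    bp = band_profile(make_epoch(np.zeros((3, 2560))))
    assert np.allclose(bp.values, 0.0)


def test_band_profile_matches_direct_dft_oracle():
    """The production STFT band profile equals an independent windowed-DFT
    computation on a 10 Hz + 20 Hz equal-amplitude mixture."""
    epoch = tone_epoch([10.0, 20.0])
    bp = band_profile(epoch)
    oracle = direct_dft_band_profile(epoch)
    np.testing.assert_allclose(bp.values, oracle, rtol=1e-7, atol=1e-12)
    # each tone dominates its own band; bands without a tone stay near zero
    alpha, beta = bp.values[2], bp.values[3]
    rest = bp.values[[0, 1, 4]]
    assert alpha.mean() > 10 * rest.mean()
    assert beta.mean() > 10 * rest.mean()


def test_band_profile_amplitude_equivariance():
    """Scaling the signal by k scales every profile entry by k."""
    epoch = tone_epoch([10.0, 20.0])
    base = band_profile(epoch).values
    for k in (0.5, 3.0, 17.0):
        scaled = band_profile(make_epoch(k * epoch.data))
        # absolute floor covers rows holding only spectral-leakage residue
        np.testing.assert_allclose(
            scaled.values, k * base, rtol=1e-10, atol=1e-12 * k * base.max()
        )


def test_band_above_nyquist_rejected():
    with pytest.raises(ValueError, match="Nyquist"):
        validate_bands({"hf": (200.0, 300.0)}, FS)


def test_epoch_shorter_than_window_rejected():
    with pytest.raises(ValueError, match="window"):
        band_profile(make_epoch(np.zeros((2, 100))))


# -- correlation maps ------------------------------------------------------


def test_identical_channels_give_all_ones():
    x = np.tile(np.sin(np.linspace(0, 40, 2560)), (4, 1))
    cm = correlation_map(make_epoch(x))
    np.testing.assert_allclose(cm.values, 1.0)


def test_anticorrelated_channel_gives_minus_one():
    base = np.sin(np.linspace(0, 40, 2560))
    cm = correlation_map(make_epoch(np.vstack([base, -base])))
    assert cm.values[0, 1] == pytest.approx(-1.0)


def test_independent_noise_under_null_bound():
    """|r| for independent channels stays below ~2/sqrt(n) x 2 at n=2560."""
    rng = np.random.default_rng(4)
    cm = correlation_map(make_epoch(rng.standard_normal((2, 2560))))
    assert abs(cm.values[0, 1]) < 0.08


def test_zero_variance_channel_guarded():
    rng = np.random.default_rng(5)
    x = rng.standard_normal((3, 2560))
    x[1] = 2.5  # constant channel: correlation undefined
    cm = correlation_map(make_epoch(x))
    assert cm.n_zero_variance == 1
    assert np.allclose(cm.values[1, [0, 2]], 0.0)
    assert cm.values[1, 1] == 1.0


def test_correlation_invariant_to_positive_affine_rescale():
    rng = np.random.default_rng(6)
    x = rng.standard_normal((4, 2000))
    cm1 = correlation_map(make_epoch(x))
    y = x * np.array([[2.0], [0.5], [7.0], [1.3]]) + np.array([[5.0], [-3.0], [0.1], [9.0]])
    cm2 = correlation_map(make_epoch(y))
    np.testing.assert_allclose(cm1.values, cm2.values, atol=1e-12)


# -- baseline profiles and normalization -----------------------------------


def baseline_epochs(n=4, seed=0):
    spec = SynthSpec(n_channels=3, duration_s=n * 10.0, seed=seed)
    rec = generate_recording(spec)
    step = int(10 * FS)
    return [
        make_epoch(rec.signal[:, k * step : (k + 1) * step], label=0, t0=k * 10.0)
        for k in range(n)
    ]


def test_identical_epochs_mean_equals_any_one():
    e = baseline_epochs(1)[0]
    bset = build_baseline_profiles([e, e, e])
    np.testing.assert_allclose(bset.mean_band_profile, band_profile(e).values)
    assert bset.n_profiles_used == 3


def test_two_epoch_mean_is_exact_average():
    e1, e2 = baseline_epochs(2)
    bset = build_baseline_profiles([e1, e2])
    expected = (band_profile(e1).values + band_profile(e2).values) / 2
    np.testing.assert_allclose(bset.mean_band_profile, expected)


def test_requesting_more_profiles_than_available_warns():
    eps = baseline_epochs(3)
    with pytest.warns(UserWarning, match="only 3"):
        bset = build_baseline_profiles(eps, n_profiles=1000)
    assert bset.n_profiles_used == 3


def test_baseline_profiles_input_validation():
    with pytest.raises(ValueError, match="no baseline"):
        build_baseline_profiles([])
    eps = baseline_epochs(2)
    eps[1].label = 1
    with pytest.raises(ValueError, match="label-0"):
        build_baseline_profiles(eps)


def test_self_normalization_is_all_ones():
    """An epoch equal to the baseline mean normalizes to exactly 1."""
    e = baseline_epochs(1)[0]
    bset = build_baseline_profiles([e])
    out = normalize(band_profile(e), bset)
    np.testing.assert_allclose(out.values, 1.0)
    out_c = normalize(correlation_map(e), bset)
    np.testing.assert_allclose(out_c.values, 1.0)


def test_doubled_profile_normalizes_to_two():
    e = baseline_epochs(1)[0]
    bset = build_baseline_profiles([e])
    doubled = band_profile(make_epoch(2 * e.data))
    np.testing.assert_allclose(normalize(doubled, bset).values, 2.0, rtol=1e-9)


def test_zero_baseline_cell_guarded_to_one():
    e = baseline_epochs(1)[0]
    bset = build_baseline_profiles([e])
    bset.mean_band_profile = bset.mean_band_profile.copy()
    bset.mean_band_profile[0, 0] = 0.0
    out = normalize(band_profile(e), bset)
    assert out.values[0, 0] == 1.0
    assert out.n_guarded == 1


def test_normalize_shape_mismatch_rejected():
    e = baseline_epochs(1)[0]
    bset = build_baseline_profiles([e])
    bad = BandProfile(np.ones((5, 7)), list(BANDS), 0.5)
    with pytest.raises(ValueError, match="shape"):
        normalize(bad, bset)


def test_normalized_baseline_epochs_center_on_one():
    """Across many baseline epochs the normalized profile averages to ~1
    per cell (Monte-Carlo tolerance)."""
    eps = baseline_epochs(40, seed=8)
    bset = build_baseline_profiles(eps)
    vals = np.mean([normalize(band_profile(e), bset).values for e in eps], axis=0)
    assert np.abs(vals - 1.0).max() < 0.05


@given(st.integers(min_value=0, max_value=2**20))
def test_correlation_entries_bounded(seed):
    rng = np.random.default_rng(seed)
    cm = correlation_map(make_epoch(rng.standard_normal((3, 64))))
    assert (cm.values <= 1.0).all() and (cm.values >= -1.0).all()
    np.testing.assert_allclose(cm.values, cm.values.T)
    np.testing.assert_allclose(np.diag(cm.values), 1.0)
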