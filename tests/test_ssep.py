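import numpy as np
import pytest

from beatssep import dirichlet
from beatssep.ssep import (
    EpochSet,
    SSEPExtractor,
    amplitude_spectrum,
    average_reference,
    epoch_extract,
    highpass,
    noise_subtract,
    target_amplitude,
    trial_average,
)

FS = 1000.0
N32 = 32000


def _epochs(data, fs=FS):
    return EpochSet(np.asarray(data, dtype=float), fs)


# ---------------------------------------------------------------- referencing
def test_average_reference_two_channels_closed_form(rng):
    a, b = rng.standard_normal((2, 500))
    out = average_reference(_epochs([[a, b]])).data[0]
    np.testing.assert_allclose(out[0], (a - b) / 2, atol=1e-14)
    np.testing.assert_allclose(out[1], (b - a) / 2, atol=1e-14)


def test_average_reference_idempotent_and_zero_mean(rng):
    data = rng.standard_normal((3, 8, 1000))
    once = average_reference(_epochs(data))
    assert np.max(np.abs(once.data.mean(axis=1))) < 1e-10
    twice = average_reference(once)
    np.testing.assert_allclose(twice.data, once.data, atol=1e-14)


def test_average_reference_rejects_single_channel():
    with pytest.raises(ValueError, match="2 channels"):
        average_reference(_epochs(np.zeros((1, 1, 100))))


# ------------------------------------------------------------------ filtering
def test_highpass_rejects_dc():
    x = np.full(40000, 7.3)
    y = highpass(x, FS)
    assert np.max(np.abs(y)) < 1e-3 * 7.3


def test_highpass_passband_and_stopband():
    """2.4 Hz passes within 1%; 0.01 Hz drift is attenuated > 90%."""
    t = np.arange(int(200 * FS)) / FS
    keep = slice(int(50 * FS), int(150 * FS))  # interior, away from edges
    for f, check in ((2.4, lambda r: abs(r - 1) < 0.01),
                     (0.01, lambda r: r < 0.10)):
        x = np.sin(2 * np.pi * f * t)
        y = highpass(x, FS)
        ratio = np.sqrt(np.mean(y[keep] ** 2) / np.mean(x[keep] ** 2))
        assert check(ratio), (f, ratio)


def test_highpass_rejects_too_short_signal():
    with pytest.raises(ValueError, match="short"):
        highpass(np.zeros(10), FS)


# ------------------------------------------------------------------- epoching
@pytest.mark.parametrize("fs,expected", [(1000.0, 32000), (1024.0, 32768)])
def test_epoch_length_and_resolution(fs, expected):
    cont = np.zeros((2, int(36 * fs)))
    ep = epoch_extract(cont, fs)
    assert ep.shape[-1] == expected
    assert fs / expected == pytest.approx(0.03125)


def test_epoch_offsets_and_bounds():
    cont = np.arange(40000, dtype=float)[None, :]
    ep = epoch_extract(cont, FS, stim_onset_s=3.0, start_offset_s=1.0, length_s=2.0)
    assert ep[0, 0] == 4000.0
    with pytest.raises(ValueError, match="exceeds"):
        epoch_extract(cont, FS, stim_onset_s=10.0)


# ------------------------------------------------------------------ averaging
def test_trial_average_basics(rng):
    x = rng.standard_normal((1, 2, 100))
    same = np.concatenate([x] * 5)
    np.testing.assert_allclose(trial_average(_epochs(same)), x[0], atol=1e-14)
    np.testing.assert_allclose(
        trial_average(_epochs(np.concatenate([x, -x]))), 0.0, atol=1e-14
    )


def test_trial_average_noise_shrinks_as_sqrt_n(rng):
    sigma, n_trials = 2.0, 10
    noise = rng.normal(0, sigma, size=(n_trials, 1, 200000))
    resid = trial_average(_epochs(noise))
    assert resid.std() == pytest.approx(sigma / np.sqrt(n_trials), rel=0.05)


# ------------------------------------------------------------------- spectrum
def test_amplitude_spectrum_exact_bin_identity():
    t = np.arange(N32) / FS
    k = 64  # 2.0 Hz exactly on a bin
    x = 0.1 * np.sin(2 * np.pi * (k * FS / N32) * t)
    spec = amplitude_spectrum(x, FS)
    assert spec.amps[0, k] == pytest.approx(0.1, abs=1e-12)
    others = np.delete(spec.amps[0], k)
    assert np.max(others) < 1e-10


def test_amplitude_spectrum_constant_is_dc_only():
    spec = amplitude_spectrum(np.full(N32, 3.0), FS)
    assert spec.amps[0, 0] == pytest.approx(3.0, abs=1e-12)
    assert np.max(spec.amps[0, 1:]) < 1e-10


def test_amplitude_spectrum_off_bin_matches_dirichlet_oracle():
    """Leakage of an off-bin 2.4 Hz sinusoid equals the closed form."""
    amp, f0, phase = 0.1, 2.4, 1.1
    t = np.arange(N32) / FS
    spec = amplitude_spectrum(amp * np.sin(2 * np.pi * f0 * t + phase), FS)
    bins = np.arange(60, 95)
    oracle = dirichlet.sinusoid_bin_amplitudes(amp, f0, phase, FS, N32, bins)
    np.testing.assert_allclose(spec.amps[0, bins], oracle, atol=1e-9)


# ----------------------------------------------------------- noise subtraction
def test_noise_subtract_flat_background_and_isolated_peak():
    freqs = np.fft.rfftfreq(N32, 1 / FS)
    flat = np.full((1, len(freqs)), 0.7)
    from beatssep.ssep import AmplitudeSpectrum

    spec = AmplitudeSpectrum(freqs=freqs, amps=flat.copy(), fs=FS)
    sub = noise_subtract(spec)
    interior = sub.amps[0, 4:-4]
    np.testing.assert_allclose(interior, 0.0, atol=1e-12)

    peak = np.zeros((1, len(freqs)))
    peak[0, 100] = 2.0
    sub2 = noise_subtract(AmplitudeSpectrum(freqs=freqs, amps=peak, fs=FS))
    assert sub2.amps[0, 100] == pytest.approx(2.0)
    for off in (-4, -3, 3, 4):
        assert sub2.amps[0, 100 + off] == pytest.approx(-0.5)
    for off in (-2, -1, 1, 2, 5, -5):
        assert sub2.amps[0, 100 + off] == pytest.approx(0.0, abs=1e-14)


def test_noise_subtract_refuses_double_application():
    freqs = np.fft.rfftfreq(1000, 1 / FS)
    from beatssep.ssep import AmplitudeSpectrum

    spec = noise_subtract(
        AmplitudeSpectrum(freqs=freqs, amps=np.ones((1, len(freqs))), fs=FS)
    )
    with pytest.raises(ValueError, match="already"):
        noise_subtract(spec)


def test_noise_subtract_unbiased_on_white_noise(rng):
    """Mean corrected amplitude at a fixed bin ~ 0 over 500 realizations."""
    n, reps, k = 4096, 500, 200
    vals = np.empty(reps)
    for i in range(reps):
        spec = amplitude_spectrum(rng.standard_normal(n), FS)
        vals[i] = noise_subtract(spec).amps[0, k]
    se = vals.std(ddof=1) / np.sqrt(reps)
    assert abs(vals.mean()) < 3 * se


# ------------------------------------------------------------ target amplitude
def test_target_amplitude_conventions_and_errors():
    freqs = np.fft.rfftfreq(N32, 1 / FS)
    from beatssep.ssep import AmplitudeSpectrum

    amps = np.zeros((1, len(freqs)))
    spec = AmplitudeSpectrum(freqs=freqs, amps=amps, fs=FS)
    _, val = target_amplitude(spec, 1.2)
    assert val == 0.0
    # nearest-bin convention at 0.03125 Hz resolution
    for f0, k in ((0.8, 26), (1.2, 38), (1.6, 51), (2.4, 77)):
        amps2 = np.zeros((1, len(freqs)))
        amps2[0, k] = 3.0
        _, v = target_amplitude(
            AmplitudeSpectrum(freqs=freqs, amps=amps2, fs=FS), f0)
        assert v == pytest.approx(1.0)  # 3-bin mean of (0, 3, 0)
    with pytest.raises(ValueError, match="outside"):
        target_amplitude(spec, 600.0)


def test_target_amplitude_linear_in_input():
    t = np.arange(N32) / FS
    x = 0.05 * np.sin(2 * np.pi * 1.2 * t + 0.3)
    one = target_amplitude(amplitude_spectrum(x, FS), 1.2)[1]
    two = target_amplitude(amplitude_spectrum(2 * x, FS), 1.2)[1]
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_single_sine_three_bin_matches_closed_form():
    """Noise-free 0.05 uV sinusoid at 1.2 Hz: 3-bin mean == Dirichlet value."""
    amp, f0, phase = 0.05, 1.2, 0.9
    t = np.arange(N32) / FS
    spec = noise_subtract(
        amplitude_spectrum(amp * np.sin(2 * np.pi * f0 * t + phase), FS))
    got = target_amplitude(spec, f0)[1]
    want = dirichlet.three_bin_estimate(amp, f0, phase, FS, N32)
    assert got == pytest.approx(want, abs=1e-9)


# --------------------------------------------------------------- full pipeline
def _multisine_epochs(components, n_trials=3, fs=FS, dur=36.0):
    t = np.arange(int(dur * fs)) / fs
    sig = sum(a * np.sin(2 * np.pi * f * t + p) for a, f, p in components)
    trial = np.stack([sig, -sig])  # zero-mean dipolar pair of channels
    return EpochSet(np.stack([trial] * n_trials), fs)


def test_pipeline_oracle_equivalence_noiseless_multisine(rng):
    """End to end (drift filter off): estimates equal the closed form <=1e-9."""
    components = [
        (rng.uniform(0.01, 0.1), f0, rng.uniform(0, 2 * np.pi))
        for f0 in (0.8, 1.2, 1.6, 2.4)
    ]
    epochs = _multisine_epochs(components)
    ext = SSEPExtractor(fs=FS, hp_cutoff=None)
    vals = ext.transform(epochs)
    shifted = [(a, f, p + 2 * np.pi * f * ext.start_offset_s)
               for a, f, p in components]
    for f0, got in zip(ext.freqs_, vals):
        want = dirichlet.multi_sine_three_bin(shifted, f0, FS, N32)
        assert got == pytest.approx(want, abs=1e-9)


def test_drift_filter_leaves_stimulus_frequency_intact(rng):
    """With the 0.1 Hz filter on, the 2.4 Hz estimate moves < 1%."""
    components = [(0.07, 2.4, rng.uniform(0, 2 * np.pi))]
    epochs = _multisine_epochs(components)
    off = SSEPExtractor(fs=FS, hp_cutoff=None, target_freqs=(2.4,)).transform(epochs)
    on = SSEPExtractor(fs=FS, target_freqs=(2.4,)).transform(epochs)
    assert on[0] == pytest.approx(off[0], rel=0.01)


def test_pipeline_homogeneous_of_degree_one(rng):
    components = [(0.05, 1.2, 0.4), (0.07, 2.4, 1.3)]
    epochs = _multisine_epochs(components)
    ext = SSEPExtractor(fs=FS, hp_cutoff=None)
    base = ext.transform(epochs)
    scaled = ext.transform(EpochSet(epochs.data * 3.0, FS))
    np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-10)


def test_pipeline_invariant_to_trial_order(rng):
    data = rng.standard_normal((5, 2, int(36 * FS)))
    ext = SSEPExtractor(fs=FS)
    a = ext.transform(EpochSet(data, FS))
    b = ext.transform(EpochSet(data[::-1].copy(), FS))
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_subject_table_runs_over_dataset(tmp_path, tiny_cfg):
    from beatssep.cli_io import write_csv  # noqa: F401  (import check)
    from beatssep.ssep import subject_ssep_table
    from beatssep.synthdata import simulate_multilab

    simulate_multilab(tiny_cfg, seed=11, outdir=tmp_path)
    table = subject_ssep_table(tmp_path)
    # labs x subjects x conditions x frequencies
    assert len(table) == 1 * 2 * 3 * 4
    assert set(table["condition"]) == {"control", "binary", "ternary"}
    assert table.attrs["incomplete"] == []
    # removing one condition file flags the subject but keeps the rest
    (tmp_path / "lab_01" / "sub_001" / "ternary.h5").unlink()
    table2 = subject_ssep_table(tmp_path)
    assert len(table2) == 5 * 4
    assert table2.attrs["incomplete"] == [("lab_01", "sub_001", "ternary")]
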