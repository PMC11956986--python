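"""Closed-form spectral leakage of rectangular-windowed sinusoids.

The DFT of a finite sinusoid whose frequency does not coincide with a bin
spreads deterministically across bins according to the Dirichlet kernel.
These closed forms are evaluated directly from the geometric-sum identity,
with no FFT, so they serve as an independent route against which the
FFT-based spectrum pipeline can be checked to machine precision.  The
target frequencies used here (0.8/1.2/1.6/2.4 Hz) are deliberately not
integer multiples of the 1/32 s resolution, so leakage is part of the
measured quantity, not an artifact.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "dirichlet_sum",
    "sinusoid_bin_amplitudes",
    "multi_sinusoid_bin_amplitudes",
    "three_bin_estimate",
    "multi_sine_three_bin",
]


def dirichlet_sum(theta: np.ndarray, n: int) -> np.ndarray:
    """sum_{j=0}^{n-1} exp(i*theta*j), stable near theta = 0 mod 2pi."""
    theta = np.asarray(theta, dtype=float)
    half = theta / 2.0
    sin_half = np.sin(half)
    with np.errstate(divide="ignore", invalid="ignore"):
        mag = np.where(
            np.abs(sin_half) < 1e-12, float(n), np.sin(n * half) / sin_half
        )
    return np.exp(1j * half * (n - 1)) * mag


def sinusoid_bin_amplitudes(
    amp: float,
    f0: float,
    phase: float,
    fs: float,
    n_samples: int,
    bins: np.ndarray,
) -> np.ndarray:
    """Single-sided amplitude (2|X_k|/N) of ``amp*sin(2 pi f0 t + phase)``.

    Both the positive- and negative-frequency images contribute to each
    bin, which matters at tight tolerances even far from ``f0``.
    """
    bins = np.atleast_1d(np.asarray(bins, dtype=int))
    omega = 2.0 * np.pi * f0 / fs
    theta_k = 2.0 * np.pi * bins / n_samples
    # sin = (e^{i(wn+p)} - e^{-i(wn+p)}) / 2i
    pos = np.exp(1j * phase) * dirichlet_sum(omega - theta_k, n_samples)
    neg = np.exp(-1j * phase) * dirichlet_sum(-omega - theta_k, n_samples)
    x_k = amp * (pos - neg) / 2j
    scale = np.where((bins == 0) | (2 * bins == n_samples), 1.0, 2.0)
    return scale * np.abs(x_k) / n_samples


def multi_sinusoid_bin_amplitudes(
    components,
    fs: float,
    n_samples: int,
    bins: np.ndarray,
) -> np.ndarray:
    """Single-sided amplitudes of a sum of sinusoids (amp, freq, phase).

    Complex bin values add across components before the magnitude is
    taken, so mutual leakage between components is handled exactly.
    """
    bins = np.atleast_1d(np.asarray(bins, dtype=int))
    theta_k = 2.0 * np.pi * bins / n_samples
    total = np.zeros(len(bins), dtype=complex)
    for amp, f0, phase in components:
        omega = 2.0 * np.pi * f0 / fs
        pos = np.exp(1j * phase) * dirichlet_sum(omega - theta_k, n_samples)
        neg = np.exp(-1j * phase) * dirichlet_sum(-omega - theta_k, n_samples)
        total += amp * (pos - neg) / 2j
    scale = np.where((bins == 0) | (2 * bins == n_samples), 1.0, 2.0)
    return scale * np.abs(total) / n_samples


def multi_sine_three_bin(
    components,
    f0: float,
    fs: float,
    n_samples: int,
    noise_subtracted: bool = True,
    neighbor_offsets=(-4, -3, 3, 4),
) -> float:
    """3-bin (noise-subtracted) estimate at ``f0`` for a sum of sinusoids."""
    df = fs / n_samples
    k0 = round(f0 / df)
    target_bins = np.array([k0 - 1, k0, k0 + 1])
    if not noise_subtracted:
        return float(np.mean(
            multi_sinusoid_bin_amplitudes(components, fs, n_samples, target_bins)
        ))
    corrected = []
    for k in target_bins:
        neigh = np.array([k + o for o in neighbor_offsets])
        neigh = neigh[(neigh >= 0) & (neigh <= n_samples // 2)]
        amps = multi_sinusoid_bin_amplitudes(
            components, fs, n_samples, np.concatenate(([k], neigh))
        )
        corrected.append(amps[0] - np.mean(amps[1:]))
    return float(np.mean(corrected))


def three_bin_estimate(
    amp: float,
    f0: float,
    phase: float,
    fs: float,
    n_samples: int,
    noise_subtracted: bool = True,
    neighbor_offsets=(-4, -3, 3, 4),
) -> float:
    """Closed-form value of the 3-bin SSEP estimate for a pure sinusoid.

    Mirrors the pipeline's estimator — optional neighbor-bin noise
    subtraction followed by the mean over the three bins centred on the
    nearest bin to ``f0`` — but computed entirely from the Dirichlet
    closed form.
    """
    df = fs / n_samples
    k0 = round(f0 / df)
    target_bins = np.array([k0 - 1, k0, k0 + 1])
    if noise_subtracted:
        corrected = []
        for k in target_bins:
            neigh = np.array([k + o for o in neighbor_offsets])
            neigh = neigh[(neigh >= 0) & (neigh <= n_samples // 2)]
            amps = sinusoid_bin_amplitudes(
                amp, f0, phase, fs, n_samples, np.concatenate(([k], neigh))
            )
            corrected.append(amps[0] - np.mean(amps[1:]))
        return float(np.mean(corrected))
    amps = sinusoid_bin_amplitudes(amp, f0, phase, fs, n_samples, target_bins)
    return float(np.mean(amps))
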