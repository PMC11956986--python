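"""Synthesis of the beat-ambiguous auditory stimulus.

The stimulus is a 333.3 Hz pure tone amplitude-modulated at 2.4 Hz with an
asymmetric Hanning envelope (22 ms half-cosine rise, 394 ms half-cosine
fall, zero-padded to the 2.4 Hz period so the AM rate is exact), then
amplitude-modulated by an 11 Hz sinusoid that introduces a pseudo-periodic
fine structure.  A 3 s stretch of the modulated waveform is appended to the
33 s base, and an 880 Hz / 40 ms probe tone can be summed in at either the
binary-beat or ternary-beat position near the end of the trial.

All waveforms are unitless sound-pressure sequences in [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "StimulusSpec",
    "Waveform",
    "build_envelope",
    "synthesize_stimulus",
    "add_probe",
    "add_interruption",
    "write_stimulus_wavs",
]


@dataclass(frozen=True)
class StimulusSpec:
    """All synthesis constants for the stimulus.

    Durations are in the units indicated by each field name; ``mod2_depth``
    is the 11 Hz modulation depth ``m`` in ``(1 + m sin(2 pi 11 t))/(1+m)``
    (the modulator's depth is not pinned down by the source description, so
    it is configurable with a default of 0.5).
    """

    carrier_hz: float = 333.3
    am_rate_hz: float = 2.4
    rise_ms: float = 22.0
    fall_ms: float = 394.0
    mod2_hz: float = 11.0
    mod2_depth: float = 0.5
    base_duration_s: float = 33.0
    extension_s: float = 3.0
    probe_hz: float = 880.0
    probe_dur_ms: float = 40.0
    probe_ramp_ms: float = 5.0
    probe_amp: float = 0.5
    probe_onset_binary_s: float = 34.184
    probe_onset_ternary_s: float = 33.732
    extension_source: str = "start"  # which stretch is copied: "start"|"end"
    fs: float = 44100.0

    def validate(self) -> None:
        for name in (
            "carrier_hz", "am_rate_hz", "rise_ms", "fall_ms", "mod2_hz",
            "base_duration_s", "extension_s", "probe_hz", "probe_dur_ms",
            "fs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.mod2_depth <= 1.0:
            raise ValueError("mod2_depth must lie in [0, 1]")
        if self.rise_ms + self.fall_ms > 1000.0 / self.am_rate_hz:
            raise ValueError(
                "rise_ms + fall_ms exceeds one AM period "
                f"({1000.0 / self.am_rate_hz:.3f} ms): the envelope cycle "
                "must fit within the amplitude-modulation period"
            )
        total = self.base_duration_s + self.extension_s
        for onset in (self.probe_onset_binary_s, self.probe_onset_ternary_s):
            if not 0 <= onset < total:
                raise ValueError("probe onset outside the stimulus")
        if self.extension_source not in ("start", "end"):
            raise ValueError("extension_source must be 'start' or 'end'")


@dataclass
class Waveform:
    samples: np.ndarray
    fs: float

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.fs)


def _n_samples(duration_s: float, fs: float) -> int:
    return int(round(duration_s * fs))


def build_envelope(spec: StimulusSpec, duration_s: float) -> Waveform:
    """Tile the asymmetric-Hanning AM envelope over ``duration_s`` seconds.

    One cycle is a half-raised-cosine rise from 0 to 1 over ``rise_ms``,
    an immediate half-raised-cosine fall back to 0 over ``fall_ms``, then
    zero padding up to the 2.4 Hz AM period; the cycle is evaluated in
    continuous time (``t mod 1/am_rate``) so the AM rate is exact rather
    than rounded to an integer number of samples.
    """
    spec.validate()
    if duration_s <= 0:
        raise ValueError("duration_s must be strictly positive")
    fs = spec.fs
    t = np.arange(_n_samples(duration_s, fs)) / fs
    period = 1.0 / spec.am_rate_hz
    tau = np.mod(t, period)
    rise = spec.rise_ms / 1000.0
    fall = spec.fall_ms / 1000.0
    env = np.zeros_like(tau)
    in_rise = tau < rise
    env[in_rise] = 0.5 - 0.5 * np.cos(np.pi * tau[in_rise] / rise)
    in_fall = (tau >= rise) & (tau < rise + fall)
    env[in_fall] = 0.5 + 0.5 * np.cos(np.pi * (tau[in_fall] - rise) / fall)
    return Waveform(env, fs)


def synthesize_stimulus(spec: StimulusSpec) -> Waveform:
    """Carrier x AM envelope x normalized 11 Hz modulator, plus extension.

    The returned waveform is ``base_duration_s + extension_s`` long; the
    extension is a verbatim copy of ``extension_s`` seconds of the fully
    modulated base waveform (its start by default, configurable).
    """
    spec.validate()
    if spec.fs < 2.0 * spec.carrier_hz:
        raise ValueError(
            f"fs={spec.fs} Hz cannot represent a {spec.carrier_hz} Hz "
            "carrier (aliasing)"
        )
    fs = spec.fs
    n_base = _n_samples(spec.base_duration_s, fs)
    t = np.arange(n_base) / fs
    carrier = np.sin(2.0 * np.pi * spec.carrier_hz * t)
    env = build_envelope(spec, spec.base_duration_s).samples
    m = spec.mod2_depth
    mod2 = (1.0 + m * np.sin(2.0 * np.pi * spec.mod2_hz * t)) / (1.0 + m)
    base = carrier * env * mod2
    n_ext = _n_samples(spec.extension_s, fs)
    ext = base[:n_ext] if spec.extension_source == "start" else base[-n_ext:]
    return Waveform(np.concatenate([base, ext]), fs)


def _probe_burst(spec: StimulusSpec, fs: float) -> np.ndarray:
    """880 Hz tone burst with raised-cosine on/off ramps around the 40 ms."""
    ramp = spec.probe_ramp_ms / 1000.0
    dur = spec.probe_dur_ms / 1000.0
    n = int(math.ceil((dur + 2.0 * ramp) * fs))
    t = np.arange(n) / fs
    # cosine phase so the burst is active from its very first sample
    tone = spec.probe_amp * np.cos(2.0 * np.pi * spec.probe_hz * t)
    gate = np.ones(n)
    n_ramp = int(round(ramp * fs))
    if n_ramp > 0:
        # half-sample offset keeps the gate strictly positive inside the burst
        up = 0.5 - 0.5 * np.cos(np.pi * (np.arange(n_ramp) + 0.5) / n_ramp)
        gate[:n_ramp] = up
        gate[-n_ramp:] = up[::-1]
    return tone * gate


def add_probe(wave: Waveform, spec: StimulusSpec, probe_type: str) -> Waveform:
    """Sum the probe tone onto ``wave`` at the binary or ternary position.

    Samples outside the burst window are untouched; the output is rescaled
    only if the summed waveform would leave [-1, 1].
    """
    spec.validate()
    if probe_type == "binary":
        onset_s = spec.probe_onset_binary_s
    elif probe_type == "ternary":
        onset_s = spec.probe_onset_ternary_s
    else:
        raise ValueError(f"unknown probe_type {probe_type!r}")
    fs = wave.fs
    burst = _probe_burst(spec, fs)
    i0 = int(round(onset_s * fs))
    if i0 + len(burst) > len(wave.samples):
        raise ValueError("probe extends past the end of the waveform")
    out = wave.samples.copy()
    out[i0:i0 + len(burst)] += burst
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    return Waveform(out, fs)


def add_interruption(wave: Waveform, t_s: float, dur_ms: float = 4.0) -> Waveform:
    """Silence a short stretch of the waveform (control-trial catch events)."""
    i0 = int(round(t_s * wave.fs))
    n = int(round(dur_ms / 1000.0 * wave.fs))
    if i0 < 0 or i0 + n > len(wave.samples):
        raise ValueError("interruption outside the waveform")
    out = wave.samples.copy()
    out[i0:i0 + n] = 0.0
    return Waveform(out, wave.fs)


def write_stimulus_wavs(spec: StimulusSpec, outdir) -> dict:
    """Write base/binary-probe/ternary-probe WAVs (float32) to ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = synthesize_stimulus(spec)
    paths = {}
    for name, wav in (
        ("stimulus_base.wav", base),
        ("stimulus_binaryprobe.wav", add_probe(base, spec, "binary")),
        ("stimulus_ternaryprobe.wav", add_probe(base, spec, "ternary")),
    ):
        path = outdir / name
        wavfile.write(path, int(round(spec.fs)), wav.samples.astype(np.float32))
        paths[name] = path
    return paths
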