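"""Synthetic multi-lab EEG and behavior with the structure the analysis assumes.

Two tiers of generator share one population model:

* an EEG-domain tier (:func:`simulate_epochs`, :func:`simulate_multilab`)
  that embeds phase-locked sinusoids at 0.8/1.2/1.6/2.4 Hz in 1/f plus
  white noise, replicated over channels and trials, so the full spectral
  pipeline (epoching, averaging, leakage, noise subtraction) is exercised;
* an amplitude-domain tier (:func:`simulate_subject_amplitudes`) that
  emits the subject-level amplitude estimates the pipeline would produce,
  as true amplitude plus Gaussian measurement noise, cheap enough for
  replicated parameter-recovery studies of the meta-analytic stage.

The population model: each subject owns a baseline SSEP amplitude per
frequency (truncated-at-zero normal across subjects) and imagery adds a
deterministic increment at the congruent frequency (1.2 Hz for binary
imagery, 0.8 Hz for ternary).  Phases are constant across trials within a
subject — the steady-state assumption that makes trial averaging
amplitude-preserving.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ssep import EpochSet, TARGET_FREQS

CONDITIONS = ("control", "binary", "ternary")
# frequency whose amplitude the imagery condition is meant to raise
CONGRUENT_FREQ = {"binary": 1.2, "ternary": 0.8}

__all__ = [
    "CONDITIONS",
    "CONGRUENT_FREQ",
    "SimConfig",
    "SubjectParams",
    "draw_subject",
    "make_pink_noise",
    "simulate_epochs",
    "simulate_behavior",
    "simulate_subject_amplitudes",
    "simulate_multilab",
]


@dataclass
class SimConfig:
    """Population and recording parameters for the simulated study.

    Amplitude defaults mirror the grand pattern of the printed per-lab
    summary: a ~0.07 uV response at the 2.4 Hz stimulus frequency, near-zero
    baseline at the beat frequencies, an imagery-congruent increment of
    0.03 uV, between-subject SDs of ~0.02 uV, and subject-level
    measurement noise of ~0.03 uV after noise subtraction.
    """

    n_labs: int = 13
    subjects_per_lab: int = 16
    trials_imagery: int = 10
    trials_control: int = 12
    n_channels: int = 64
    fs: float = 1000.0
    trial_duration_s: float = 36.0
    freqs: tuple = TARGET_FREQS
    amp_mean: dict = field(
        default_factory=lambda: {0.8: 0.02, 1.2: 0.02, 1.6: 0.02, 2.4: 0.07}
    )
    amp_sd: dict = field(
        default_factory=lambda: {0.8: 0.02, 1.2: 0.02, 1.6: 0.02, 2.4: 0.02}
    )
    imagery_increment: float = 0.03
    harmonic_increment: float = 0.0  # 1.6 Hz during ternary imagery
    measurement_sd: float = 0.03  # amplitude-domain observation noise (uV)
    pink_alpha: float = 1.0
    pink_scale_uv: float = 10.0
    white_scale_uv: float = 2.0
    channel_gains: np.ndarray | None = None
    music_years_mean: float = 4.0
    music_years_sd: float = 5.0
    dance_years_mean: float = 1.5
    dance_years_sd: float = 3.0
    behavior_coefs: dict = field(
        default_factory=lambda: {
            "intercept": 0.2,
            "amp_stimulus": 8.0,  # per uV; the replicated behavioral finding
            "amp_imagery": 0.0,
            "probe_on": 0.0,
            "music_years": 0.0,
            "dance_years": 0.0,
            "imagery_ternary": 0.0,
        }
    )
    rating_cutpoints: tuple = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)
    rating_loc: float = 1.0
    rating_scale: float = 1.0

    def validate(self) -> None:
        for name in ("n_labs", "subjects_per_lab", "trials_imagery",
                     "trials_control", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for f in self.freqs:
            if self.amp_sd[f] < 0 or self.amp_mean[f] < 0:
                raise ValueError("amplitude means/SDs must be >= 0")
        if self.pink_alpha < 0:
            raise ValueError("pink-noise exponent must be >= 0")


@dataclass
class SubjectParams:
    subject_id: str
    lab_id: str
    music_years: float
    dance_years: float
    ssep_amp: dict  # condition -> {freq: amplitude uV}
    ssep_phase: dict  # freq -> radians
    noise_scale: float
    behavior_coefs: dict


def _trunc_normal(mean, sd, rng, size=None):
    """Normal truncated at zero (degenerate at the mean when sd == 0)."""
    if sd == 0:
        return np.full(size, float(mean)) if size else float(mean)
    a = (0.0 - mean) / sd
    out = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                              size=size, random_state=rng)
    return out if size else float(out)


def draw_subject(cfg: SimConfig, lab_id: str, subject_id: str,
                 rng: np.random.Generator) -> SubjectParams:
    """Draw one subject's generating parameters from the population model."""
    cfg.validate()
    base = {f: _trunc_normal(cfg.amp_mean[f], cfg.amp_sd[f], rng)
            for f in cfg.freqs}
    ssep_amp = {c: dict(base) for c in CONDITIONS}
    ssep_amp["binary"][1.2] = base[1.2] + cfg.imagery_increment
    ssep_amp["ternary"][0.8] = base[0.8] + cfg.imagery_increment
    if 1.6 in ssep_amp["ternary"]:
        ssep_amp["ternary"][1.6] = base[1.6] + cfg.harmonic_increment
    phases = {f: float(rng.uniform(0.0, 2.0 * np.pi)) for f in cfg.freqs}
    return SubjectParams(
        subject_id=subject_id,
        lab_id=lab_id,
        music_years=_trunc_normal(cfg.music_years_mean, cfg.music_years_sd, rng),
        dance_years=_trunc_normal(cfg.dance_years_mean, cfg.dance_years_sd, rng),
        ssep_amp=ssep_amp,
        ssep_phase=phases,
        noise_scale=cfg.white_scale_uv,
        behavior_coefs=dict(cfg.behavior_coefs),
    )


def make_pink_noise(n_samples: int, fs: float, alpha: float,
                    rng: np.random.Generator, scale: float = 1.0,
                    f_min: float = 0.1) -> np.ndarray:
    """Zero-mean noise with PSD ~ 1/f^alpha above ``f_min``, by spectral shaping.

    Below ``f_min`` the shaping is held flat at the ``f_min`` value to keep
    the variance finite; DC is removed.  The output is rescaled to standard
    deviation ``scale``.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if alpha < 0:
        raise ValueError("pink-noise exponent must be >= 0")
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    band = freqs >= f_min
    shaping[band] = (freqs[band] / f_min) ** (-alpha / 2.0)
    shaping[0] = 0.0
    out = np.fft.irfft(spec * shaping, n=n_samples)
    sd = out.std()
    if sd > 0:
        out *= scale / sd
    return out


def default_channel_gains(cfg: SimConfig) -> np.ndarray:
    """Zero-mean dipolar topography: alternating +1/-1 channel gains.

    The average reference subtracts the instantaneous channel mean, so a
    channel-uniform signal would be annihilated by re-referencing.  A
    zero-mean gain pattern makes the average reference the identity on
    the SSEP signal and |gain| = 1 everywhere keeps the channel-averaged
    spectral amplitude equal to the generating amplitude.
    """
    if cfg.n_channels == 1:
        return np.ones(1)
    if cfg.n_channels % 2:
        raise ValueError(
            "default dipolar gain map needs an even channel count; "
            "pass channel_gains explicitly for odd layouts"
        )
    return np.tile([1.0, -1.0], cfg.n_channels // 2)


def _signal_for(subj: SubjectParams, condition: str, t: np.ndarray) -> np.ndarray:
    sig = np.zeros_like(t)
    for f, amp in subj.ssep_amp[condition].items():
        sig += amp * np.sin(2.0 * np.pi * f * t + subj.ssep_phase[f])
    return sig


def simulate_epochs(subj: SubjectParams, condition: str, cfg: SimConfig,
                    rng: np.random.Generator) -> EpochSet:
    """EEG-domain trials for one subject x condition.

    Each trial is the subject's multi-sine SSEP signal replicated on every
    channel (times an optional per-channel gain), plus independent pink and
    white noise per channel and trial.  t = 0 is stimulus onset, so the
    returned records still require epoching (1-33 s).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    cfg.validate()
    n_trials = cfg.trials_control if condition == "control" else cfg.trials_imagery
    n = int(round(cfg.trial_duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    sig = _signal_for(subj, condition, t)
    gains = default_channel_gains(cfg) if cfg.channel_gains is None \
        else np.asarray(cfg.channel_gains, dtype=float)
    data = np.empty((n_trials, cfg.n_channels, n))
    for i in range(n_trials):
        for c in range(cfg.n_channels):
            noise = 0.0
            if cfg.pink_scale_uv > 0:
                noise = make_pink_noise(n, cfg.fs, cfg.pink_alpha, rng,
                                        scale=cfg.pink_scale_uv)
            if cfg.white_scale_uv > 0:
                noise = noise + rng.normal(0.0, cfg.white_scale_uv, size=n)
            data[i, c] = gains[c] * sig + noise
    return EpochSet(data=data, fs=cfg.fs, condition=condition)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_behavior(subj: SubjectParams, cfg: SimConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Trial-level probe responses for the two imagery conditions.

    Accuracy is Bernoulli with a logistic link on the subject's amplitudes
    and covariates; the imagery-success rating follows an ordered-logit
    cut-point model on a 1-7 scale.  Probe positions (binary/ternary beat)
    are balanced within each block; a probe is ON beat when its position
    matches the imagery being performed.
    """
    b = subj.behavior_coefs
    rows = []
    for imagery in ("binary", "ternary"):
        amp_im = subj.ssep_amp[imagery][CONGRUENT_FREQ[imagery]]
        amp_st = subj.ssep_amp[imagery][2.4]
        n = cfg.trials_imagery
        probe_pos = np.array(["binary", "ternary"] * ((n + 1) // 2))[:n]
        rng.shuffle(probe_pos)
        for trial, pos in enumerate(probe_pos):
            on_beat = pos == imagery
            lp = (
                b["intercept"]
                + b["amp_stimulus"] * amp_st
                + b["amp_imagery"] * amp_im
                + b["probe_on"] * float(on_beat)
                + b["music_years"] * subj.music_years
                + b["dance_years"] * subj.dance_years
                + b["imagery_ternary"] * float(imagery == "ternary")
            )
            acc = int(rng.random() < _sigmoid(lp))
            latent = cfg.rating_loc + cfg.rating_scale * rng.logistic()
            rating = 1 + int(np.sum(latent > np.asarray(cfg.rating_cutpoints)))
            rows.append(
                {
                    "lab_id": subj.lab_id,
                    "subject_id": subj.subject_id,
                    "condition": imagery,
                    "trial": trial,
                    "probe_type": "ON" if on_beat else "OFF",
                    "accuracy": acc,
                    "rating": rating,
                }
            )
    return pd.DataFrame(rows)


def simulate_subject_amplitudes(cfg: SimConfig,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Amplitude-domain tier: observed subject-level SSEP estimates.

    Returns the same tidy schema the EEG pipeline emits (lab_id,
    subject_id, condition, frequency_hz, amplitude_uv), with
    observed = true subject amplitude + N(0, measurement_sd).  Observed
    values may be negative, as noise-subtracted spectra are.
    """
    cfg.validate()
    rows = []
    for li in range(cfg.n_labs):
        lab_id = f"lab_{li + 1:02d}"
        for si in range(cfg.subjects_per_lab):
            subj = draw_subject(cfg, lab_id, f"sub_{si + 1:03d}", rng)
            for cond in CONDITIONS:
                for f in cfg.freqs:
                    obs = subj.ssep_amp[cond][f] + rng.normal(0.0, cfg.measurement_sd)
                    rows.append(
                        {
                            "lab_id": lab_id,
                            "subject_id": subj.subject_id,
                            "condition": cond,
                            "frequency_hz": f,
                            "amplitude_uv": obs,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_multilab(cfg: SimConfig, seed: int, outdir) -> "pd.DataFrame":
    """Write a full on-disk dataset: epoch HDF5 files plus per-lab CSVs.

    Layout: ``lab_XX/sub_YYY/<condition>.h5`` with per-lab ``behavior.csv``
    and ``participants.csv``.  Fully reproducible from ``seed``.
    Returns the combined participants table.
    """
    from pathlib import Path

    from . import cli_io

    cfg.validate()
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants_all = []
    for li in range(cfg.n_labs):
        lab_id = f"lab_{li + 1:02d}"
        lab_dir = outdir / lab_id
        behavior = []
        participants = []
        for si in range(cfg.subjects_per_lab):
            subject_id = f"sub_{si + 1:03d}"
            subj = draw_subject(cfg, lab_id, subject_id, rng)
            sub_dir = lab_dir / subject_id
            sub_dir.mkdir(parents=True, exist_ok=True)
            for cond in CONDITIONS:
                epochs = simulate_epochs(subj, cond, cfg, rng)
                cli_io.save_epochs(sub_dir / f"{cond}.h5", epochs)
            behavior.append(simulate_behavior(subj, cfg, rng))
            participants.append(
                {
                    "lab_id": lab_id,
                    "subject_id": subject_id,
                    "tested": True,
                    "excluded_reason": "none",
                    "music_years": subj.music_years,
                    "dance_years": subj.dance_years,
                }
            )
        cli_io.write_csv(pd.concat(behavior, ignore_index=True),
                         lab_dir / "behavior.csv")
        part = pd.DataFrame(participants)
        cli_io.write_csv(part, lab_dir / "participants.csv")
        participants_all.append(part)
    return pd.concat(participants_all, ignore_index=True)
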