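"""Synthetic multi-subject iEEG with preictal/ictal structure.

Each subject gets a 2-minute, 400 Hz recording per channel with seizure
onset centered at 60 s. The preictal half is 1/f^beta background noise
(beta ~ 1) plus subject-specific alpha (~10 Hz) and theta (~6 Hz) rhythms.
The ictal half adds band-limited noise in configurable bands (beta /
low-gamma / high-gamma power gains) and a periodic train of sharp
discharges (~3 Hz) whose amplitude ramps up after onset — enough ictal
structure for band-power, PLHG and Benford-conformity metrics to separate
the halves, without pretending to be a biophysical neural-mass model.

Determinism: recordings depend only on (seed, subject_index, channel);
subject-level parameters are drawn once per subject so channels within a
subject share rhythm frequencies and amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ConfigError
from .spectral import BANDS

_HIGHEST_BAND_EDGE = max(hi for _, hi in BANDS.values())


def _default_gains() -> dict[str, float]:
    return {"beta": 3.0, "low_gamma": 8.0, "high_gamma": 5.0}


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the study conditions."""

    n_subjects: int = 10
    channels_per_subject: int = 4
    sample_rate: float = 400.0
    duration: float = 120.0
    onset_time: float = 60.0
    seed: int = 0
    ictal_band_gain: dict[str, float] = field(default_factory=_default_gains)
    discharge_rate: float = 3.0
    discharge_amp: float = 60.0
    subject_variability: float = 0.1
    line_noise_amp: float = 0.0
    line_freq: float = 60.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.channels_per_subject < 1:
            raise ConfigError("n_subjects and channels_per_subject must be >= 1")
        if self.sample_rate <= 2 * _HIGHEST_BAND_EDGE:
            raise ConfigError(
                f"sample_rate must exceed {2 * _HIGHEST_BAND_EDGE} Hz "
                "(twice the highest band edge)"
            )
        if not (0 < self.onset_time < self.duration):
            raise ConfigError("onset_time must lie strictly inside (0, duration)")
        for band, gain in self.ictal_band_gain.items():
            if band not in BANDS:
                raise ConfigError(f"unknown band in ictal_band_gain: {band!r}")
            if gain <= 0:
                raise ConfigError("all ictal band gains must be > 0")
        if self.discharge_rate <= 0:
            raise ConfigError("discharge_rate must be > 0")
        if self.discharge_amp < 0:
            raise ConfigError("discharge_amp must be >= 0")
        if self.subject_variability < 0:
            raise ConfigError("subject_variability must be >= 0")


@dataclass
class Recording:
    """A (channels x time) iEEG segment with an annotated seizure onset."""

    samples: np.ndarray
    sample_rate: float
    onset_sample: int
    subject_id: str
    channel_ids: list[str]
    montage_tag: str = "common-reference"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("recording samples must be finite")
        if not (0 <= self.onset_sample < self.samples.shape[1]):
            raise ConfigError("onset_sample outside the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate


def _subject_params(config: SyntheticConfig, subject_index: int) -> dict:
    rng = np.random.default_rng([config.seed, subject_index, 17])
    v = config.subject_variability

    def jitter(center, spread):
        return center * (1.0 + spread * v * rng.standard_normal())

    return {
        "alpha_freq": float(np.clip(jitter(10.0, 1.0), 8.2, 11.8)),
        "theta_freq": float(np.clip(jitter(6.0, 1.0), 4.2, 7.8)),
        "alpha_amp": abs(jitter(6.0, 2.0)),
        "theta_amp": abs(jitter(4.0, 2.0)),
        "bg_scale": abs(jitter(20.0, 1.0)),
        "discharge_rate": float(np.clip(jitter(config.discharge_rate, 1.0), 2.0, 4.0)),
        "discharge_amp": abs(jitter(config.discharge_amp, 1.5)),
    }


def _one_over_f(rng: np.random.Generator, n: int, beta: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^beta noise of length n."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = f[1:] ** (-beta / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


def _discharge_wavelet(fs: float) -> np.ndarray:
    """Biphasic sharp transient ~40 ms wide (Gaussian derivative)."""
    half = int(0.05 * fs)
    t = np.arange(-half, half + 1) / fs
    sigma = 0.008
    w = -t / sigma ** 2 * np.exp(-(t ** 2) / (2 * sigma ** 2))
    return w / np.abs(w).max()


def generate_recording(config: SyntheticConfig, subject_index: int) -> Recording:
    """All channels of one synthetic subject as a multichannel Recording."""
    fs = config.sample_rate
    n = int(round(config.duration * fs))
    onset = int(round(config.onset_time * fs))
    t = np.arange(n) / fs
    params = _subject_params(config, subject_index)

    channels = []
    for ch in range(config.channels_per_subject):
        rng = np.random.default_rng([config.seed, subject_index, 101 + ch])
        x = params["bg_scale"] * _one_over_f(rng, n)
        x += params["alpha_amp"] * np.sin(
            2 * np.pi * params["alpha_freq"] * t + rng.uniform(0, 2 * np.pi)
        )
        x += params["theta_amp"] * np.sin(
            2 * np.pi * params["theta_freq"] * t + rng.uniform(0, 2 * np.pi)
        )

        # Ictal band-limited noise: target power = (gain - 1) x the baseline
        # band power, so ictal/preictal band-power ratio ~ gain.
        ramp = np.clip((t - config.onset_time) / 1.0, 0.0, 1.0)  # 1 s onset ramp
        for band, gain in config.ictal_band_gain.items():
            lo, hi = BANDS[band]
            sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
            base_var = signal.sosfiltfilt(sos, x[:onset]).var()
            if gain <= 1 or base_var == 0:
                continue
            nb = signal.sosfiltfilt(sos, rng.standard_normal(n))
            nb *= np.sqrt((gain - 1.0) * base_var / nb.var())
            x += nb * ramp

        # Rhythmic discharges with a 10 s amplitude ramp after onset.
        wavelet = _discharge_wavelet(fs)
        train = np.zeros(n)
        period = 1.0 / params["discharge_rate"]
        times = np.arange(config.onset_time + 0.2, config.duration - 0.1, period)
        times += rng.normal(0.0, 0.01, size=times.shape)
        amp_ramp = np.clip((times - config.onset_time) / 10.0, 0.05, 1.0)
        for tt, aa in zip(times, amp_ramp):
            train[int(round(tt * fs))] += aa
        x += params["discharge_amp"] * np.convolve(train, wavelet, mode="same")

        if config.line_noise_amp > 0:
            x += config.line_noise_amp * np.sin(2 * np.pi * config.line_freq * t)
        channels.append(x)

    subject_id = f"S{subject_index:03d}"
    return Recording(
        samples=np.vstack(channels),
        sample_rate=fs,
        onset_sample=onset,
        subject_id=subject_id,
        channel_ids=[f"{subject_id}-ch{c}" for c in range(len(channels))],
    )


def generate_dataset(config: SyntheticConfig) -> list[Recording]:
    """One single-channel Recording per (subject, channel).

    Subject parameters are drawn once per subject, so recordings within a
    subject share rhythm frequencies and amplitudes.
    """
    out = []
    for s in range(config.n_subjects):
        multi = generate_recording(config, s)
        for c in range(multi.n_channels):
            out.append(
                Recording(
                    samples=multi.samples[c : c + 1],
                    sample_rate=multi.sample_rate,
                    onset_sample=multi.onset_sample,
                    subject_id=multi.subject_id,
                    channel_ids=[multi.channel_ids[c]],
                    montage_tag=multi.montage_tag,
                )
            )
    return out
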