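"""Signal conditioning and 1 s epoching/labeling.

The conditioning chain standardizes any input recording: optional
re-referencing, notch at the line frequency, anti-alias lowpass (passband
edge 180 Hz) + resampling to 400 Hz, a zero-phase FIR high-pass with 1 Hz
passband edge, and cropping to 2 minutes with the seizure onset aligned at
60 s. Epochs are non-overlapping 1 s single-channel segments; every epoch
starting at or after onset is labeled ictal (1), everything before is
preictal (0). A 50%-overlap epoching mode is available for deployment-side
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError
from .synthetic import Recording


@dataclass
class Epoch:
    """A 1 s, single-channel, labeled segment — the unit of computation."""

    samples: np.ndarray
    label: int
    subject_id: str
    channel_id: str
    offset: float  # seconds relative to seizure onset; label 1 iff offset >= 0


@dataclass
class EpochSet:
    """Column-oriented batch of epochs (the in-memory dataset container)."""

    X: np.ndarray  # (n_epochs, n_samples)
    y: np.ndarray  # (n_epochs,) in {0, 1}
    subject_ids: np.ndarray
    channel_ids: np.ndarray
    offsets: np.ndarray
    sample_rate: float = 400.0

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.subject_ids)

    def subset(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.X[mask], self.y[mask], self.subject_ids[mask],
            self.channel_ids[mask], self.offsets[mask], self.sample_rate,
        )

    @classmethod
    def from_epochs(cls, epochs: list[Epoch], sample_rate: float = 400.0):
        return cls(
            X=np.vstack([e.samples for e in epochs]),
            y=np.array([e.label for e in epochs], dtype=np.int64),
            subject_ids=np.array([e.subject_id for e in epochs]),
            channel_ids=np.array([e.channel_id for e in epochs]),
            offsets=np.array([e.offset for e in epochs], dtype=np.float64),
            sample_rate=sample_rate,
        )


def rereference(recording: Recording, montage: str) -> Recording:
    """Re-reference to 'common-average' or keep 'common-reference'."""
    if montage == "common-reference":
        return replace(recording, montage_tag=montage)
    if montage == "common-average":
        samples = recording.samples - recording.samples.mean(axis=0, keepdims=True)
        return replace(recording, samples=samples, montage_tag=montage)
    raise ParameterError(f"unknown montage: {montage!r}")


def notch(recording: Recording, line_freq: float, q: float = 30.0) -> Recording:
    """Zero-phase IIR notch at the mains frequency (50 or 60 Hz)."""
    nyq = recording.sample_rate / 2
    if line_freq >= nyq:
        raise ParameterError(f"line_freq {line_freq} >= Nyquist {nyq}")
    b, a = signal.iirnotch(line_freq, q, fs=recording.sample_rate)
    filtered = signal.filtfilt(b, a, recording.samples, axis=1)
    return replace(recording, samples=filtered)


def _zero_phase_fir(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Centered (zero-phase) FIR convolution along the last axis with
    reflected edge padding to suppress boundary transients."""
    pad = len(h) // 2
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    out = signal.fftconvolve(xp, h.reshape((1,) * (x.ndim - 1) + (-1,)),
                             mode="same", axes=-1)
    return out[..., pad:-pad]


def _lowpass_fir(fs: float, passband_edge: float, stopband_edge: float) -> np.ndarray:
    width = stopband_edge - passband_edge
    numtaps, beta = signal.kaiserord(60.0, width / (fs / 2))
    numtaps |= 1  # odd taps -> type-I linear phase
    cutoff = (passband_edge + stopband_edge) / 2
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs)


def antialias_resample(
    recording: Recording,
    target_rate: float = 400.0,
    passband_edge: float = 180.0,
) -> Recording:
    """Anti-alias lowpass (passband edge 180 Hz, stopband at the target
    Nyquist) followed by polyphase resampling to ``target_rate``."""
    fs = recording.sample_rate
    if fs < target_rate:
        raise ParameterError("upsampling is not supported by this chain")
    stop = target_rate / 2
    if fs == target_rate:
        h = _lowpass_fir(fs, passband_edge, stop)
        return replace(recording, samples=_zero_phase_fir(recording.samples, h))
    from fractions import Fraction

    frac = Fraction(target_rate / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    h = _lowpass_fir(fs * up, passband_edge, stop)
    resampled = signal.resample_poly(recording.samples, up, down, axis=1, window=h * up)
    onset = int(round(recording.onset_sample * up / down))
    return replace(
        recording, samples=resampled, sample_rate=target_rate, onset_sample=onset
    )


def highpass_fir(recording: Recording, passband_edge: float = 1.0) -> Recording:
    """Zero-phase FIR high-pass (linear-phase kernel, centered convolution).

    DC and slow drift below ~0.5 Hz are rejected; tones at and above the
    passband edge pass with no group delay.
    """
    fs = recording.sample_rate
    width = passband_edge / 2  # transition 0.5 -> 1 Hz for the default edge
    numtaps, beta = signal.kaiserord(50.0, width / (fs / 2))
    numtaps |= 1
    cutoff = passband_edge - width / 2
    h = signal.firwin(
        numtaps, cutoff, window=("kaiser", beta), pass_zero=False, fs=fs
    )
    if recording.n_samples < numtaps:
        raise DataError("recording shorter than the high-pass FIR kernel")
    return replace(recording, samples=_zero_phase_fir(recording.samples, h))


def crop_align(
    recording: Recording, total: float = 120.0, onset_at: float = 60.0
) -> Recording:
    """Crop to ``total`` seconds with seizure onset aligned at ``onset_at``."""
    fs = recording.sample_rate
    n_total = int(round(total * fs))
    n_pre = int(round(onset_at * fs))
    start = recording.onset_sample - n_pre
    stop = start + n_total
    if start < 0 or stop > recording.n_samples:
        raise DataError(
            "insufficient context around onset for the requested crop window"
        )
    return replace(
        recording, samples=recording.samples[:, start:stop], onset_sample=n_pre
    )


def epoch_and_label(
    recording: Recording, window: float = 1.0, overlap: float = 0.0
) -> list[Epoch]:
    """Split each channel into labeled ``window``-second epochs.

    ``overlap`` is 0 (non-overlapping, the pretraining format) or 0.5
    (50%-overlap sliding window, the deployment augmentation format).
    Windows are half-open [t, t + window); the epoch starting exactly at
    onset is the first ictal epoch.
    """
    if overlap not in (0, 0.5):
        raise ParameterError("overlap must be 0 or 0.5")
    fs = recording.sample_rate
    w = int(round(window * fs))
    step = int(round(w * (1 - overlap)))
    starts = np.arange(0, recording.n_samples - w + 1, step)
    epochs = []
    for c in range(recording.n_channels):
        for s in starts:
            offset = (s - recording.onset_sample) / fs
            epochs.append(
                Epoch(
                    samples=recording.samples[c, s : s + w].copy(),
                    label=int(s >= recording.onset_sample),
                    subject_id=recording.subject_id,
                    channel_id=recording.channel_ids[c],
                    offset=float(offset),
                )
            )
    return epochs


def build_epochset(
    recordings: list[Recording], window: float = 1.0, overlap: float = 0.0
) -> EpochSet:
    """Epoch every recording and stack into one EpochSet."""
    epochs: list[Epoch] = []
    for rec in recordings:
        epochs.extend(epoch_and_label(rec, window, overlap))
    return EpochSet.from_epochs(epochs, sample_rate=recordings[0].sample_rate)
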