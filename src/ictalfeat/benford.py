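"""First-digit statistics: Benford's law and the Cho-Gaines distance.

Intracranial EEG amplitudes, like many natural measurement sets, spread
their first significant digits approximately as P_d = log10((d+1)/d).
Departure from that logarithmic law is quantified here with the
Cho-Gaines (Euclidean) distance, D = sqrt(N * sum_d (e_d - o_d)^2),
where N is the recording sample rate. Two per-epoch features come out of
this: the distance computed on the raw time-domain samples (TDCG) and on
the FFT magnitude spectrum of the epoch (FDCG).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .errors import DataError, DegenerateEpochError

DIGITS = np.arange(1, 10)


class ChoGainesResult(NamedTuple):
    """Cho-Gaines distance together with the rate factor N used."""

    distance: float
    n_scale: float


def leading_digit(values) -> np.ndarray:
    """First significant decimal digit of ``|values|``, elementwise.

    Zeros map to digit 0 (the construction is undefined at 0); everything
    else maps into {1..9} via ``floor(|e| / 10**floor(log10 |e|))``.

    Parameters
    ----------
    values : array_like
        Finite numeric array of any shape.

    Returns
    -------
    numpy.ndarray of int
        Same shape as the input, entries in {0..9}.
    """
    v = np.abs(np.asarray(values, dtype=np.float64))
    if not np.all(np.isfinite(v)):
        raise DataError("leading_digit requires finite input values")
    out = np.zeros(v.shape, dtype=np.int64)
    nz = v > 0
    if np.any(nz):
        e = np.floor(np.log10(v[nz]))
        d = np.floor(v[nz] / 10.0 ** e).astype(np.int64)
        # Floating-point edge cases: log10 can land one ulp off the exact
        # exponent, giving a ratio of 10 (true digit 1) or below 1 (true 9).
        d[d > 9] = 1
        d[d < 1] = 9
        out[nz] = d
    return out


def digit_distribution(digits) -> np.ndarray:
    """Normalized counts of digits 1..9; zeros are excluded from support.

    Raises
    ------
    DegenerateEpochError
        If no nonzero digit is present.
    """
    d = np.asarray(digits, dtype=np.int64).ravel()
    counts = np.bincount(d[(d >= 1) & (d <= 9)], minlength=10)[1:10]
    total = counts.sum()
    if total == 0:
        raise DegenerateEpochError("no nonzero leading digits in input")
    return counts / total


def benford_expected() -> np.ndarray:
    """Benford probabilities P_d = log10((d+1)/d) for d = 1..9."""
    return np.log10((DIGITS + 1) / DIGITS)


def cho_gaines(observed, expected, n_scale: float) -> ChoGainesResult:
    """Cho-Gaines distance ``sqrt(N * sum((e_i - o_i)**2))``.

    ``n_scale`` is the recording sample rate N; the distance scales as
    sqrt(N) and is symmetric in its two distribution arguments.
    """
    o = np.asarray(observed, dtype=np.float64)
    e = np.asarray(expected, dtype=np.float64)
    if o.shape != (9,) or e.shape != (9,):
        raise DataError("digit distributions must have support {1..9}")
    if n_scale <= 0:
        raise DataError("n_scale must be positive")
    dist = float(np.sqrt(n_scale * np.sum((e - o) ** 2)))
    return ChoGainesResult(distance=dist, n_scale=float(n_scale))


def _digit_counts_rows(digits: np.ndarray) -> np.ndarray:
    """Per-row digit counts (n_rows, 9) for a 2-D digit matrix."""
    n = digits.shape[0]
    offsets = (np.arange(n) * 10)[:, None]
    flat = (digits + offsets).ravel()
    counts = np.bincount(flat, minlength=10 * n).reshape(n, 10)
    return counts[:, 1:10]


def tdcg(epoch, sample_rate: float = 400.0) -> float:
    """Time-domain Cho-Gaines conformity of one epoch's raw samples."""
    dist = digit_distribution(leading_digit(epoch))
    return cho_gaines(dist, benford_expected(), sample_rate).distance


def fdcg(epoch, sample_rate: float = 400.0, squared: bool = False) -> float:
    """Frequency-domain Cho-Gaines conformity of one epoch.

    The digit pool is the one-sided FFT magnitude spectrum with the DC bin
    dropped; set ``squared=True`` to pool squared magnitudes instead.
    """
    x = np.asarray(epoch, dtype=np.float64)
    mag = np.abs(np.fft.rfft(x))[1:]
    if squared:
        mag = mag ** 2
    dist = digit_distribution(leading_digit(mag))
    return cho_gaines(dist, benford_expected(), sample_rate).distance


def tdcg_table(epochs: np.ndarray, sample_rate: float = 400.0) -> np.ndarray:
    """Vectorized TDCG over a (n_epochs, n_samples) matrix."""
    X = np.asarray(epochs, dtype=np.float64)
    counts = _digit_counts_rows(leading_digit(X))
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise DegenerateEpochError("all-zero epoch in batch")
    probs = counts / totals[:, None]
    exp = benford_expected()
    return np.sqrt(sample_rate * np.sum((probs - exp) ** 2, axis=1))


def fdcg_table(epochs: np.ndarray, sample_rate: float = 400.0,
               squared: bool = False) -> np.ndarray:
    """Vectorized FDCG over a (n_epochs, n_samples) matrix."""
    X = np.asarray(epochs, dtype=np.float64)
    mag = np.abs(np.fft.rfft(X, axis=1))[:, 1:]
    if squared:
        mag = mag ** 2
    counts = _digit_counts_rows(leading_digit(mag))
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise DegenerateEpochError("zero spectrum epoch in batch")
    probs = counts / totals[:, None]
    exp = benford_expected()
    return np.sqrt(sample_rate * np.sum((probs - exp) ** 2, axis=1))
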