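"""Band powers, energy ratio / epileptogenicity index, PLHG, and the
16-element engineered feature vector computed per 1 s epoch.

Bands (Hz): delta 2-4, theta 4-8, alpha 8-12, beta 12-30, low gamma 30-80,
high gamma 80-150. Powers come from Welch's method on the epoch (a single
Hann-windowed 400-sample segment at 400 Hz, i.e. a modified periodogram at
1 Hz resolution; a 1 s epoch leaves no room for segment averaging at 2 Hz
band edges). The DC bin is excluded from the total power.

The energy ratio ER = (P_beta + P_lowgamma + P_highgamma) / (P_theta +
P_alpha) is computed on relative band powers; the epileptogenicity index
EI = ER / (N_d - N_0 + 1) reduces to ER for single 1 s epochs, where the
onset-delay terms collapse to one.

PLHG (phase-locked high gamma) measures ictal phase-amplitude coupling:
|mean(A_HFO * exp(i(phi_LF - phi_HFO)))| with the low-frequency composite
band 4-30 Hz (theta+alpha+beta) and the high-frequency composite 30-150 Hz
(low+high gamma), envelope and instantaneous phases from the analytic
(Hilbert) signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import signal

from .benford import fdcg_table, tdcg_table
from .errors import DegenerateEpochError

BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 80.0),
    "high_gamma": (80.0, 150.0),
}
BAND_NAMES = list(BANDS)

#: Canonical order of the 16 engineered features.
ENGINEERED_FEATURE_NAMES = (
    [f"rel_{b}" for b in BAND_NAMES]
    + [f"log_{b}" for b in BAND_NAMES]
    + ["ei", "plhg", "tdcg", "fdcg"]
)


@dataclass(frozen=True)
class BandPowerSet:
    """Absolute Welch band powers of one epoch plus total power (DC excluded)."""

    delta: float
    theta: float
    alpha: float
    beta: float
    low_gamma: float
    high_gamma: float
    total_power: float

    def as_dict(self) -> dict[str, float]:
        return {b: getattr(self, b) for b in BAND_NAMES}


def _welch(X: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    n = X.shape[-1]
    nperseg = min(n, int(round(fs)))
    return signal.welch(X, fs=fs, window="hann", nperseg=nperseg, axis=-1)


def band_power_table(epochs: np.ndarray, fs: float = 400.0) -> pd.DataFrame:
    """Welch band powers for a (n_epochs, n_samples) matrix.

    Returns a DataFrame with one column per band plus ``total`` (all bins
    with f > 0). Band intervals are half-open [lo, hi).
    """
    X = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    f, psd = _welch(X, fs)
    df = f[1] - f[0]
    out = {}
    for name, (lo, hi) in BANDS.items():
        sel = (f >= lo) & (f < hi)
        out[name] = psd[:, sel].sum(axis=1) * df
    out["total"] = psd[:, f > 0].sum(axis=1) * df
    return pd.DataFrame(out)


def welch_band_powers(epoch, fs: float = 400.0) -> BandPowerSet:
    """Band powers of a single epoch."""
    row = band_power_table(np.asarray(epoch)[None, :], fs).iloc[0]
    return BandPowerSet(
        **{b: float(row[b]) for b in BAND_NAMES}, total_power=float(row["total"])
    )


def relative_band_powers(bp: BandPowerSet) -> dict[str, float]:
    """Band powers normalized by total power (DC excluded)."""
    if bp.total_power <= 0:
        raise DegenerateEpochError("zero total power")
    return {b: getattr(bp, b) / bp.total_power for b in BAND_NAMES}


def log_abs_band_powers(bp: BandPowerSet, base: float = 10.0) -> dict[str, float]:
    """log (base 10 by default) of the absolute band powers."""
    vals = {}
    for b in BAND_NAMES:
        p = getattr(bp, b)
        if p <= 0:
            raise DegenerateEpochError(f"non-positive {b} band power")
        vals[b] = np.log(p) / np.log(base)
    return vals


def energy_ratio(rel: dict[str, float]) -> float:
    """ER = (P_beta + P_lowgamma + P_highgamma) / (P_theta + P_alpha)."""
    denom = rel["theta"] + rel["alpha"]
    if denom <= 0:
        raise DegenerateEpochError("zero theta+alpha power in energy ratio")
    return (rel["beta"] + rel["low_gamma"] + rel["high_gamma"]) / denom


def epileptogenicity_index(er: float, n_delay: int = 0) -> float:
    """EI = ER / (N_d - N_0 + 1); ``n_delay`` is N_d - N_0, zero for a
    single 1 s epoch so that EI reduces to the energy ratio."""
    if n_delay < 0:
        raise ValueError("n_delay must be >= 0")
    return er / (n_delay + 1)


def _bandpass_sos(lo: float, hi: float, fs: float, order: int = 4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def plhg_from_components(a_hfo, phi_lf, phi_hfo) -> float:
    """|mean(A_HFO * exp(i(phi_LF - phi_HFO)))| over the epoch samples."""
    a = np.asarray(a_hfo, dtype=np.float64)
    phasor = np.exp(1j * (np.asarray(phi_lf) - np.asarray(phi_hfo)))
    return float(np.abs(np.mean(a * phasor)))


def _plhg_matrix(X: np.ndarray, fs: float, mode: str) -> np.ndarray:
    """Vectorized PLHG over rows of X."""
    if mode == "composite":
        pairs = [((4.0, 30.0), (30.0, 150.0))]
    elif mode == "per_band":
        lf_bands = [BANDS["theta"], BANDS["alpha"], BANDS["beta"]]
        hf_bands = [BANDS["low_gamma"], BANDS["high_gamma"]]
        pairs = list(product(lf_bands, hf_bands))
    else:
        raise ValueError(f"unknown PLHG mode: {mode!r}")
    vals = np.zeros((len(pairs), X.shape[0]))
    for k, (lf, hf) in enumerate(pairs):
        lo = signal.sosfiltfilt(_bandpass_sos(*lf, fs), X, axis=-1)
        hi = signal.sosfiltfilt(_bandpass_sos(*hf, fs), X, axis=-1)
        alo = signal.hilbert(lo, axis=-1)
        ahi = signal.hilbert(hi, axis=-1)
        phasor = np.exp(1j * (np.angle(alo) - np.angle(ahi)))
        vals[k] = np.abs(np.mean(np.abs(ahi) * phasor, axis=-1))
    return vals.mean(axis=0)


def plhg(epoch, fs: float = 400.0, mode: str = "composite") -> float:
    """Phase-locked high gamma of one epoch.

    ``mode='composite'`` (default) band-passes to the 4-30 Hz LF and
    30-150 Hz HFO composites before the analytic signal; ``mode='per_band'``
    averages PLHG over the (theta, alpha, beta) x (low gamma, high gamma)
    band pairs.
    """
    x = np.asarray(epoch, dtype=np.float64)
    if not np.any(x):
        return 0.0
    return float(_plhg_matrix(x[None, :], fs, mode)[0])


def spectrum_representation(epochs: np.ndarray) -> np.ndarray:
    """One-sided FFT magnitude with DC dropped: (n, 400) -> (n, 200)."""
    X = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    return np.abs(np.fft.rfft(X, axis=-1))[:, 1:]


def engineered_feature_table(
    epochs: np.ndarray,
    fs: float = 400.0,
    plhg_mode: str = "composite",
    log_base: float = 10.0,
    strict: bool = True,
) -> pd.DataFrame:
    """The 16 engineered features for every row of a (n, 400) epoch matrix.

    Columns follow :data:`ENGINEERED_FEATURE_NAMES`. With ``strict=False``,
    degenerate epochs (zero power in a band or in the ER denominator)
    produce 0.0 entries instead of raising, which keeps batch jobs such as
    the narrowband probe running on pathological inputs.
    """
    X = np.atleast_2d(np.asarray(epochs, dtype=np.float64))
    bp = band_power_table(X, fs)
    total = bp["total"].to_numpy()
    bands = bp[BAND_NAMES].to_numpy()

    bad_total = total <= 0
    bad_band = (bands <= 0).any(axis=1)
    if strict and (bad_total.any() or bad_band.any()):
        raise DegenerateEpochError(
            "epoch with zero total or band power; use strict=False to zero-fill"
        )
    safe_total = np.where(bad_total, 1.0, total)
    rel = bands / safe_total[:, None]
    rel[bad_total] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(np.where(bands > 0, bands, np.nan)) / np.log(log_base)
    logp = np.nan_to_num(logp, nan=0.0)

    idx = {b: i for i, b in enumerate(BAND_NAMES)}
    denom = rel[:, idx["theta"]] + rel[:, idx["alpha"]]
    numer = rel[:, idx["beta"]] + rel[:, idx["low_gamma"]] + rel[:, idx["high_gamma"]]
    bad_denom = denom <= 0
    if strict and bad_denom.any():
        raise DegenerateEpochError("zero theta+alpha power in energy ratio")
    er = np.where(bad_denom, 0.0, numer / np.where(bad_denom, 1.0, denom))
    ei = er  # single 1 s epochs: N_d - N_0 + 1 == 1

    nonzero = np.any(X != 0, axis=1)
    plhg_vals = np.zeros(X.shape[0])
    if np.any(nonzero):
        plhg_vals[nonzero] = _plhg_matrix(X[nonzero], fs, plhg_mode)

    if strict:
        td = tdcg_table(X, fs)
        fd = fdcg_table(X, fs)
    else:
        td = np.zeros(X.shape[0])
        fd = np.zeros(X.shape[0])
        if np.any(nonzero):
            td[nonzero] = tdcg_table(X[nonzero], fs)
            fd[nonzero] = fdcg_table(X[nonzero], fs)

    data = np.column_stack([rel, logp, ei, plhg_vals, td, fd])
    return pd.DataFrame(data, columns=ENGINEERED_FEATURE_NAMES)


def engineered_features(epoch, fs: float = 400.0, **kw) -> pd.Series:
    """Named 16-vector of engineered features for a single epoch."""
    return engineered_feature_table(np.asarray(epoch)[None, :], fs, **kw).iloc[0]
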