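"""Raw trials → analysis-ready smoothed discharge-rate matrices.

The fixed pipeline is: force-based trial selection, binarization of
discharge trains over the analysis window, 400-ms Hanning smoothing
(a low-pass with −3 dB cutoff near 1.8 Hz, isolating the frequency band
that drives force), zero-phase 0.75-Hz Butterworth high-pass detrending,
and per-unit standardization.  The resulting r × c matrix (r time samples,
c motor units) feeds both the linear (PCA/FA) and nonlinear (mutual
information network) analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

from .recordings_io import DischargeTrain

__all__ = [
    "ForceSummary",
    "TrialSelection",
    "SpikeTrainMatrix",
    "SmoothedRateMatrix",
    "force_rmse",
    "select_post_skill_trials",
    "binarize",
    "smooth_rates",
    "detrend_standardize",
    "hanning_cutoff_hz",
    "decimate_columns",
]


class PipelineOrderError(RuntimeError):
    """Raised when stages are applied out of their fixed order."""


class DegenerateUnitError(ValueError):
    pass


@dataclass
class ForceSummary:
    rmse: float            # force–target RMSE, %MVC
    cov_force: float       # CoV of force, % (SD / mean * 100)
    trial_index: int | None = None

    def __post_init__(self) -> None:
        if self.rmse < 0 or self.cov_force < 0:
            raise ValueError("rmse and cov_force must be >= 0")


@dataclass
class TrialSelection:
    selected_indices: tuple[int, int, int]
    summaries: list[ForceSummary]

    def __post_init__(self) -> None:
        a, b, c = self.selected_indices
        if not (b == a + 1 and c == b + 1):
            raise ValueError("selected indices must be consecutive")


@dataclass
class SpikeTrainMatrix:
    data: np.ndarray              # (r, c) in {0, 1}
    fs: float
    unit_ids: list[str]
    window: tuple[int, int]       # [start, end) in original sample indices

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


@dataclass
class SmoothedRateMatrix:
    data: np.ndarray              # (r, c) float
    fs: float
    unit_ids: list[str]
    smoothed: bool = True
    detrended: bool = False
    standardized: bool = False
    window_ms: float = 400.0

    def __post_init__(self) -> None:
        r, c = self.data.shape
        if r <= c:
            warnings.warn(
                f"matrix has r={r} time samples <= c={c} units; "
                "eigenstructure will be rank-deficient",
                stacklevel=2,
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_units(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# Force-based trial selection
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float, order: int = 3) -> np.ndarray:
    sos = signal.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def force_rmse(
    force: np.ndarray,
    target: np.ndarray,
    fs: float,
    lowpass_hz: float = 15.0,
    trial_index: int | None = None,
) -> ForceSummary:
    """Force–target RMSE and force CoV for one trial window.

    The force is low-pass filtered at 15 Hz (3rd-order Butterworth,
    zero-phase); both signals are then linearly detrended before the RMSE.
    The CoV uses the SD of the detrended filtered force over its
    pre-detrend mean, ×100.
    """
    force = np.asarray(force, dtype=float)
    target = np.asarray(target, dtype=float)
    if force.shape != target.shape:
        raise ValueError("force and target must have the same length")
    f = _lowpass(force, fs, lowpass_hz)
    f_d = signal.detrend(f, type="linear")
    t_d = signal.detrend(target, type="linear")
    rmse = float(np.sqrt(np.mean((f_d - t_d) ** 2)))
    mean = float(f.mean())
    cov = float(np.abs(f_d.std() / mean) * 100.0) if mean != 0 else 0.0
    return ForceSummary(rmse=rmse, cov_force=cov, trial_index=trial_index)


def select_post_skill_trials(summaries: Sequence[ForceSummary]) -> TrialSelection:
    """Earliest consecutive trial triplet minimizing mean force–target RMSE.

    Emulates selecting post-skill-acquisition trials out of a learning
    sequence; ties break to the earliest triplet.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 candidate trials")
    summaries = sorted(summaries, key=lambda s: s.trial_index)
    idx = [s.trial_index for s in summaries]
    if any(i is None for i in idx):
        raise ValueError("all summaries need a trial_index")
    by_index = {s.trial_index: s for s in summaries}
    best: tuple[float, tuple[int, int, int]] | None = None
    for start in idx:
        triplet = (start, start + 1, start + 2)
        if not all(t in by_index for t in triplet):
            continue
        mean_rmse = float(np.mean([by_index[t].rmse for t in triplet]))
        if best is None or mean_rmse < best[0]:  # strict < keeps earliest tie
            best = (mean_rmse, triplet)
    if best is None:
        raise ValueError("no run of 3 consecutive trial indices found")
    return TrialSelection(best[1], list(summaries))


# ---------------------------------------------------------------------------
# Spike-train matrices and smoothing
# ---------------------------------------------------------------------------

def binarize(
    trains: Sequence[DischargeTrain],
    window_start_s: float,
    window_end_s: float,
) -> SpikeTrainMatrix:
    """Binary spike-train matrix over the half-open window [start, end).

    Row ``k`` corresponds to original sample ``start + k``; column order
    follows the train order.  Per the recording protocol, the analysis
    window is typically the last 25 s of the 30-s plateau.
    """
    if not trains:
        raise ValueError("no trains given")
    fs = trains[0].fs
    start = int(round(window_start_s * fs))
    end = int(round(window_end_s * fs))
    if end <= start:
        raise ValueError("empty analysis window")
    data = np.zeros((end - start, len(trains)), dtype=np.uint8)
    for j, train in enumerate(trains):
        s = train.discharge_samples
        s = s[(s >= start) & (s < end)]
        data[s - start, j] = 1
    return SpikeTrainMatrix(data, fs, [t.unit_id for t in trains], (start, end))


def _hanning_kernel(window_ms: float, fs: float) -> np.ndarray:
    m = int(round(window_ms / 1000.0 * fs))
    if m < 3:
        raise ValueError("smoothing window too short for this sampling rate")
    w = signal.windows.hann(m, sym=True)
    return w * fs / w.sum()  # unit time-integral -> output in pulses/s


def smooth_rates(spikes: SpikeTrainMatrix, window_ms: float = 400.0) -> SmoothedRateMatrix:
    """Convolve each binary spike train with an area-normalized Hanning window.

    Centered "same" convolution with zero padding; output columns are
    instantaneous discharge rates in pulses/s.
    """
    if window_ms <= 0:
        raise ValueError("window_ms must be > 0")
    kernel = _hanning_kernel(window_ms, spikes.fs)
    if len(kernel) > spikes.n_samples:
        raise ValueError("smoothing window longer than the record")
    data = signal.oaconvolve(
        spikes.data.astype(float), kernel[:, None], mode="same", axes=0
    )
    return SmoothedRateMatrix(
        data, spikes.fs, list(spikes.unit_ids), smoothed=True, window_ms=window_ms
    )


def hanning_cutoff_hz(window_ms: float = 400.0, fs: float = 2048.0) -> float:
    """−3 dB cutoff frequency of the Hanning smoothing kernel.

    Computed from the kernel's frequency response; for a 400-ms window this
    is ≈ 1.8 Hz (the closed form is ≈ 0.72 / T for window length T).
    """
    kernel = _hanning_kernel(window_ms, fs)
    n_fft = 1 << 18
    h = np.abs(np.fft.rfft(kernel, n_fft))
    h /= h[0]
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    target = 1.0 / np.sqrt(2.0)
    below = np.nonzero(h < target)[0][0]
    # linear interpolation between the two bins straddling −3 dB
    f0, f1 = freqs[below - 1], freqs[below]
    h0, h1 = h[below - 1], h[below]
    return float(f0 + (h0 - target) / (h0 - h1) * (f1 - f0))


def detrend_standardize(
    rates: SmoothedRateMatrix,
    highpass_hz: float = 0.75,
    order: int = 3,
) -> SmoothedRateMatrix:
    """Zero-phase high-pass detrending followed by per-unit z-scoring.

    The 0.75-Hz 3rd-order Butterworth high-pass removes offsets and slow
    trends; columns are then standardized to mean 0, SD 1 so that the PCA
    covariance equals the correlation matrix.
    """
    if not rates.smoothed:
        raise PipelineOrderError("detrend_standardize expects smoothed rates")
    if rates.standardized:
        raise PipelineOrderError("matrix is already standardized")
    X = rates.data
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateUnitError(
                f"unit {rates.unit_ids[j]!r} has a constant smoothed rate"
            )
    sos = signal.butter(order, highpass_hz, btype="high", fs=rates.fs, output="sos")
    X = signal.sosfiltfilt(sos, X, axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        j = int(np.nonzero(sd == 0)[0][0])
        raise DegenerateUnitError(
            f"unit {rates.unit_ids[j]!r} is constant after detrending"
        )
    X = (X - X.mean(axis=0)) / sd
    return SmoothedRateMatrix(
        X,
        rates.fs,
        list(rates.unit_ids),
        smoothed=True,
        detrended=True,
        standardized=True,
        window_ms=rates.window_ms,
    )


# ---------------------------------------------------------------------------
# Decimation helper (shared by parallel analysis and the MI network)
# ---------------------------------------------------------------------------

def decimate_columns(
    X: np.ndarray, fs: float, target_hz: float
) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation of each column to approximately ``target_hz``.

    The smoothed rates are band-limited near 1.8 Hz, so they are massively
    oversampled at 2048 Hz; decimation shrinks the sample dimension without
    information loss.  The overall factor is applied in stages of <= 13 as
    recommended for IIR decimators.  Returns (decimated, new_fs).
    """
    if target_hz <= 0:
        raise ValueError("target_hz must be > 0")
    q = int(round(fs / target_hz))
    if q <= 1:
        return X, fs
    factors: list[int] = []
    remaining = q
    while remaining > 13:
        for f in (8, 10, 12, 13, 7, 6, 5, 4, 3, 2):
            if remaining % f == 0:
                factors.append(f)
                remaining //= f
                break
        else:  # prime-ish factor; fall back to one big FIR stage
            factors.append(remaining)
            remaining = 1
    if remaining > 1:
        factors.append(remaining)
    out = np.asarray(X, dtype=float)
    for f in factors:
        ftype = "iir" if f <= 13 else "fir"
        out = signal.decimate(out, f, axis=0, ftype=ftype, zero_phase=True)
    return out, fs / q
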