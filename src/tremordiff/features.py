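"""Per-segment tremor descriptors.

Two descriptors are computed for every preprocessed segment: intensity as the
mean absolute value (MAV, analyzed on the natural-log scale), and dominant
frequency from two spectrum estimates — a Hanning-windowed Welch averaged
periodogram, and the diagonal slice of the bispectrum computed by the
indirect (third-order-cumulant) estimator with a Hanning lag window.

The bispectrum diagonal slice |B(w, w)| is sensitive to quadratic phase
coupling between harmonics: for a phase-coupled harmonic stack it peaks at
the fundamental, while for independent-phase tones of the same power it
stays near the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import signal

from tremordiff.records import Segment

__all__ = [
    "SpectrumEstimate",
    "mav",
    "ln_mav",
    "psd_welch",
    "third_order_cumulant",
    "bispectrum_diag",
    "bispectrum_2d",
    "dominant_frequency",
    "extract_features",
    "FEATURE_COLUMNS",
]

#: Column layout of the feature table produced by :func:`extract_features`.
FEATURE_COLUMNS = [
    "subject_id",
    "group",
    "stage",
    "posture",
    "segment_index",
    "segment_length_s",
    "mav",
    "ln_mav",
    "domfreq_psd",
    "domfreq_bispec",
]

DEFAULT_BAND = (1.0, 20.0)


@dataclass
class SpectrumEstimate:
    """A one-dimensional nonnegative spectrum on an increasing frequency grid.

    ``kind`` is ``"psd"`` for power spectral density (units of power per Hz)
    or ``"bispectrum_diag"`` for the magnitude of the bispectrum diagonal
    slice |B(w, w)|.
    """

    kind: str
    frequencies: np.ndarray
    values: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.frequencies.shape != self.values.shape:
            raise ValueError("frequencies and values must have the same shape")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.values < 0) or np.any(~np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite and nonnegative")


def _samples(segment) -> np.ndarray:
    """Accept a Segment or a bare array-like of samples."""
    if isinstance(segment, Segment):
        return segment.samples
    return np.asarray(segment, dtype=float)


def _rate(segment, sampling_rate: float | None) -> float:
    if isinstance(segment, Segment):
        return segment.sampling_rate
    if sampling_rate is None:
        raise ValueError("sampling_rate required for bare sample arrays")
    return float(sampling_rate)


def mav(segment) -> float:
    """Mean absolute value of the segment samples (m/s^2)."""
    x = _samples(segment)
    if x.size == 0:
        raise ValueError("cannot compute MAV of an empty segment")
    return float(np.mean(np.abs(x)))


def ln_mav(segment) -> float:
    """Natural log of the MAV; NaN (flagged missing) for an all-zero segment."""
    m = mav(segment)
    if m <= 0:
        return float("nan")
    return float(np.log(m))


def psd_welch(
    segment,
    window_length_s: float = 10.0,
    overlap_fraction: float = 0.5,
    sampling_rate: float | None = None,
    grid_hz: float = 0.1,
) -> SpectrumEstimate:
    """Welch averaged periodogram with a sliding Hanning window.

    The transform is zero-padded so the grid spacing is at most ``grid_hz``.
    With density scaling the integral of the PSD over frequency matches the
    (windowed) signal variance.
    """
    x = _samples(segment)
    fs = _rate(segment, sampling_rate)
    nperseg = int(round(window_length_s * fs))
    if nperseg > x.size:
        raise ValueError(
            f"Welch window of {nperseg} samples exceeds segment length {x.size}"
        )
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    noverlap = int(nperseg * overlap_fraction)
    nfft = max(nperseg, int(np.ceil(fs / grid_hz)))
    freqs, power = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        nfft=nfft,
        detrend="constant",
        scaling="density",
    )
    return SpectrumEstimate(
        kind="psd",
        frequencies=freqs,
        values=np.maximum(power, 0.0),
        resolution=float(freqs[1] - freqs[0]),
    )


def third_order_cumulant(segment, max_lag: int) -> np.ndarray:
    """Biased sample third-order cumulant C(k, l) on lags |k|, |l| <= max_lag.

    C(k, l) = (1/M) * sum_n x(n) x(n+k) x(n+l) over all n for which the three
    indices are in range. The returned array has shape
    ``(2*max_lag + 1, 2*max_lag + 1)`` with lag 0 at the centre, and is exactly
    symmetric under (k, l) exchange.

    The inner correlation is evaluated with FFTs (zero padding reproduces the
    valid-index restriction of the direct triple sum to rounding error).
    """
    x = _samples(segment)
    M = x.size
    L = int(max_lag)
    if L < 0:
        raise ValueError("max_lag must be nonnegative")
    if L >= M:
        raise ValueError(f"max_lag {L} must be smaller than segment length {M}")
    x = x - x.mean()
    nfft = sp_fft.next_fast_len(M + L)
    Xf = sp_fft.rfft(x, nfft)
    C = np.empty((2 * L + 1, 2 * L + 1))
    y = np.empty(M)
    for i, k in enumerate(range(-L, L + 1)):
        y[:] = 0.0
        if k >= 0:
            y[: M - k] = x[: M - k] * x[k:]
        else:
            y[-k:] = x[-k:] * x[: M + k]
        # c[l mod nfft] = sum_n y(n) x(n + l)
        c = sp_fft.irfft(np.conj(sp_fft.rfft(y, nfft)) * Xf, nfft)
        C[i, :L] = c[nfft - L : nfft]
        C[i, L:] = c[: L + 1]
    C /= M
    return 0.5 * (C + C.T)


def _hanning_lag_window(max_lag: int) -> np.ndarray:
    """Symmetric Hanning lag window of length 2*max_lag + 1, unity at lag 0."""
    if max_lag == 0:
        return np.ones(1)
    return np.hanning(2 * max_lag + 1)


def bispectrum_diag_complex(
    segment,
    max_lag: int = 100,
    sampling_rate: float | None = None,
    grid_hz: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex bispectrum diagonal slice B(w, w) on a nonnegative grid.

    The third-order cumulant is tapered with a separable Hanning lag window
    and Fourier transformed; on the diagonal w1 = w2 the 2-D transform
    reduces to a 1-D transform of the anti-diagonal sums of the windowed
    cumulant (zero-padded to a grid of at most ``grid_hz``).

    The complex value is what coherent averaging across independent
    realizations needs: for quadratically phase-coupled components the phase
    of B(w, w) is locked and the average survives, while for independent
    phases it cancels. A single realization's |B(w, w)| alone cannot
    distinguish the two cases.
    """
    fs = _rate(segment, sampling_rate)
    L = int(max_lag)
    C = third_order_cumulant(segment, L)
    w = _hanning_lag_window(L)
    Cw = C * np.outer(w, w)
    # anti-diagonal sums d(s) = sum_{k+l=s} Cw(k, l), s in [-2L, 2L]
    flipped = Cw[:, ::-1]
    d = np.array(
        [np.trace(flipped, offset=-s) for s in range(-2 * L, 2 * L + 1)]
    )
    nfft = max(4 * L + 1, int(np.ceil(fs / grid_hz)))
    buf = np.zeros(nfft, dtype=complex)
    for s, value in zip(range(-2 * L, 2 * L + 1), d):
        buf[s % nfft] += value
    B = np.fft.fft(buf)
    n_keep = nfft // 2 + 1
    freqs = np.arange(n_keep) * fs / nfft
    return freqs, B[:n_keep]


def bispectrum_diag(
    segment,
    max_lag: int = 100,
    sampling_rate: float | None = None,
    grid_hz: float = 0.1,
) -> SpectrumEstimate:
    """Magnitude of the bispectrum diagonal slice |B(w, w)|.

    See :func:`bispectrum_diag_complex` for the estimator; peak picking for
    the dominant frequency uses the magnitude, which is invariant to the
    arbitrary sign/orientation of the axis-reduced segment.
    """
    freqs, B = bispectrum_diag_complex(
        segment, max_lag=max_lag, sampling_rate=sampling_rate, grid_hz=grid_hz
    )
    fs = _rate(segment, sampling_rate)
    return SpectrumEstimate(
        kind="bispectrum_diag",
        frequencies=freqs,
        values=np.abs(B),
        resolution=float(freqs[1] - freqs[0]),
    )


def bispectrum_2d(
    segment,
    max_lag: int = 32,
    sampling_rate: float | None = None,
    nfft: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Full 2-D bispectrum estimate B(w1, w2) (diagnostic helper).

    Returns ``(freqs, B)`` where ``B[i, j]`` estimates B(freqs[i], freqs[j])
    on the full FFT grid. The output is symmetrized so that
    ``B(w1, w2) == B(w2, w1)`` holds exactly, matching the symmetry of the
    windowed cumulant it transforms.
    """
    fs = _rate(segment, sampling_rate)
    L = int(max_lag)
    C = third_order_cumulant(segment, L)
    w = _hanning_lag_window(L)
    Cw = C * np.outer(w, w)
    n = nfft or 4 * L + 1
    if n < 2 * L + 1:
        raise ValueError("nfft must cover the lag range")
    buf = np.zeros((n, n), dtype=complex)
    lags = np.arange(-L, L + 1)
    idx = lags % n
    buf[np.ix_(idx, idx)] = Cw
    B = np.fft.fft2(buf)
    B = 0.5 * (B + B.T)
    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    return freqs, B


def dominant_frequency(
    spectrum: SpectrumEstimate, band: tuple[float, float] = DEFAULT_BAND
) -> float:
    """Frequency of the spectrum maximum within ``band`` (ties: lowest wins).

    Returns NaN (flagged missing) if the spectrum is identically zero on the
    band.
    """
    low, high = band
    freqs = spectrum.frequencies
    if freqs[0] > low or freqs[-1] < high:
        raise ValueError(
            f"spectrum grid [{freqs[0]}, {freqs[-1]}] does not cover band {band}"
        )
    mask = (freqs >= low) & (freqs <= high)
    values = spectrum.values[mask]
    if not np.any(values > 0):
        return float("nan")
    return float(freqs[mask][np.argmax(values)])


def extract_features(
    segments: list[Segment],
    welch_window_s: float = 10.0,
    welch_overlap: float = 0.5,
    cumulant_max_lag: int = 100,
    grid_hz: float = 0.1,
    band: tuple[float, float] = DEFAULT_BAND,
) -> pd.DataFrame:
    """Build the per-segment feature table.

    One row per segment with provenance and the four feature columns. Rows
    whose features are flagged missing (NaN) are carried, never dropped.
    For segments shorter than the Welch window the window shrinks to the
    segment; the cumulant lag is likewise capped at segment length - 1.
    """
    rows = []
    for seg in segments:
        m = mav(seg)
        lm = float(np.log(m)) if m > 0 else float("nan")
        window_s = min(welch_window_s, seg.length_s)
        psd = psd_welch(
            seg,
            window_length_s=window_s,
            overlap_fraction=welch_overlap,
            grid_hz=grid_hz,
        )
        lag = min(cumulant_max_lag, seg.n_samples - 1)
        bis = bispectrum_diag(seg, max_lag=lag, grid_hz=grid_hz)
        prov = seg.provenance
        rows.append(
            {
                "subject_id": prov.subject_id,
                "group": prov.group,
                "stage": prov.stage,
                "posture": prov.posture,
                "segment_index": prov.segment_index,
                "segment_length_s": seg.length_s,
                "mav": m,
                "ln_mav": lm,
                "domfreq_psd": dominant_frequency(psd, band),
                "domfreq_bispec": dominant_frequency(bis, band),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
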