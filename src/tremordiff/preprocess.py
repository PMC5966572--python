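"""Raw-recording conditioning: segmentation, notch, bandpass, decimation and
axis reduction.

The stages are applied in this fixed order: cut non-overlapping windows within
each trial, remove mains interference with cascaded zero-phase notches, apply
a zero-phase 1-20 Hz Butterworth bandpass, decimate to the target rate, then
project the three axes onto their first principal direction.

All zero-phase filtering reflects the signal at both ends (1 s by default)
before the forward-backward pass and trims afterwards, so 30-s windows do not
carry filter start-up transients into downstream amplitude features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from tremordiff.records import RawSegment, Segment, SegmentProvenance, TremorRecording

__all__ = [
    "FilterSpec",
    "segment_recording",
    "notch_filter",
    "bandpass_filter",
    "downsample",
    "reduce_axes",
    "preprocess_pipeline",
]

DEFAULT_NOTCH_HARMONICS = tuple(float(f) for f in range(50, 500, 50))


@dataclass(frozen=True)
class FilterSpec:
    """Filtering configuration for the conditioning stages.

    ``notch_harmonics`` lists every notch centre to apply (the mains base
    frequency and its harmonics, all of which must lie below Nyquist at the
    recording rate). The bandpass is an order-``butter_order`` Butterworth
    applied forward-backward when ``zero_phase`` is set, doubling the
    effective order.
    """

    notch_base: float = 50.0
    notch_harmonics: tuple[float, ...] = DEFAULT_NOTCH_HARMONICS
    notch_q: float = 35.0
    bandpass_low: float = 1.0
    bandpass_high: float = 20.0
    butter_order: int = 2
    zero_phase: bool = True
    target_rate: float = 100.0
    edge_pad_s: float = 1.0

    def validate(self, sampling_rate: float) -> None:
        nyquist = sampling_rate / 2.0
        if not (0 < self.bandpass_low < self.bandpass_high < nyquist):
            raise ValueError(
                f"bandpass edges ({self.bandpass_low}, {self.bandpass_high}) "
                f"must satisfy 0 < low < high < Nyquist ({nyquist} Hz)"
            )
        for f in self.notch_harmonics:
            if f >= nyquist:
                raise ValueError(
                    f"notch frequency {f} Hz is at or above Nyquist ({nyquist} Hz)"
                )
        if self.notch_q <= 0:
            raise ValueError("notch_q must be positive")
        if self.butter_order < 1:
            raise ValueError("butter_order must be >= 1")


def segment_recording(
    recording: TremorRecording, segment_length_s: float
) -> list[RawSegment]:
    """Cut non-overlapping consecutive windows within each trial.

    Windows never span a trial boundary; any trailing remainder shorter than
    ``segment_length_s`` is discarded. Segments are indexed in temporal order
    across the whole recording.
    """
    if segment_length_s <= 0:
        raise ValueError("segment_length_s must be positive")
    fs = recording.sampling_rate
    window = int(round(segment_length_s * fs))
    if window <= 0:
        raise ValueError("segment length shorter than one sample")
    segments: list[RawSegment] = []
    index = 0
    for trial_index, (start, end) in enumerate(recording.trial_bounds):
        n_windows = (end - start) // window
        for w in range(n_windows):
            a = start + w * window
            prov = SegmentProvenance(
                subject_id=recording.subject_id,
                group=recording.group,
                stage=recording.stage,
                posture=recording.posture,
                segment_index=index,
                trial_index=trial_index,
            )
            segments.append(
                RawSegment(
                    axes=recording.axes[:, a : a + window],
                    sampling_rate=fs,
                    provenance=prov,
                )
            )
            index += 1
    return segments


def _reflect_filtfilt(
    sos: np.ndarray, x: np.ndarray, sampling_rate: float, pad_s: float
) -> np.ndarray:
    """Forward-backward filter with explicit edge reflection instead of the
    default filtfilt padding."""
    pad = min(int(round(pad_s * sampling_rate)), x.size - 1)
    if pad > 0:
        xp = np.pad(x, pad, mode="reflect")
    else:
        xp = x
    y = signal.sosfiltfilt(sos, xp, padlen=0)
    return y[pad : pad + x.size] if pad > 0 else y


def _check_finite(x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        bad = int(np.flatnonzero(~np.isfinite(np.asarray(x)))[0])
        raise ValueError(f"non-finite input value at index {bad}")


def notch_sos(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Cascaded second-order notch sections at every configured centre."""
    spec.validate(sampling_rate)
    sections = []
    for f in spec.notch_harmonics:
        b, a = signal.iirnotch(f, spec.notch_q, fs=sampling_rate)
        sections.append(signal.tf2sos(b, a))
    return np.vstack(sections)


def notch_filter(
    samples: np.ndarray, sampling_rate: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Remove mains interference with cascaded zero-phase notches."""
    spec = spec or FilterSpec()
    x = np.asarray(samples, dtype=float)
    _check_finite(x)
    sos = notch_sos(spec, sampling_rate)
    if not spec.zero_phase:
        return signal.sosfilt(sos, x)
    return _reflect_filtfilt(sos, x, sampling_rate, spec.edge_pad_s)


def bandpass_sos(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    spec.validate(sampling_rate)
    return signal.butter(
        spec.butter_order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass_filter(
    samples: np.ndarray, sampling_rate: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Zero-phase Butterworth bandpass (applied forward-backward)."""
    spec = spec or FilterSpec()
    x = np.asarray(samples, dtype=float)
    _check_finite(x)
    sos = bandpass_sos(spec, sampling_rate)
    if not spec.zero_phase:
        return signal.sosfilt(sos, x)
    return _reflect_filtfilt(sos, x, sampling_rate, spec.edge_pad_s)


def downsample(
    samples: np.ndarray, from_rate: float = 1000.0, to_rate: float = 100.0
) -> np.ndarray:
    """Decimate by an integer factor, keeping every k-th sample.

    The input is assumed band-limited below ``to_rate / 2`` (the bandpass at
    20 Hz guarantees this in the pipeline), so no further anti-alias filter
    is applied.
    """
    ratio = from_rate / to_rate
    k = int(round(ratio))
    if k <= 0 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"from_rate/to_rate must be a positive integer, got {ratio}"
        )
    return np.asarray(samples, dtype=float)[::k]


def reduce_axes(raw: RawSegment) -> Segment:
    """Project a filtered 3-axis window onto its first principal direction.

    The projection direction is the unit eigenvector of the 3x3 sample
    covariance with the largest eigenvalue; its sign is fixed by requiring
    non-negative sample skewness of the projected signal (with the largest-
    magnitude vector component made non-negative as a tie-break), so the
    orientation is deterministic. The output is zero-mean. An all-zero window
    is passed through with a ``degenerate_axes`` provenance flag.
    """
    x = raw.axes
    if not np.any(x):
        return Segment(
            samples=np.zeros(raw.n_samples),
            sampling_rate=raw.sampling_rate,
            provenance=raw.provenance.with_flag("degenerate_axes"),
        )
    centered = x - x.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / max(raw.n_samples - 1, 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, -1]
    y = direction @ centered
    skew = float(np.mean(y**3))
    if skew < 0:
        y = -y
    elif skew == 0 and direction[np.argmax(np.abs(direction))] < 0:
        y = -y
    return Segment(
        samples=y, sampling_rate=raw.sampling_rate, provenance=raw.provenance
    )


def preprocess_pipeline(
    recording: TremorRecording,
    segment_length_s: float = 30.0,
    spec: FilterSpec | None = None,
) -> list[Segment]:
    """Segment, notch, bandpass, decimate and reduce a recording.

    Returns one :class:`Segment` per complete window at ``spec.target_rate``.
    """
    spec = spec or FilterSpec()
    fs = recording.sampling_rate
    spec.validate(fs)
    n_sos = notch_sos(spec, fs)
    b_sos = bandpass_sos(spec, fs)
    out: list[Segment] = []
    for raw in segment_recording(recording, segment_length_s):
        filtered = np.empty_like(raw.axes)
        for i in range(3):
            axis = raw.axes[i]
            _check_finite(axis)
            axis = _reflect_filtfilt(n_sos, axis, fs, spec.edge_pad_s)
            axis = _reflect_filtfilt(b_sos, axis, fs, spec.edge_pad_s)
            filtered[i] = axis
        decimated = np.stack(
            [downsample(filtered[i], fs, spec.target_rate) for i in range(3)]
        )
        out.append(
            reduce_axes(
                RawSegment(
                    axes=decimated,
                    sampling_rate=spec.target_rate,
                    provenance=raw.provenance,
                )
            )
        )
    return out
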