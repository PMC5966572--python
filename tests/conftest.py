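import numpy as np
import pytest

from tremordiff.records import SegmentProvenance, Segment, TremorRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(
    axes,
    sampling_rate=1000.0,
    posture="P2",
    group="PD",
    stage="S1",
    subject_id="T-000",
    trial_bounds=None,
):
    axes = np.atleast_2d(np.asarray(axes, dtype=float))
    if axes.shape[0] == 1:
        axes = np.vstack([axes, np.zeros_like(axes), np.zeros_like(axes)])
    return TremorRecording(
        subject_id=subject_id,
        group=group,
        stage=stage,
        posture=posture,
        sampling_rate=sampling_rate,
        axes=axes,
        trial_bounds=trial_bounds or [],
    )


def make_segment(samples, sampling_rate=100.0, **prov):
    defaults = dict(
        subject_id="T-000",
        group="PD",
        stage="S1",
        posture="P2",
        segment_index=0,
    )
    defaults.update(prov)
    return Segment(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=sampling_rate,
        provenance=SegmentProvenance(**defaults),
    )


def coupled_stack(
    fundamental_hz,
    duration_s=30.0,
    sampling_rate=100.0,
    amplitudes=(1.0, 0.4, 0.15),
    phase=0.3,
):
    """Phase-coupled harmonic stack: phase of harmonic h is h * fundamental."""
    t = np.arange(int(round(duration_s * sampling_rate))) / sampling_rate
    x = np.zeros_like(t)
    for h, a in enumerate(amplitudes, start=1):
        x += a * np.cos(2 * np.pi * h * fundamental_hz * t + h * phase)
    return x
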