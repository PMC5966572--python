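"""Synthetic tremor-acceleration cohort generator.

Each subject's tremor is a slowly amplitude-modulated stack of phase-coupled
harmonics of a per-subject fundamental frequency (phase of harmonic h equals
h times the fundamental phase, so the bispectrum diagonal is non-degenerate),
superimposed with sub-1-Hz postural drift, 50-Hz mains interference and white
sensor noise, and distributed across the three accelerometer axes along a
random per-subject unit direction.

Per-subject fundamentals and intensity targets are drawn from the group
signal model, so the post-pipeline feature distributions of a generated
cohort reproduce the configured group means/SDs. The tremor amplitude is
calibrated analytically: the MAV of the band-limited unit-amplitude waveform
is computed once and the waveform scaled so the expected post-pipeline ln-MAV
equals the per-subject draw.

Session structure: posture P1 is recorded as five equal trials (trial bounds
recorded, windows never span them); posture P2 as one continuous trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from tremordiff import preprocess
from tremordiff.records import POSTURES, SUBGROUPS, TremorRecording

__all__ = [
    "GroupSignalModel",
    "CohortConfig",
    "generate_subject",
    "generate_cohort",
    "reference_models",
    "write_recording",
    "write_cohort",
]

#: Per-subject fundamentals are truncated to this plausible tremor range (Hz).
FUNDAMENTAL_RANGE = (1.5, 15.0)

#: Time constant (s) of the AR(1) frequency-wander process.
FREQ_WANDER_TAU_S = 10.0

_P1_TRIALS = 5


@dataclass(frozen=True)
class GroupSignalModel:
    """Distribution parameters of one (group, posture) signal population.

    ``tremor_freq_mean``/``sd`` parameterize the per-subject fundamental
    (Hz); ``ln_mav_mean``/``sd`` the per-subject intensity target on the
    natural-log scale. ``harmonic_amplitudes`` are unitless ratios with the
    fundamental normalized to 1. Nuisance components: ``freq_jitter_sd``
    (slow frequency wander, Hz), ``amp_mod_depth`` (fractional amplitude
    modulation, < 1 so the envelope stays positive), ``drift_amp`` (sub-1-Hz
    drift RMS, m/s^2), ``mains_amp`` (50-Hz amplitude, m/s^2) and
    ``noise_sd`` (white sensor noise, m/s^2).
    """

    tremor_freq_mean: float
    tremor_freq_sd: float
    ln_mav_mean: float
    ln_mav_sd: float
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.4, 0.15)
    freq_jitter_sd: float = 0.2
    amp_mod_depth: float = 0.3
    drift_amp: float = 0.3
    mains_amp: float = 0.5
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not (1.0 < self.tremor_freq_mean < 20.0):
            raise ValueError("tremor_freq_mean must lie in (1, 20) Hz")
        for name in ("tremor_freq_sd", "ln_mav_sd", "freq_jitter_sd",
                     "drift_amp", "mains_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.harmonic_amplitudes or self.harmonic_amplitudes[0] != 1.0:
            raise ValueError("harmonic_amplitudes[0] must be 1 (fundamental)")
        if not (0 <= self.amp_mod_depth < 1):
            raise ValueError("amp_mod_depth must lie in [0, 1)")

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonic_amplitudes)


@dataclass
class CohortConfig:
    """Full cohort specification: subgroup counts, models, timing and seed."""

    n_per_subgroup: dict[str, int]
    models: dict[tuple[str, str], GroupSignalModel]
    recording_duration: float = 300.0
    sampling_rate: float = 1000.0
    seed: int = 0
    postures: tuple[str, ...] = POSTURES

    def __post_init__(self) -> None:
        for key, n in self.n_per_subgroup.items():
            if key not in SUBGROUPS:
                raise ValueError(f"unknown subgroup {key!r}")
            if n < 0:
                raise ValueError("subgroup counts must be nonnegative")
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        for posture in self.postures:
            if posture not in POSTURES:
                raise ValueError(f"unknown posture {posture!r}")
        for (subgroup, posture) in self._required_model_keys():
            if (subgroup, posture) not in self.models:
                raise ValueError(f"missing model for {(subgroup, posture)}")
        highest = max(
            m.n_harmonics * FUNDAMENTAL_RANGE[1]
            for m in self.models.values()
        )
        if self.sampling_rate < 2 * max(highest, 50.0):
            raise ValueError(
                f"sampling_rate {self.sampling_rate} below twice the highest "
                f"modeled frequency component"
            )

    def _required_model_keys(self):
        for subgroup, n in self.n_per_subgroup.items():
            if n > 0:
                for posture in self.postures:
                    yield subgroup, posture


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float
) -> float:
    if sd == 0:
        return float(np.clip(mean, low, high))
    for _ in range(1000):
        value = rng.normal(mean, sd)
        if low < value < high:
            return float(value)
    return float(np.clip(mean, low, high))


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            return v / norm


def _ar1_process(
    rng: np.random.Generator, n: int, sd: float, tau_s: float, fs: float
) -> np.ndarray:
    """Stationary first-order autoregressive wander with SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    phi = float(np.exp(-1.0 / (tau_s * fs)))
    innov_sd = sd * np.sqrt(1.0 - phi**2)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, sd)
    return signal.lfilter([1.0], [1.0, -phi], e)


def _drift(
    rng: np.random.Generator, n: int, amp: float, fs: float
) -> np.ndarray:
    """Random low-pass process below 1 Hz with RMS ``amp``."""
    if amp == 0:
        return np.zeros(n)
    sos = signal.butter(2, 0.3, btype="lowpass", fs=fs, output="sos")
    raw = signal.sosfiltfilt(sos, rng.normal(size=n))
    rms = np.sqrt(np.mean(raw**2))
    if rms < 1e-12:
        return np.zeros(n)
    return amp * raw / rms


def _trial_bounds(posture: str, n_samples: int) -> list[tuple[int, int]]:
    if posture == "P1":
        edges = np.linspace(0, n_samples, _P1_TRIALS + 1).astype(int)
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]
    return [(0, n_samples)]


def generate_subject(
    model: GroupSignalModel,
    posture: str,
    duration_s: float = 300.0,
    sampling_rate: float = 1000.0,
    rng: np.random.Generator | None = None,
    subject_id: str = "S000",
    group: str = "PD",
    stage: str = "S1",
) -> TremorRecording:
    """Generate one subject/posture 3-axis recording from a signal model.

    Deterministic given the RNG state: the same seeded generator and model
    produce bit-identical recordings.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    highest = model.n_harmonics * FUNDAMENTAL_RANGE[1]
    if sampling_rate < 2 * max(highest, 50.0):
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz below twice the highest "
            f"modeled frequency ({max(highest, 50.0)} Hz)"
        )
    rng = rng or np.random.default_rng()
    fs = float(sampling_rate)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    f0 = _truncated_normal(
        rng, model.tremor_freq_mean, model.tremor_freq_sd, *FUNDAMENTAL_RANGE
    )
    target_ln_mav = rng.normal(model.ln_mav_mean, model.ln_mav_sd)
    tremor_dir = _random_unit_vector(rng)
    phase0 = rng.uniform(0, 2 * np.pi)

    # instantaneous fundamental with slow AR(1) wander; fully coupled phases
    wander = _ar1_process(rng, n, model.freq_jitter_sd, FREQ_WANDER_TAU_S, fs)
    inst_freq = np.clip(f0 + wander, *FUNDAMENTAL_RANGE)
    phase = phase0 + 2 * np.pi * np.cumsum(inst_freq) / fs
    stack = np.zeros(n)
    for h, amp in enumerate(model.harmonic_amplitudes, start=1):
        stack += amp * np.cos(h * phase)

    if model.amp_mod_depth > 0:
        am_freq = rng.uniform(0.05, 0.2)
        am_phase = rng.uniform(0, 2 * np.pi)
        envelope = 1.0 + model.amp_mod_depth * np.sin(
            2 * np.pi * am_freq * t + am_phase
        )
    else:
        envelope = np.ones(n)
    unit_tremor = envelope * stack

    # analytic amplitude calibration: MAV of the band-limited unit waveform
    spec = preprocess.FilterSpec()
    unit_filtered = preprocess.bandpass_filter(unit_tremor, fs, spec)
    unit_decimated = preprocess.downsample(unit_filtered, fs, spec.target_rate)
    unit_mav = float(np.mean(np.abs(unit_decimated)))
    if unit_mav <= 0:
        raise RuntimeError("degenerate unit waveform in calibration")
    amplitude = float(np.exp(target_ln_mav)) / unit_mav

    axes = np.outer(tremor_dir, amplitude * unit_tremor)
    if model.drift_amp > 0:
        drift_dir = _random_unit_vector(rng)
        axes += np.outer(drift_dir, _drift(rng, n, model.drift_amp, fs))
    if model.mains_amp > 0:
        mains_dir = _random_unit_vector(rng)
        mains_phase = rng.uniform(0, 2 * np.pi)
        axes += np.outer(
            mains_dir,
            model.mains_amp * np.cos(2 * np.pi * 50.0 * t + mains_phase),
        )
    if model.noise_sd > 0:
        axes += rng.normal(0.0, model.noise_sd, size=(3, n))

    return TremorRecording(
        subject_id=subject_id,
        group=group,
        stage=stage,
        posture=posture,
        sampling_rate=fs,
        axes=axes,
        trial_bounds=_trial_bounds(posture, n),
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[TremorRecording], pd.DataFrame]:
    """Generate the full labeled cohort.

    One recording per subject per configured posture. Subjects use
    independent seed-sequence substreams keyed by (subgroup, index, posture),
    so changing one subgroup's count never perturbs the others' recordings.
    Returns the recordings and a label table with one row per subject.
    """
    recordings: list[TremorRecording] = []
    label_rows = []
    for g_idx, subgroup in enumerate(SUBGROUPS):
        count = config.n_per_subgroup.get(subgroup, 0)
        group, stage = subgroup[:2], f"S{subgroup[2]}"
        for i in range(count):
            subject_id = f"{subgroup}-{i:03d}"
            for p_idx, posture in enumerate(config.postures):
                seq = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(g_idx, i, p_idx)
                )
                rng = np.random.default_rng(seq)
                recordings.append(
                    generate_subject(
                        config.models[(subgroup, posture)],
                        posture=posture,
                        duration_s=config.recording_duration,
                        sampling_rate=config.sampling_rate,
                        rng=rng,
                        subject_id=subject_id,
                        group=group,
                        stage=stage,
                    )
                )
            label_rows.append(
                {
                    "subject_id": subject_id,
                    "group": group,
                    "stage": stage,
                    "subgroup": subgroup,
                    "postures": ",".join(config.postures),
                }
            )
    labels = pd.DataFrame(
        label_rows,
        columns=["subject_id", "group", "stage", "subgroup", "postures"],
    )
    return recordings, labels


# Default per-(subgroup, posture) calibration targets. The ln-MAV targets are
# group summary statistics of a reference clinical PD/ET cohort; the
# frequency targets exist in two variants because the two spectrum estimators
# were summarized separately for that cohort.
_LN_MAV_TARGETS = {
    ("PD1", "P1"): (0.0, 1.3),
    ("ET1", "P1"): (0.5, 1.3),
    ("PD2", "P1"): (0.8, 1.2),
    ("ET2", "P1"): (0.7, 1.7),
    ("PD1", "P2"): (0.4, 1.5),
    ("ET1", "P2"): (-2.0, 0.7),
    ("PD2", "P2"): (-0.4, 2.0),
    ("ET2", "P2"): (-2.1, 0.5),
}

_FREQ_TARGETS_PSD = {
    ("PD1", "P1"): (6.2, 1.7),
    ("ET1", "P1"): (6.9, 1.7),
    ("PD2", "P1"): (5.9, 1.8),
    ("ET2", "P1"): (7.0, 1.9),
    ("PD1", "P2"): (5.0, 1.2),
    ("ET1", "P2"): (7.7, 1.9),
    ("PD2", "P2"): (5.5, 1.9),
    ("ET2", "P2"): (8.6, 1.9),
}

_FREQ_TARGETS_BISPECTRUM = {
    ("PD1", "P1"): (5.2, 1.9),
    ("ET1", "P1"): (6.3, 1.9),
    ("PD2", "P1"): (5.2, 1.3),
    ("ET2", "P1"): (6.3, 1.8),
    ("PD1", "P2"): (4.6, 0.9),
    ("ET1", "P2"): (6.0, 1.3),
    ("PD2", "P2"): (4.7, 1.2),
    ("ET2", "P2"): (6.7, 1.5),
}


def reference_models(
    frequency_calibration: str = "psd", **overrides
) -> dict[tuple[str, str], GroupSignalModel]:
    """Default per-(subgroup, posture) models calibrated to the reference
    cohort's group statistics.

    ``frequency_calibration`` selects which dominant-frequency summary the
    fundamental-frequency distribution is matched to (``"psd"`` or
    ``"bispectrum"``). Extra keyword arguments override the corresponding
    :class:`GroupSignalModel` nuisance fields for every cell.
    """
    if frequency_calibration == "psd":
        freq_targets = _FREQ_TARGETS_PSD
    elif frequency_calibration == "bispectrum":
        freq_targets = _FREQ_TARGETS_BISPECTRUM
    else:
        raise ValueError("frequency_calibration must be 'psd' or 'bispectrum'")
    models = {}
    for key in _LN_MAV_TARGETS:
        freq_mean, freq_sd = freq_targets[key]
        mav_mean, mav_sd = _LN_MAV_TARGETS[key]
        models[key] = GroupSignalModel(
            tremor_freq_mean=freq_mean,
            tremor_freq_sd=freq_sd,
            ln_mav_mean=mav_mean,
            ln_mav_sd=mav_sd,
            **overrides,
        )
    return models


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_recording(
    recording: TremorRecording, directory: str | Path, seed_note: str = ""
) -> Path:
    """Write a recording as ``time_s,ax,ay,az`` CSV plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{recording.subject_id}_{recording.posture}.csv"
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame(
        {
            "time_s": t,
            "ax": recording.axes[0],
            "ay": recording.axes[1],
            "az": recording.axes[2],
        }
    )
    # 17 significant digits round-trip float64 exactly
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "subject_id": recording.subject_id,
        "group": recording.group,
        "stage": recording.stage,
        "posture": recording.posture,
        "sampling_rate_hz": recording.sampling_rate,
        "trial_bounds": [list(b) for b in recording.trial_bounds],
        "seed_provenance": seed_note,
    }
    _sidecar_path(csv_path).write_text(json.dumps(meta, indent=1))
    return csv_path


def write_cohort(
    recordings: list[TremorRecording],
    labels: pd.DataFrame,
    directory: str | Path,
    seed_note: str = "",
) -> Path:
    """Write every recording plus the ground-truth label table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for recording in recordings:
        write_recording(recording, directory, seed_note=seed_note)
    labels_path = directory / "labels.csv"
    labels.to_csv(labels_path, index=False)
    return directory
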