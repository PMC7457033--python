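"""Synthetic longitudinal motor-attempt EEG with known ground-truth ERD.

The generator emulates a 12-session exoskeleton-BCI training study in
subacute stroke: each session is three runs of 30 cued trials (~11 s each,
cue at 3 s, balanced task/idle), recorded on a 31-channel 10–20 cap at
200 Hz. Sensorimotor mu (8–13 Hz) and beta (14–30 Hz) rhythm sources sit
over each motor cortex with a Gaussian spatial profile centred at C3/C4;
during task trials the source amplitude is multiplied by sqrt(g) over
[cue+1, cue+4] s, so band power drops to a fraction g of rest and the true
event-related desynchronisation is E = g - 1. A 1/f Gaussian background plus
white sensor noise completes the signal. Patient phenotypes set how the ERD
depth g evolves over the 12 sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .io import IDLE, TASK, Marker, Recording, write_brainvision
from .montage import Montage, default_montage, mirror_channel

PHENOTYPES = ("increasing", "sustained", "weak", "bilateral_mixed")

#: Session-schedule of the task-power fraction g per phenotype: (start, end)
#: linearly interpolated across sessions. "bilateral_mixed" alternates.
_PHENOTYPE_DEPTH = {
    "increasing": (0.9, 0.3),
    "sustained": (0.35, 0.35),
    "weak": (0.98, 0.98),
    "bilateral_mixed": (0.55, 0.9),  # alternated session-by-session
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-protocol and signal-model parameters.

    Amplitudes are standard deviations in uV at the profile-peak channel;
    mu/beta rhythm power dominates the 8–30 Hz band there so that the
    measured ERD tracks the programmed fraction g closely.
    """

    sampling_rate: float = 200.0
    trial_duration: float = 11.0
    cue_time: float = 3.0
    runs_per_session: int = 3
    trials_per_run: int = 30
    sessions: int = 12
    noise_exponent: float = 1.0
    rest_interval: tuple[float, float] = (1.0, 3.0)
    mu_amplitude: float = 4.0
    beta_amplitude: float = 2.0
    pink_noise_std: float = 1.0
    sensor_noise_std: float = 0.5
    rng_seed: int = 0
    montage: Montage = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 < self.cue_time < self.trial_duration:
            raise ValueError("cue_time must lie within the trial")
        if self.rest_interval[0] < 0 or self.rest_interval[1] < self.rest_interval[0]:
            raise ValueError("invalid rest_interval bounds")

    @property
    def trials_per_session(self) -> int:
        return self.runs_per_session * self.trials_per_run

    @property
    def n_channels(self) -> int:
        return self.montage.n_channels


@dataclass(frozen=True)
class VirtualPatient:
    """A simulated participant with a longitudinal ERD phenotype.

    ``erd_depth_schedule[s-1]`` is the task-power fraction g for session s at
    the ipsilesional motor channel; ``contralesional_ratio`` is the fraction
    of the ipsilesional effect expressed at the mirror channel.
    """

    patient_id: str
    lesion_side: str  # "left" | "right"
    phenotype: str
    erd_depth_schedule: tuple[float, ...]
    contralesional_ratio: float = 0.8

    def __post_init__(self) -> None:
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"unknown lesion_side {self.lesion_side!r}")
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if any(not 0 <= g <= 1 for g in self.erd_depth_schedule):
            raise ValueError("erd_depth_schedule values must lie in [0, 1]")

    @property
    def ipsilesional_channel(self) -> str:
        # attempted movement of the affected hand activates the lesioned
        # hemisphere's motor cortex: left lesion -> C3, right lesion -> C4
        return "C3" if self.lesion_side == "left" else "C4"

    @property
    def contralesional_channel(self) -> str:
        return mirror_channel(self.ipsilesional_channel)

    def depth(self, session_index: int, sessions: int) -> float:
        if not 1 <= session_index <= sessions:
            raise ValueError(f"session_index {session_index} out of range 1..{sessions}")
        return self.erd_depth_schedule[session_index - 1]


def phenotype_schedule(phenotype: str, sessions: int = 12) -> tuple[float, ...]:
    """Per-session g values implementing the phenotype's longitudinal course."""
    if phenotype not in PHENOTYPES:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    start, end = _PHENOTYPE_DEPTH[phenotype]
    if phenotype == "bilateral_mixed":
        return tuple(start if s % 2 == 0 else end for s in range(sessions))
    if sessions == 1:
        return (start,)
    return tuple(start + (end - start) * s / (sessions - 1) for s in range(sessions))


def make_patient(patient_id: str, lesion_side: str, phenotype: str,
                 sessions: int = 12, contralesional_ratio: float | None = None) -> VirtualPatient:
    if contralesional_ratio is None:
        contralesional_ratio = 1.0 if phenotype == "bilateral_mixed" else 0.8
    return VirtualPatient(patient_id, lesion_side, phenotype,
                          phenotype_schedule(phenotype, sessions), contralesional_ratio)


def default_cohort(sessions: int = 12) -> list[VirtualPatient]:
    """Seven virtual patients mirroring the studied phenotype mix.

    Two with increasingly deep ERD, two with sustained deep ERD, two with
    weak/no modulation (right-hemisphere lesions), one bilateral/mixed.
    """
    roster = [
        ("P01", "left", "increasing"),
        ("P02", "right", "weak"),
        ("P03", "left", "increasing"),
        ("P04", "left", "sustained"),
        ("P05", "left", "sustained"),
        ("P06", "left", "bilateral_mixed"),
        ("P07", "right", "weak"),
    ]
    return [make_patient(pid, side, ph, sessions) for pid, side, ph in roster]


# ---------------------------------------------------------------------------
# Signal primitives
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, n_channels: int,
                fs: float, exponent: float) -> np.ndarray:
    """(n, n_channels) Gaussian 1/f^exponent noise, unit std per channel."""
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal((nfft, n_channels))
    spectrum = sfft.rfft(white, axis=0)
    f = sfft.rfftfreq(nfft, d=1.0 / fs)
    f_ref = 0.5  # flatten below 0.5 Hz to keep variance finite
    shape = np.where(f < f_ref, f_ref, f) ** (-exponent / 2.0)
    shape[0] = 0.0
    out = sfft.irfft(spectrum * shape[:, None], n=nfft, axis=0)[:n]
    out /= out.std(axis=0, keepdims=True)
    return out


def _band_source(rng: np.random.Generator, n: int, fs: float,
                 low: float, high: float) -> np.ndarray:
    """Unit-std band-limited Gaussian oscillation (rhythm source)."""
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _rhythm(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    return (config.mu_amplitude * _band_source(rng, n, config.sampling_rate, 8.0, 13.0)
            + config.beta_amplitude * _band_source(rng, n, config.sampling_rate, 14.0, 30.0))


def spatial_profile(montage: Montage, center_label: str, sigma: float | None = None) -> np.ndarray:
    """Gaussian channel weights centred at an electrode (peak weight 1)."""
    pos = montage.position_array()
    center = np.asarray(montage.positions[center_label])
    if sigma is None:
        sigma = montage.spacing()
    d2 = ((pos - center) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * sigma**2))


def _hemisphere_gains(patient: VirtualPatient, g: float) -> tuple[float, float]:
    """Task-window power fractions at (ipsilesional, contralesional) sources."""
    return g, 1.0 - patient.contralesional_ratio * (1.0 - g)


def _render(n: int, config: SimulationConfig, patient: VirtualPatient,
            env_ipsi: np.ndarray, env_contra: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Mix background + enveloped bilateral rhythm sources to the cap."""
    mont = config.montage
    data = config.pink_noise_std * _pink_noise(rng, n, mont.n_channels,
                                               config.sampling_rate, config.noise_exponent)
    data += config.sensor_noise_std * rng.standard_normal((n, mont.n_channels))
    prof_i = spatial_profile(mont, patient.ipsilesional_channel)
    prof_c = spatial_profile(mont, patient.contralesional_channel)
    src_i = _rhythm(rng, n, config) * env_ipsi
    src_c = _rhythm(rng, n, config) * env_contra
    data += np.outer(src_i, prof_i) + np.outer(src_c, prof_c)
    return data


def _task_window(config: SimulationConfig, cue_sample: int) -> tuple[int, int]:
    fs = config.sampling_rate
    return cue_sample + round(1.0 * fs), cue_sample + round(4.0 * fs)


# ---------------------------------------------------------------------------
# Simulation operations
# ---------------------------------------------------------------------------

def simulate_trial(patient: VirtualPatient, session_index: int, label: str,
                   config: SimulationConfig, rng: np.random.Generator):
    """One 11-s trial segment: (samples x channels array, cue Marker)."""
    if label not in (TASK, IDLE):
        raise ValueError(f"unknown trial label {label!r}")
    g = patient.depth(session_index, config.sessions)
    n = round(config.trial_duration * config.sampling_rate)
    cue = round(config.cue_time * config.sampling_rate)
    env_i = np.ones(n)
    env_c = np.ones(n)
    if label == TASK:
        gi, gc = _hemisphere_gains(patient, g)
        lo, hi = _task_window(config, cue)
        env_i[lo:hi] = np.sqrt(gi)
        env_c[lo:hi] = np.sqrt(gc)
    data = _render(n, config, patient, env_i, env_c, rng)
    return data, Marker(cue, label, run=1)


def simulate_session(patient: VirtualPatient, session_index: int,
                     config: SimulationConfig, rng: np.random.Generator) -> Recording:
    """One continuous training session: 3 runs x 30 balanced cued trials.

    Trials are preceded by uniformly jittered rest intervals; the rhythm and
    background are generated continuously so there are no splice artefacts.
    """
    g = patient.depth(session_index, config.sessions)
    gi, gc = _hemisphere_gains(patient, g)
    fs = config.sampling_rate
    n_trial = round(config.trial_duration * fs)
    cue_off = round(config.cue_time * fs)

    markers: list[Marker] = []
    task_windows: list[tuple[int, int]] = []
    cursor = 0
    for run in range(1, config.runs_per_session + 1):
        half = config.trials_per_run // 2
        labels = [TASK] * half + [IDLE] * (config.trials_per_run - half)
        labels = [labels[i] for i in rng.permutation(config.trials_per_run)]
        for label in labels:
            rest = rng.uniform(*config.rest_interval)
            cursor += round(rest * fs)
            cue = cursor + cue_off
            markers.append(Marker(cue, label, run))
            if label == TASK:
                task_windows.append(_task_window(config, cue))
            cursor += n_trial
    n_total = cursor + round(config.rest_interval[1] * fs)  # trailing rest pad

    env_i = np.ones(n_total)
    env_c = np.ones(n_total)
    for lo, hi in task_windows:
        env_i[lo:hi] = np.sqrt(gi)
        env_c[lo:hi] = np.sqrt(gc)
    data = _render(n_total, config, patient, env_i, env_c, rng)
    return Recording(data, fs, markers, config.montage)


def ground_truth_rows(patient: VirtualPatient, session_index: int,
                      config: SimulationConfig) -> list[dict]:
    """Programmed per-channel ERD fractions (E = g - 1) for one session."""
    g = patient.depth(session_index, config.sessions)
    gi, gc = _hemisphere_gains(patient, g)
    return [
        {"patient_id": patient.patient_id, "session": session_index,
         "channel": patient.ipsilesional_channel, "hemisphere": "ipsilesional",
         "g": gi, "true_erd": gi - 1.0, "phenotype": patient.phenotype},
        {"patient_id": patient.patient_id, "session": session_index,
         "channel": patient.contralesional_channel, "hemisphere": "contralesional",
         "g": gc, "true_erd": gc - 1.0, "phenotype": patient.phenotype},
    ]


def session_rng(config: SimulationConfig, patient: VirtualPatient,
                session_index: int) -> np.random.Generator:
    """Stream-independent RNG for one (patient, session): order-insensitive."""
    import zlib

    pid = zlib.crc32(patient.patient_id.encode("utf-8"))
    return np.random.Generator(np.random.Philox(
        key=config.rng_seed, counter=[0, 0, pid, session_index]))


def simulate_longitudinal_study(config: SimulationConfig,
                                patients: list[VirtualPatient],
                                out_dir: str | Path) -> pd.DataFrame:
    """Write every session's BrainVision triplet plus a ground-truth table.

    Files are ``<out_dir>/<patient>_s<session>.vhdr/.vmrk/.eeg`` and
    ``<out_dir>/ground_truth.csv``. Returns the ground-truth table.
    """
    if not patients:
        raise ValueError("need at least one patient")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for patient in patients:
        for s in range(1, config.sessions + 1):
            rec = simulate_session(patient, s, config, session_rng(config, patient, s))
            write_brainvision(rec, out_dir / f"{patient.patient_id}_s{s:02d}")
            rows.extend(ground_truth_rows(patient, s, config))
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return truth
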