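"""Shared fixtures: simulated sessions and epoch builders reused across tests."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import smrbci as sb


def constant_depth_patient(g: float, lesion_side: str = "left",
                           sessions: int = 12) -> sb.VirtualPatient:
    """Patient whose ERD depth is the same fraction g in every session."""
    return sb.VirtualPatient("PX", lesion_side, "sustained", (g,) * sessions,
                             contralesional_ratio=0.8)


def task_epochs(g: float, n_trials: int, seed: int,
                config: sb.SimulationConfig | None = None) -> sb.EpochSet:
    """Task-trial epochs cut at [-2.5, 6.5) s around the cue (TF-ready)."""
    cfg = config or sb.SimulationConfig(rng_seed=seed)
    pat = constant_depth_patient(g)
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    lo = round((cfg.cue_time - 2.5) * fs)
    hi = round((cfg.cue_time + 6.5) * fs)
    data = []
    for _ in range(n_trials):
        seg, _marker = sb.simulate_trial(pat, 1, "task", cfg, rng)
        data.append(seg[lo:hi].T)
    return sb.EpochSet(np.array(data), np.array(["task"] * n_trials),
                       np.ones(n_trials, dtype=int), (-2.5, 6.5), fs, cfg.montage)


@pytest.fixture(scope="session")
def sim_config():
    return sb.SimulationConfig(rng_seed=7)


@pytest.fixture(scope="session")
def strong_patient():
    return dataclasses.replace(constant_depth_patient(0.2), patient_id="PSTRONG")


@pytest.fixture(scope="session")
def strong_session(sim_config, strong_patient):
    """One full 3x30-trial session with deep (g=0.2) ERD."""
    return sb.simulate_session(strong_patient, 1, sim_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def strong_decode_epochs(strong_session):
    """Band-filtered task/idle decoding epochs of the strong session."""
    return sb.decoding_epochs(sb.bandpass(strong_session, 8.0, 30.0))


@pytest.fixture(scope="session")
def strong_task_wide(strong_session):
    """Wide task epochs of the strong session for time-frequency analysis."""
    return sb.extract_epochs(strong_session, -4.0, 7.0, label_filter={"task"})


@pytest.fixture(scope="session")
def small_study_config(tmp_path_factory):
    """Two-session miniature study used for end-to-end/determinism checks."""
    def make(out_name: str, seed: int = 3) -> sb.StudyConfig:
        sim = sb.SimulationConfig(sessions=2, trials_per_run=10, rng_seed=seed)
        patients = [sb.make_patient("P01", "left", "increasing", sessions=2),
                    sb.make_patient("P02", "right", "weak", sessions=2)]
        out = tmp_path_factory.mktemp("study") / out_name
        return sb.StudyConfig(simulation=sim, patients=patients, out_dir=out, seed=seed)
    return make
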