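"""EEG containers and I/O: BrainVision triplets, band filtering, epoch cutting.

A :class:`Recording` is a continuous multichannel signal (time x channels, uV)
with cue markers; an :class:`EpochSet` holds fixed-length labelled trial
segments cut relative to those markers. BrainVision files are the plain-text
header / marker / raw-binary triplet (.vhdr/.vmrk/.eeg) written by Brain
Products amplifiers; we support multiplexed IEEE_FLOAT_32 and INT_16 (with
per-channel resolution scaling).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal

from .montage import Montage, default_montage

logger = logging.getLogger(__name__)

TASK = "task"
IDLE = "idle"

#: BrainVision stimulus descriptions for the two cue classes.
_MARKER_CODE = {TASK: "S  1", IDLE: "S  2"}
_CODE_MARKER = {v: k for k, v in _MARKER_CODE.items()}


@dataclass(frozen=True)
class Marker:
    """Cue event: sample index of cue onset, trial class, acquisition run."""

    sample: int
    label: str
    run: int = 1


@dataclass
class Recording:
    """Continuous EEG: (n_samples, n_channels) in uV plus cue markers."""

    data: np.ndarray
    sfreq: float
    markers: list[Marker]
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (samples x channels)")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        n = self.data.shape[0]
        for m in self.markers:
            if not 0 <= m.sample < n:
                raise ValueError(f"marker sample {m.sample} outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochSet:
    """Labelled fixed-length trials: (n_trials, n_channels, n_samples)."""

    data: np.ndarray
    labels: np.ndarray
    runs: np.ndarray
    window: tuple[float, float]
    sfreq: float
    montage: Montage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (trials x channels x samples)")
        if len(self.labels) != len(self.data) or len(self.runs) != len(self.data):
            raise ValueError("labels/runs length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the cue (half-open window)."""
        n = self.data.shape[2]
        start = round(self.window[0] * self.sfreq)
        return (start + np.arange(n)) / self.sfreq

    def select_channels(self, labels) -> "EpochSet":
        idx = [self.montage.index(l) for l in labels]
        return replace(self, data=self.data[:, idx, :], montage=self.montage.subset(tuple(labels)))

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], labels=self.labels[mask], runs=self.runs[mask])


# ---------------------------------------------------------------------------
# BrainVision triplet
# ---------------------------------------------------------------------------

def write_brainvision(recording: Recording, path: str | Path,
                      binary_format: str = "IEEE_FLOAT_32",
                      resolution: float = 0.1) -> tuple[Path, Path, Path]:
    """Write ``path``.vhdr/.vmrk/.eeg (multiplexed, little-endian).

    ``resolution`` (uV per integer unit) only applies to INT_16 output.
    Returns the three paths written.
    """
    path = Path(path)
    if path.suffix == ".vhdr":
        path = path.with_suffix("")
    vhdr, vmrk, eeg = (path.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    if binary_format not in ("IEEE_FLOAT_32", "INT_16"):
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}")

    res = 1.0 if binary_format == "IEEE_FLOAT_32" else resolution
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={1e6 / recording.sfreq:g}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, label in enumerate(recording.montage.labels, start=1):
        lines.append(f"Ch{i}={label},,{res:g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    k = 2
    prev_run = None
    for m in sorted(recording.markers, key=lambda m: m.sample):
        if prev_run is not None and m.run != prev_run:
            mlines.append(f"Mk{k}=New Segment,,{m.sample + 1},1,0,00000000000000000000")
            k += 1
        prev_run = m.run
        mlines.append(f"Mk{k}=Stimulus,{_MARKER_CODE[m.label]},{m.sample + 1},1,0")
        k += 1
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    if binary_format == "IEEE_FLOAT_32":
        raw = recording.data.astype("<f4")
    else:
        scaled = np.round(recording.data / res)
        if np.any(np.abs(scaled) > 32767):
            logger.warning("INT_16 export clips samples beyond ±%g µV", 32767 * res)
        raw = np.clip(scaled, -32768, 32767).astype("<i2")
    raw.tofile(eeg)
    return vhdr, vmrk, eeg


def _parse_vhdr_sections(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = sections.setdefault(m.group(1), {})
        elif "=" in line and current is not None:
            key, _, val = line.partition("=")
            current[key.strip()] = val.strip()
    return sections


def read_brainvision(path: str | Path, montage: Montage | None = None) -> Recording:
    """Read a BrainVision triplet given its .vhdr path.

    If ``montage`` is omitted, the default 31-channel montage is used when the
    header labels match it; otherwise positions are assigned by nearest
    template label and missing labels raise.
    """
    vhdr = Path(path)
    if vhdr.suffix != ".vhdr":
        vhdr = vhdr.with_suffix(".vhdr")
    sections = _parse_vhdr_sections(vhdr.read_text(encoding="utf-8"))
    try:
        common = sections["Common Infos"]
        n_chan = int(common["NumberOfChannels"])
        samp_int_us = float(common["SamplingInterval"])
        data_file = common["DataFile"]
        marker_file = common.get("MarkerFile")
        binfo = sections["Binary Infos"]
        binary_format = binfo["BinaryFormat"]
        chan_info = sections["Channel Infos"]
    except KeyError as exc:
        raise ValueError(f"malformed BrainVision header {vhdr}: missing {exc}") from exc
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")

    labels, resolutions = [], []
    for i in range(1, n_chan + 1):
        parts = chan_info[f"Ch{i}"].split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    resolutions = np.array(resolutions)

    eeg = vhdr.parent / data_file
    if binary_format == "IEEE_FLOAT_32":
        raw = np.fromfile(eeg, dtype="<f4").reshape(-1, n_chan).astype(np.float64)
        data = raw * resolutions  # resolution is typically 1 for float data
    elif binary_format == "INT_16":
        raw = np.fromfile(eeg, dtype="<i2").reshape(-1, n_chan).astype(np.float64)
        data = raw * resolutions
    else:
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}")

    markers: list[Marker] = []
    if marker_file:
        run = 0
        msec = _parse_vhdr_sections((vhdr.parent / marker_file).read_text(encoding="utf-8"))
        infos = msec.get("Marker Infos", {})
        for key in sorted(infos, key=lambda k: int(k[2:])):
            parts = infos[key].split(",")
            mtype, desc, pos = parts[0], parts[1], int(parts[2])
            if mtype == "New Segment":
                run += 1
            elif mtype == "Stimulus" and desc in _CODE_MARKER:
                markers.append(Marker(pos - 1, _CODE_MARKER[desc], max(run, 1)))

    if montage is None:
        montage = Montage(tuple(labels), {
            l: default_montage().positions[l.upper()] for l in labels
        })
    return Recording(data, 1e6 / samp_int_us, markers, montage)


# ---------------------------------------------------------------------------
# Filtering and epoching
# ---------------------------------------------------------------------------

def bandpass(obj, low_hz: float, high_hz: float, order: int = 4):
    """Zero-phase Butterworth band-pass (forward-backward), same type out.

    Accepts a :class:`Recording`, an :class:`EpochSet`, or a bare array whose
    last-but-one (Recording-style: first) axis is time.
    """
    if isinstance(obj, Recording):
        nyq = obj.sfreq / 2
    elif isinstance(obj, EpochSet):
        nyq = obj.sfreq / 2
    else:
        raise TypeError("bandpass expects a Recording or EpochSet")
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"invalid band edges ({low_hz}, {high_hz}) for fs/2={nyq}")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=2 * nyq, output="sos")
    if isinstance(obj, Recording):
        return replace(obj, data=signal.sosfiltfilt(sos, obj.data, axis=0))
    return replace(obj, data=signal.sosfiltfilt(sos, obj.data, axis=2))


def extract_epochs(recording: Recording, window_start_s: float, window_end_s: float,
                   label_filter=None) -> EpochSet:
    """Cut one epoch per (selected) marker over [start, end) s around the cue.

    Sample convention: start inclusive, end exclusive, so a [1, 4) s window at
    200 Hz is samples cue+200 ... cue+799. Markers whose window would run past
    either recording edge are dropped with a logged count.
    """
    if window_end_s <= window_start_s:
        raise ValueError("window end must exceed start")
    fs = recording.sfreq
    start_off = round(window_start_s * fs)
    n_samp = round((window_end_s - window_start_s) * fs)
    epochs, labels, runs = [], [], []
    dropped = 0
    for m in sorted(recording.markers, key=lambda m: m.sample):
        if label_filter is not None and m.label not in label_filter:
            continue
        lo = m.sample + start_off
        hi = lo + n_samp
        if lo < 0 or hi > recording.n_samples:
            dropped += 1
            continue
        epochs.append(recording.data[lo:hi].T)
        labels.append(m.label)
        runs.append(m.run)
    if dropped:
        logger.warning("extract_epochs: dropped %d trial(s) at recording edges", dropped)
    data = np.array(epochs) if epochs else np.empty((0, recording.n_channels, n_samp))
    return EpochSet(data, np.array(labels), np.array(runs, dtype=int),
                    (window_start_s, window_end_s), fs, recording.montage)


def decoding_epochs(recording: Recording,
                    task_window: tuple[float, float] = (1.0, 4.0),
                    idle_window: tuple[float, float] = (-4.0, -1.0)) -> EpochSet:
    """Task/idle state epochs for decoding, in acquisition order.

    The task state is the [1, 4) s window after each task cue (motor attempt
    under way); the idle state is a [−4, −1) s pre-cue rest window, taken
    around the static-trial cues. Both windows are 3 s, giving one labelled
    epoch per trial.
    """
    fs = recording.sfreq
    windows = {TASK: task_window, IDLE: idle_window}
    n_samp = round((task_window[1] - task_window[0]) * fs)
    if n_samp != round((idle_window[1] - idle_window[0]) * fs):
        raise ValueError("task and idle windows must have equal length")
    data, labels, runs = [], [], []
    dropped = 0
    for m in sorted(recording.markers, key=lambda m: m.sample):
        w = windows[m.label]
        lo = m.sample + round(w[0] * fs)
        hi = lo + n_samp
        if lo < 0 or hi > recording.n_samples:
            dropped += 1
            continue
        data.append(recording.data[lo:hi].T)
        labels.append(m.label)
        runs.append(m.run)
    if dropped:
        logger.warning("decoding_epochs: dropped %d trial(s) at recording edges", dropped)
    return EpochSet(np.array(data), np.array(labels), np.array(runs, dtype=int),
                    task_window, recording.sfreq, recording.montage)


def epochs_to_csv(epochs: EpochSet, path: str | Path) -> Path:
    """Long-format CSV export: trial, channel, sample, value."""
    import pandas as pd

    n_t, n_c, n_s = epochs.data.shape
    t, c, s = np.meshgrid(np.arange(n_t), np.arange(n_c), np.arange(n_s), indexing="ij")
    df = pd.DataFrame({
        "trial": t.ravel(),
        "channel": np.asarray(epochs.montage.labels)[c.ravel()],
        "sample": s.ravel(),
        "value": epochs.data.ravel(),
    })
    path = Path(path)
    df.to_csv(path, index=False)
    return path
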