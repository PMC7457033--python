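"""Time–frequency power and ERD/ERS quantification.

A windowed Fourier transform with a fixed 200 ms Hanning window yields a
complex estimate F(t, f) on a dense grid (default −2000..6000 ms in 5 ms
steps, 1..30 Hz in 1 Hz steps); power is P = |F|², trial-averaged. The
relative power change against a pre-cue resting baseline,

    E = (A − R) / R,

with A the mean power over the post-cue interest window and R over the
baseline window, is negative for event-related desynchronisation (ERD) and
positive for synchronisation (ERS). Scalp topographies evaluate E per
channel over a short window and interpolate between electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig

from .io import EpochSet
from .montage import Montage

DEFAULT_FREQS = np.arange(1.0, 31.0)  # 1..30 Hz in 1 Hz steps
DEFAULT_BAND = (8.0, 30.0)
DEFAULT_BASELINE = (-2.0, 0.0)
DEFAULT_INTEREST = (1.0, 4.0)
TOPO_WINDOW = (1.4, 1.6)


@dataclass
class TimeFrequencyMap:
    """Complex F(t, f) for one epoch: (channels, freqs, times)."""

    F: np.ndarray
    times: np.ndarray  # s relative to cue
    freqs: np.ndarray  # Hz
    channels: tuple[str, ...]
    edge_flag: np.ndarray  # True where the analysis window was truncated

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.F) ** 2


@dataclass
class PowerMap:
    """Trial-averaged power P(t, f): (channels, freqs, times)."""

    P: np.ndarray
    times: np.ndarray
    freqs: np.ndarray
    channels: tuple[str, ...]
    n_trials: int


def _hann_kernels(freqs: np.ndarray, sfreq: float, window_ms: float) -> np.ndarray:
    """Complex convolution kernels, one per frequency (freqs, n_taps)."""
    half = round(window_ms / 2000.0 * sfreq)
    n = np.arange(-half, half + 1)
    h = sig.windows.hann(2 * half + 1, sym=True)
    return h[None, :] * np.exp(2j * np.pi * np.asarray(freqs)[:, None] * n / sfreq)


def windowed_fourier(epoch: np.ndarray, sfreq: float, epoch_start_s: float,
                     channels: tuple[str, ...] | None = None,
                     tmin: float = -2.0, tmax: float = 6.0, tstep: float = 0.005,
                     freqs: np.ndarray = DEFAULT_FREQS,
                     window_ms: float = 200.0,
                     dtype=np.complex128) -> TimeFrequencyMap:
    """Windowed Fourier transform of one epoch (channels x samples).

    F(t, f) = sum_n x(t+n) h(n) exp(−i 2π f n / fs) with h a Hanning window
    centred on t; frequencies are evaluated by direct DTFT (no FFT-bin
    snapping). Grid times within half a window of the epoch edges are
    computed on the truncated window and flagged.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=np.float64))
    n_samp = epoch.shape[1]
    if channels is None:
        channels = tuple(f"ch{i}" for i in range(epoch.shape[0]))
    step = tstep * sfreq
    if abs(step - round(step)) > 1e-9:
        raise ValueError("tstep must be an integer number of samples")
    step = round(step)
    kernels = _hann_kernels(freqs, sfreq, window_ms)
    n_taps = kernels.shape[1]
    if n_samp < n_taps:
        raise ValueError("epoch shorter than one analysis window")
    # conv kernel k(m) = h(m) exp(+i2pi f m/fs) gives the correlation above;
    # one batched FFT convolution across all frequencies and channels
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n_samp + n_taps - 1)
    Xf = sfft.fft(epoch.astype(dtype), nfft, axis=-1)
    Kf = sfft.fft(kernels.astype(dtype), nfft, axis=-1)
    full = sfft.ifft(Kf[:, None, :] * Xf[None, :, :], axis=-1)
    start = (n_taps - 1) // 2  # 'same' alignment: F(t) centred on sample t
    F_full = full[:, :, start:start + n_samp]

    idx0 = round((tmin - epoch_start_s) * sfreq)
    n_t = round((tmax - tmin) / tstep) + 1
    idx = idx0 + step * np.arange(n_t)
    if idx[0] < 0 or idx[-1] >= n_samp:
        raise ValueError("requested time grid extends beyond the epoch")
    times = tmin + tstep * np.arange(n_t)
    half = (kernels.shape[1] - 1) // 2
    edge = (idx < half) | (idx >= n_samp - half)
    F = np.transpose(F_full[:, :, idx], (1, 0, 2))
    return TimeFrequencyMap(F, times, np.asarray(freqs, dtype=float), channels, edge)


def power_map(epochs: EpochSet, channels=None, **tf_kwargs) -> PowerMap:
    """Trial-averaged |F|² over an epoch set (optionally a channel subset).

    Per-trial transforms run in single precision (power is accumulated in
    double); the relative error this introduces is far below trial-to-trial
    sampling noise.
    """
    if channels is not None:
        epochs = epochs.select_channels(list(channels))
    if epochs.n_trials == 0:
        raise ValueError("empty epoch set")
    tf_kwargs.setdefault("dtype", np.complex64)
    start = epochs.window[0]
    acc = None
    tf = None
    for k in range(epochs.n_trials):
        tf = windowed_fourier(epochs.data[k], epochs.sfreq, start,
                              channels=epochs.montage.labels, **tf_kwargs)
        p = tf.power.astype(np.float64)
        acc = p if acc is None else acc + p
    return PowerMap(acc / epochs.n_trials, tf.times, tf.freqs,
                    epochs.montage.labels, epochs.n_trials)


def _window_mask(axis: np.ndarray, lo: float, hi: float) -> np.ndarray:
    mask = (axis >= lo - 1e-9) & (axis <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"window [{lo}, {hi}] not covered by grid")
    return mask


def erd(power: PowerMap, baseline: tuple[float, float] = DEFAULT_BASELINE,
        interest: tuple[float, float] = DEFAULT_INTEREST,
        band: tuple[float, float] = DEFAULT_BAND):
    """Relative power change E = (A − R) / R, as a fraction.

    Returns ``(E_scalar_per_channel, E_map)`` where the scalar averages over
    the interest-window x band cells and E_map is the full per-frequency
    baseline-normalised map (channels, freqs, times).
    """
    t_base = _window_mask(power.times, *baseline)
    t_int = _window_mask(power.times, *interest)
    f_band = _window_mask(power.freqs, *band)
    R_f = power.P[:, :, t_base].mean(axis=2)  # per channel x freq
    if np.any(R_f <= 0):
        raise ValueError("baseline power is zero: E undefined")
    E_map = power.P / R_f[:, :, None] - 1.0
    A = power.P[:, f_band][:, :, t_int].mean(axis=(1, 2))
    R = R_f[:, f_band].mean(axis=1)
    return (A - R) / R, E_map


def channel_erd(epochs: EpochSet, channel_label: str,
                band: tuple[float, float] = DEFAULT_BAND,
                interest: tuple[float, float] = DEFAULT_INTEREST,
                baseline: tuple[float, float] = DEFAULT_BASELINE,
                **tf_kwargs) -> float:
    """Scalar ERD/ERS at one electrode: trial-averaged power, then E=(A−R)/R."""
    pm = power_map(epochs, channels=[channel_label], **tf_kwargs)
    scalar, _ = erd(pm, baseline=baseline, interest=interest, band=band)
    return float(scalar[0])


@dataclass
class TopographyFrame:
    """Per-channel ERD values for one time window, with scalp positions."""

    values: np.ndarray  # one scalar per montage channel
    montage: Montage
    window: tuple[float, float]
    band: tuple[float, float]

    def value(self, label: str) -> float:
        return float(self.values[self.montage.index(label)])

    def evaluate(self, points: np.ndarray, power: float = 2.0) -> np.ndarray:
        """Inverse-distance-weighted interpolation at arbitrary 2-D points.

        Exact at electrode sites (a point coinciding with an electrode
        returns that electrode's value).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pos = self.montage.position_array()
        d = np.linalg.norm(pts[:, None, :] - pos[None, :, :], axis=-1)
        hit = d < 1e-12
        with np.errstate(divide="ignore"):
            w = d ** (-power)
        w[hit.any(axis=1)] = hit[hit.any(axis=1)].astype(float)
        return (w @ self.values) / w.sum(axis=1)

    def interpolate(self, grid_size: int = 64, power: float = 2.0):
        """IDW scalp grid; ``zz`` is masked outside the head circle."""
        pos = self.montage.position_array()
        radius = np.linalg.norm(pos, axis=1).max() * 1.05
        g = np.linspace(-radius, radius, grid_size)
        xx, yy = np.meshgrid(g, g)
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
        zz = self.evaluate(pts, power=power).reshape(xx.shape)
        zz = np.ma.masked_where(xx**2 + yy**2 > radius**2, zz)
        return xx, yy, zz

    def plot(self, ax=None, grid_size: int = 64, cmap: str = "RdBu_r"):
        """Quick scalp-map rendering (values only, not publication styling)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xx, yy, zz = self.interpolate(grid_size)
        vmax = np.abs(self.values).max() or 1.0
        im = ax.pcolormesh(xx, yy, zz, cmap=cmap, vmin=-vmax, vmax=vmax, shading="auto")
        pos = self.montage.position_array()
        ax.scatter(pos[:, 0], pos[:, 1], s=8, c="k")
        ax.set_aspect("equal")
        ax.set_axis_off()
        return im


def topography(epochs: EpochSet, window: tuple[float, float] = TOPO_WINDOW,
               band: tuple[float, float] = DEFAULT_BAND,
               baseline: tuple[float, float] = DEFAULT_BASELINE,
               **tf_kwargs) -> TopographyFrame:
    """Per-channel ERD over a short post-cue window (default [1.4, 1.6] s)."""
    pm = power_map(epochs, **tf_kwargs)
    scalar, _ = erd(pm, baseline=baseline, interest=window, band=band)
    return TopographyFrame(scalar, epochs.montage, window, band)
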