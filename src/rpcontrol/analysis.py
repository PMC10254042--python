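"""Spectral diagnostics of optimized waveforms: FFT power spectra,
Hann-windowed short-time Fourier transforms, and the eigenvalue-difference
stick spectrum used to annotate peaks."""

from __future__ import annotations

import numpy as np
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann

from .spin_core import resonance_frequencies


def _check_uniform(times_us: np.ndarray) -> float:
    """Return the sampling step (us); reject non-uniform grids."""
    dt = np.diff(times_us)
    if len(dt) == 0:
        raise ValueError("need at least two samples")
    if np.max(np.abs(dt - dt[0])) > 1e-9 * max(abs(dt[0]), 1e-30):
        raise ValueError("power spectrum requires a uniform time grid")
    return float(dt[0])


def power_spectrum(
    u: np.ndarray,
    sample_step_ns: float | None = None,
    times_us: np.ndarray | None = None,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided power spectrum of a real waveform.

    Returns ``(frequency_MHz, power)``.  Without normalization the
    spectrum satisfies Parseval exactly: ``power.sum() == (u**2).sum()``;
    with ``normalize`` the spectrum is scaled to max = 1 (the published
    spectra are unitless overlays, only peak positions/ratios matter).
    """
    u = np.asarray(u, dtype=float)
    if times_us is not None:
        dt_us = _check_uniform(np.asarray(times_us))
    elif sample_step_ns is not None:
        dt_us = sample_step_ns * 1e-3
    else:
        raise ValueError("provide sample_step_ns or times_us")
    n = len(u)
    spec = np.fft.rfft(u)
    power = np.abs(spec) ** 2 / n
    # fold the negative-frequency half into the one-sided spectrum
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freq = np.fft.rfftfreq(n, d=dt_us)  # cycles/us == MHz
    if normalize and power.max() > 0:
        power = power / power.max()
    return freq, power


def stft(
    u: np.ndarray,
    sample_step_ns: float,
    window_ns: float = 256.0,
    hop_ns: float = 16.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hann-windowed short-time Fourier transform magnitude map.

    Returns ``(time_us, frequency_MHz, magnitude)`` with magnitude of
    shape (n_freq, n_time).  Window and hop are given in ns, as in the
    published spectrogram settings (256/16 ns and 300/10 ns).
    """
    u = np.asarray(u, dtype=float)
    n_win = int(round(window_ns / sample_step_ns))
    n_hop = int(round(hop_ns / sample_step_ns))
    if n_win > len(u):
        raise ValueError("window longer than signal")
    if n_hop > n_win:
        raise ValueError("hop larger than window")
    if n_hop < 1 or n_win < 2:
        raise ValueError("window/hop too short for the sampling step")
    fs_MHz = 1e3 / sample_step_ns  # samples per us
    transform = ShortTimeFFT(
        hann(n_win, sym=False), hop=n_hop, fs=fs_MHz, scale_to="magnitude"
    )
    s = transform.stft(u)
    t_us = transform.t(len(u))
    f_MHz = transform.f
    return t_us, f_MHz, np.abs(s)


def stick_spectrum(
    h: np.ndarray, transition_operator: np.ndarray | None = None,
    min_intensity: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Transition lines (frequency MHz, relative intensity) of a Hamiltonian.

    Intensities are |<i|V|j>|^2 normalized to max 1 and thresholded, the
    native substitute for an overlaid ESR powder simulation.
    """
    lines = resonance_frequencies(h, transition_operator)
    freqs = np.array([l[0] for l in lines])
    inten = np.array([l[3] for l in lines])
    if inten.max() > 0:
        inten = inten / inten.max()
    keep = inten >= min_intensity
    return freqs[keep], inten[keep]


def dominant_peak_MHz(
    freq: np.ndarray, power: np.ndarray, f_min_MHz: float = 1.0
) -> float:
    """Frequency of the strongest spectral peak above a low-frequency cutoff."""
    mask = freq >= f_min_MHz
    return float(freq[mask][np.argmax(power[mask])])
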