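"""Spectra, Hilbert envelopes and SNR statistics for both paradigms.

Two SNR definitions are used.  For the steady-state visual response, SNR is
the on-window spectral amplitude at the fundamental frequency divided by the
mean off-window amplitude in a 4 Hz band centred on that frequency.  For
frontal-midline theta, SNR is the difference of the trial-averaged Hilbert
envelope between task and rest windows divided by the rest-window standard
deviation of that envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "Spectrum",
    "EnvelopeResult",
    "trial_fft_spectrum",
    "welch_asd",
    "hilbert_envelope",
    "snr_visual",
    "snr_nback",
    "instantaneous_snr",
]


@dataclass
class Spectrum:
    frequencies: np.ndarray
    amplitudes: np.ndarray
    estimator: str = "fft"

    def __post_init__(self):
        f = np.asarray(self.frequencies, float)
        a = np.asarray(self.amplitudes, float)
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("amplitudes must be non-negative")
        self.frequencies, self.amplitudes = f, a

    def at(self, f0: float) -> float:
        """Amplitude at the bin nearest to f0."""
        return float(self.amplitudes[np.argmin(np.abs(self.frequencies - f0))])

    def band_mean(self, lo: float, hi: float) -> float:
        sel = (self.frequencies >= lo) & (self.frequencies <= hi)
        if not sel.any():
            raise ValueError("band contains no frequency bins")
        return float(self.amplitudes[sel].mean())


def trial_fft_spectrum(trials: np.ndarray, fs: float, f_check: float | None = None) -> Spectrum:
    """Trial-averaged one-sided amplitude spectrum (rectangular window).

    ``trials`` is (n_trials, n_samples); amplitudes use the 2/N convention so
    a unit sinusoid centred on a bin has amplitude 1.
    """
    trials = np.atleast_2d(np.asarray(trials, float))
    n = trials.shape[1]
    if f_check is not None and n < fs / f_check:
        warnings.warn("window shorter than one cycle of the target frequency", stacklevel=2)
    amp = 2.0 / n * np.abs(np.fft.rfft(trials, axis=1))
    amp[:, 0] /= 2.0
    if n % 2 == 0:
        amp[:, -1] /= 2.0
    return Spectrum(np.fft.rfftfreq(n, 1 / fs), amp.mean(axis=0), "fft")


def welch_asd(x: np.ndarray, fs: float, segment: float = 20.0, overlap: float = 10.0) -> Spectrum:
    """Amplitude spectral density (units /√Hz) via Welch's method (Hann)."""
    x = np.asarray(x, float)
    nper = int(round(segment * fs))
    nov = int(round(overlap * fs))
    if nper > x.shape[-1]:
        warnings.warn("data shorter than one segment; using a single segment", stacklevel=2)
        nper, nov = x.shape[-1], 0
    f, psd = sps.welch(x, fs=fs, nperseg=nper, noverlap=nov, window="hann", axis=-1)
    psd = psd.mean(axis=tuple(range(psd.ndim - 1))) if psd.ndim > 1 else psd
    return Spectrum(f[1:], np.sqrt(psd[1:]), "welch")


@dataclass
class EnvelopeResult:
    """Trial-averaged Hilbert envelope with baseline-relative change."""

    time: np.ndarray
    envelope: np.ndarray
    baseline: float
    relative_change: np.ndarray
    edge_trim: float = 0.5

    def window_mean(self, t0, t1):
        sel = self._sel(t0, t1)
        return float(self.envelope[sel].mean())

    def window_sd(self, t0, t1):
        sel = self._sel(t0, t1)
        return float(self.envelope[sel].std())

    def _sel(self, t0, t1):
        sel = (self.time >= t0) & (self.time < t1)
        if not sel.any():
            raise ValueError("window contains no samples")
        return sel


def hilbert_envelope(
    ve_trials: np.ndarray,
    fs: float,
    off_window: tuple = (24.0, 39.0),
    edge_trim: float = 0.5,
) -> EnvelopeResult:
    """|analytic signal| per trial, averaged, with baseline-relative change.

    The baseline is the mean of the trial-averaged envelope over
    ``off_window``; the first and last ``edge_trim`` seconds of each trial are
    excluded from envelope statistics (Hilbert edge effects).
    """
    ve_trials = np.atleast_2d(np.asarray(ve_trials, float))
    env = np.abs(sps.hilbert(ve_trials, axis=1)).mean(axis=0)
    n = env.shape[0]
    time = np.arange(n) / fs
    trim = int(round(edge_trim * fs))
    keep = slice(trim, n - trim if trim else n)
    time, env = time[keep], env[keep]
    sel = (time >= off_window[0]) & (time < off_window[1])
    if not sel.any():
        raise ValueError("off window contains no samples")
    baseline = env[sel].mean()
    rel = (env - baseline) / baseline
    return EnvelopeResult(time, env, float(baseline), rel, edge_trim)


def snr_visual(spectrum_on: Spectrum, spectrum_off: Spectrum, f0: float) -> float:
    """Peak on-amplitude at f0 over mean off-amplitude in [f0−2, f0+2] Hz."""
    denom = spectrum_off.band_mean(f0 - 2.0, f0 + 2.0)
    if denom == 0:
        raise ZeroDivisionError("off-window spectrum is zero in the reference band")
    return spectrum_on.at(f0) / denom


def snr_nback(
    envelope: EnvelopeResult, task: tuple = (0.0, 20.0), rest: tuple = (20.0, 40.0)
) -> float:
    """(mean task − mean rest) / sd rest, on the trial-averaged envelope."""
    sd = envelope.window_sd(*rest)
    if sd == 0:
        raise ZeroDivisionError("rest-window envelope has zero variance")
    return (envelope.window_mean(*task) - envelope.window_mean(*rest)) / sd


def instantaneous_snr(envelope: EnvelopeResult, rest: tuple = (20.0, 40.0)) -> np.ndarray:
    """Baseline-referenced envelope in rest-window standard-deviation units:
    (envelope(t) − mean_rest) / sd_rest.  Its task-minus-rest time-mean equals
    :func:`snr_nback` by construction."""
    sd = envelope.window_sd(*rest)
    if sd == 0:
        raise ZeroDivisionError("rest-window envelope has zero variance")
    return (envelope.envelope - envelope.window_mean(*rest)) / sd
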