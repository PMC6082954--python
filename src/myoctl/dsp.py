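"""Streaming preprocessing and feature extraction.

Two feature paths feed the two controllers:

* amplitude path — a causal second-order Butterworth high-pass at 50 Hz
  removes motion artifact, then an exponential moving average (EMA) of the
  full-wave-rectified signal over the latest 256 samples gives the scalar
  envelope feature ``Y_t``.  With smoothing coefficient ``a`` and
  ``b = 1 - a`` the recurrence per 10 ms cycle is::

      S_0 = Y_t;  S_{i+1} = a S_i + b |X_i|,  i = 0..255;  Y_{t+1} = S_256

  which collapses in closed form to
  ``Y_{t+1} = a^256 Y_t + b * sum_i a^(255-i) |X_i|``.

* spectral path — a 256-point FFT of each channel's latest window, power
  averaged over ±15.6 Hz (±2 bins at the 7.8125 Hz bin width) around eight
  centers that sit exactly on FFT bins 3, 6, 9, 12, 18, 24, 32 and 40
  (23.4–312.5 Hz).  Two channels give a 16-dimensional feature vector.

Both features are recomputed every 10 ms (a 20-sample hop at 2 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

__all__ = [
    "WINDOW",
    "HOP",
    "EMA_A",
    "BAND_BINS",
    "BAND_CENTERS_HZ",
    "FilterCoefficients",
    "design_highpass",
    "filter_stream",
    "ema_amplitude_update",
    "ema_amplitude_series",
    "spectral_feature",
    "spectral_feature_series",
    "feature_times",
    "features_to_csv",
]

WINDOW = 256  # samples per analysis window
HOP = 20  # samples per 10 ms cycle at 2 kHz
EMA_A = 0.9999  # smoothing coefficient a (b = 1 - a)

# FFT bin indices of the eight band centers at fs=2 kHz, N=256
# (bin width 7.8125 Hz); each band averages bins c-2 .. c+2 (±15.6 Hz).
BAND_BINS = (3, 6, 9, 12, 18, 24, 32, 40)
BAND_CENTERS_HZ = tuple(b * 2000.0 / 256 for b in BAND_BINS)
BAND_HALFWIDTH_BINS = 2


@dataclass(frozen=True)
class FilterCoefficients:
    """Second-order recursive (IIR) filter, transposed direct form II."""

    b: tuple[float, float, float]
    a: tuple[float, float, float]
    cutoff: float
    sample_rate: float

    def __post_init__(self) -> None:
        poles = np.roots(self.a)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError("filter is unstable (pole on or outside unit circle)")

    def response_at(self, freq_hz: float) -> complex:
        """Transfer function evaluated on the unit circle at ``freq_hz``."""
        w = 2 * np.pi * freq_hz / self.sample_rate
        z = np.exp(1j * w)
        num = sum(c * z ** (-k) for k, c in enumerate(self.b))
        den = sum(c * z ** (-k) for k, c in enumerate(self.a))
        return num / den


def design_highpass(cutoff: float = 50.0, sample_rate: float = 2000.0) -> FilterCoefficients:
    """Second-order Butterworth high-pass (−3 dB at ``cutoff``)."""
    if not (0 < cutoff < sample_rate / 2):
        raise ValueError("cutoff must lie strictly between 0 and Nyquist")
    b, a = signal.butter(2, cutoff, btype="highpass", fs=sample_rate)
    return FilterCoefficients(b=tuple(b), a=tuple(a), cutoff=cutoff, sample_rate=sample_rate)


def filter_stream(coeffs: FilterCoefficients, samples, zi=None):
    """Causal filtering with carried state for chunked streams.

    Returns ``(filtered, zf)``; feeding ``zf`` back as ``zi`` for the next
    chunk makes chunked filtering identical to one-shot filtering.
    """
    if zi is None:
        zi = np.zeros(2)
    zi = np.asarray(zi, dtype=float)
    if zi.shape != (2,):
        raise ValueError("carry state must have length 2 for a 2nd-order filter")
    y, zf = signal.lfilter(coeffs.b, coeffs.a, np.asarray(samples, dtype=float), zi=zi)
    return y, zf


def _ema_weights(a: float, n: int = WINDOW) -> np.ndarray:
    b = 1.0 - a
    return b * a ** np.arange(n - 1, -1, -1, dtype=float)


def ema_amplitude_update(y_prev: float, window, a: float = EMA_A) -> float:
    """One 10 ms EMA step over a 256-sample post-high-pass window.

    Vectorized closed form of the 256-step rectified-EMA recurrence; the
    literal loop is kept in the test suite as the oracle.
    """
    x = np.asarray(window, dtype=float)
    if x.shape != (WINDOW,):
        raise ValueError(f"window must hold exactly {WINDOW} samples")
    if not (0.0 < a < 1.0):
        raise ValueError("smoothing coefficient a must lie in (0, 1)")
    return float(a**WINDOW * y_prev + _ema_weights(a) @ np.abs(x))


def ema_amplitude_series(
    samples,
    a: float = EMA_A,
    window: int = WINDOW,
    hop: int = HOP,
    y0: float = 0.0,
) -> np.ndarray:
    """EMA envelope over a whole stream, one value per hop.

    ``n`` samples yield ``floor((n - window)/hop) + 1`` features (empty if
    ``n < window``).  Each feature chains from the previous via the
    recurrence, seeded with ``y0``.
    """
    x = np.abs(np.asarray(samples, dtype=float))
    n = x.shape[0]
    if n < window:
        return np.empty(0)
    views = sliding_window_view(x, window)[::hop]  # (n_feat, window)
    contrib = views @ _ema_weights(a, window)
    decay = a**window
    # y_k = decay * y_{k-1} + contrib_k; scan over the per-window sums
    y = np.empty(len(contrib))
    acc = y0
    for k, c in enumerate(contrib):
        acc = decay * acc + c
        y[k] = acc
    return y


def feature_times(n_samples: int, sample_rate: float = 2000.0, window: int = WINDOW, hop: int = HOP) -> np.ndarray:
    """Time stamps (window-end, seconds) of the feature series for a stream."""
    n_feat = max(0, (n_samples - window) // hop + 1)
    ends = window + hop * np.arange(n_feat)
    return ends / sample_rate


def spectral_feature(window_ch1, window_ch2) -> np.ndarray:
    """16-dimensional band-power feature from two 256-sample windows.

    For each channel the periodogram ``|DFT|^2 / 256`` (rectangular window)
    is averaged over the 5 bins of each of the eight bands; the result is
    channel-major: entries 0–7 are channel 1's bands in ascending center
    frequency, entries 8–15 channel 2's.
    """
    out = np.empty(16)
    for ch, win in enumerate((window_ch1, window_ch2)):
        x = np.asarray(win, dtype=float)
        if x.shape != (WINDOW,):
            raise ValueError(f"each window must hold exactly {WINDOW} samples")
        p = np.abs(np.fft.rfft(x)) ** 2 / WINDOW
        for k, c in enumerate(BAND_BINS):
            out[8 * ch + k] = p[c - BAND_HALFWIDTH_BINS : c + BAND_HALFWIDTH_BINS + 1].mean()
    return out


def spectral_feature_series(samples_2ch, window: int = WINDOW, hop: int = HOP) -> np.ndarray:
    """Band-power features over a whole two-channel stream; shape (n_feat, 16).

    Vectorized equivalent of calling :func:`spectral_feature` on every
    hop-aligned window pair.
    """
    x = np.asarray(samples_2ch, dtype=float)
    if x.ndim != 2 or x.shape[0] != 2:
        raise ValueError("expected a (2, n) two-channel array")
    n = x.shape[1]
    if n < window:
        return np.empty((0, 16))
    feats = []
    for ch in range(2):
        views = sliding_window_view(x[ch], window)[::hop]
        p = np.abs(np.fft.rfft(views, axis=1)) ** 2 / window
        bands = np.stack(
            [
                p[:, c - BAND_HALFWIDTH_BINS : c + BAND_HALFWIDTH_BINS + 1].mean(axis=1)
                for c in BAND_BINS
            ],
            axis=1,
        )
        feats.append(bands)
    return np.concatenate(feats, axis=1)


def features_to_csv(times, values, path: str) -> None:
    """Write a feature series (scalar EMA or 16-column band power) as CSV."""
    values = np.asarray(values)
    if values.ndim == 1:
        df = pd.DataFrame({"time_s": times, "Y": values})
    else:
        cols = {"time_s": times}
        for ch in range(2):
            for k, hz in enumerate(BAND_CENTERS_HZ):
                cols[f"ch{ch + 1}_{hz:.1f}Hz"] = values[:, 8 * ch + k]
        df = pd.DataFrame(cols)
    df.to_csv(path, index=False)
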