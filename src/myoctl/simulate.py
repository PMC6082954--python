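"""Synthetic surface-EMG generation.

Produces motion-labeled two-channel voltage streams with the acquisition
characteristics of a small embedded prosthesis controller: 2 kHz sampling,
12-bit quantization over 0–5 V with the analog front end biasing the signal
at +2.5 V.  Each hand motion (rest, open, grasp) is modeled as band-limited
Gaussian noise with a motion- and channel-specific spectral shape and RMS
amplitude, optionally contaminated by 50 Hz mains interference.  The model
is deliberately phenomenological: it gives downstream feature extractors
and classifiers signals whose amplitude and band-power statistics are
controllable, which is what the controllers actually consume.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionConfig",
    "MotionLabel",
    "ChannelSpectrum",
    "MotionModel",
    "TrialSchedule",
    "SampleStream",
    "make_trial_schedule",
    "simulate_emg",
    "simulate_motion_segment",
    "adc_digitize",
    "adc_undigitize",
    "default_threshold_model",
    "default_pattern_model",
    "stream_to_csv",
    "stream_from_csv",
    "write_counts",
    "read_counts",
]


class MotionLabel(enum.IntEnum):
    """Integer motion identifiers: 0 stop/rest, 1 open, 2 grasp."""

    REST = 0
    OPEN = 1
    GRASP = 2


@dataclass(frozen=True)
class AcquisitionConfig:
    """ADC and sampling parameters of the prosthesis controller.

    Defaults correspond to a 12-bit converter sampling at 2 kHz over a
    0–5 V input range with the sensor output biased at mid-scale (+2.5 V).
    """

    sample_rate: float = 2000.0
    adc_bits: int = 12
    v_min: float = 0.0
    v_max: float = 5.0
    offset: float = 2.5

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not (1 <= self.adc_bits <= 16):
            raise ValueError("adc_bits must lie in 1..16")
        if self.v_max <= self.v_min:
            raise ValueError("voltage range is empty")
        if not (self.v_min <= self.offset <= self.v_max):
            raise ValueError("offset must lie within the voltage range")

    @property
    def n_levels(self) -> int:
        return 2**self.adc_bits

    @property
    def lsb(self) -> float:
        return (self.v_max - self.v_min) / self.n_levels

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "sample_rate": self.sample_rate,
                    "adc_bits": self.adc_bits,
                    "v_min": self.v_min,
                    "v_max": self.v_max,
                    "offset": self.offset,
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path: str) -> "AcquisitionConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class ChannelSpectrum:
    """Spectral recipe for one motion on one channel.

    ``amplitude_rms`` is the nominal RMS of the zero-mean EMG component in
    volts.  ``spectral_shape`` lists ``(band_center_hz, relative_power)``
    pairs that define where the power sits; the coloring filter is a sum of
    Gaussian bumps at those centers.  ``mains_amplitude`` is the peak
    amplitude of an additive 50 Hz sinusoid.  ``effort_cv`` is the
    coefficient of variation of a slow (~0.5 s correlation) multiplicative
    gain that models the natural drift of effort during a held contraction;
    0 gives a stationary signal.
    """

    amplitude_rms: float
    spectral_shape: tuple[tuple[float, float], ...]
    mains_amplitude: float = 0.0
    bump_width_hz: float = 12.0
    effort_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_rms < 0:
            raise ValueError("amplitude_rms must be non-negative")
        if any(p < 0 for _, p in self.spectral_shape):
            raise ValueError("relative powers must be non-negative")
        if self.mains_amplitude < 0:
            raise ValueError("mains_amplitude must be non-negative")
        if self.effort_cv < 0:
            raise ValueError("effort_cv must be non-negative")


@dataclass(frozen=True)
class MotionModel:
    """Per-motion, per-channel signal recipes.

    ``channels[label]`` is a tuple of :class:`ChannelSpectrum`, one entry
    per sensor channel.  All motions must declare the same channel count.
    """

    channels: Mapping[MotionLabel, tuple[ChannelSpectrum, ...]]

    def __post_init__(self) -> None:
        counts = {len(v) for v in self.channels.values()}
        if len(counts) != 1:
            raise ValueError("all motions must define the same channel count")

    @property
    def n_channels(self) -> int:
        return len(next(iter(self.channels.values())))

    def motions(self) -> set[MotionLabel]:
        return set(self.channels)


@dataclass(frozen=True)
class TrialSchedule:
    """Randomized sequence of held-motion trials."""

    trials: tuple[tuple[MotionLabel, float], ...]
    repetitions: int
    seed: int

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.trials))

    def boundaries(self, sample_rate: float) -> np.ndarray:
        """Cumulative trial-start sample indices (including the final end)."""
        durs = np.array([d for _, d in self.trials])
        edges = np.concatenate([[0.0], np.cumsum(durs)])
        return np.round(edges * sample_rate).astype(int)


@dataclass
class SampleStream:
    """A labeled multi-channel voltage stream.

    ``samples`` has shape ``(n_channels, n)``; ``labels`` holds the
    per-sample ground-truth motion.
    """

    samples: np.ndarray
    labels: np.ndarray
    config: AcquisitionConfig

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.samples.shape[1] != self.labels.shape[0]:
            raise ValueError("labels length must equal sample length")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.config.sample_rate


def make_trial_schedule(
    motions: Sequence[MotionLabel] | set[MotionLabel],
    reps: int,
    duration_s: float,
    seed: int,
) -> TrialSchedule:
    """Build a seed-reproducible random ordering of held-motion trials.

    Each motion appears exactly ``reps`` times, every trial lasting
    ``duration_s`` seconds.
    """
    motions = sorted(set(motions))
    if not motions:
        raise ValueError("motion set must not be empty")
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    trials = [MotionLabel(m) for m in motions for _ in range(reps)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trials))
    return TrialSchedule(
        trials=tuple((trials[i], float(duration_s)) for i in order),
        repetitions=reps,
        seed=seed,
    )


def adc_digitize(voltage, config: AcquisitionConfig = AcquisitionConfig()):
    """Quantize voltages to ADC counts.  Out-of-range inputs are clamped.

    ``count = round(clamp(v, v_min, v_max) / range * 2**bits)`` clamped to
    ``[0, 2**bits - 1]``; mid-scale 2.5 V maps to count 2048 at defaults.
    """
    v = np.clip(np.asarray(voltage, dtype=float), config.v_min, config.v_max)
    frac = (v - config.v_min) / (config.v_max - config.v_min)
    counts = np.clip(np.round(frac * config.n_levels), 0, config.n_levels - 1)
    return counts.astype(np.int64)


def adc_undigitize(counts, config: AcquisitionConfig = AcquisitionConfig()):
    """Convert ADC counts back to volts (within one LSB of the original)."""
    return config.v_min + np.asarray(counts, dtype=float) * config.lsb


def _colored_noise(
    n: int,
    spec: ChannelSpectrum,
    sample_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise shaped in the frequency domain to the band recipe."""
    if spec.amplitude_rms == 0 or not spec.spectral_shape:
        return np.zeros(n)
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    psd = np.zeros_like(freqs)
    for center, power in spec.spectral_shape:
        psd += power * np.exp(-0.5 * ((freqs - center) / spec.bump_width_hz) ** 2)
    psd[0] = 0.0  # EMG is zero-mean; DC handled by the offset
    if psd.max() <= 0:
        return np.zeros(n)
    shaped = np.fft.irfft(np.fft.rfft(white) * np.sqrt(psd), n=n)
    rms = np.sqrt(np.mean(shaped**2))
    if rms == 0:
        return np.zeros(n)
    shaped *= spec.amplitude_rms / rms
    if spec.effort_cv > 0:
        shaped *= _effort_gain(n, spec.effort_cv, sample_rate, rng)
    return shaped


def _effort_gain(
    n: int, cv: float, sample_rate: float, rng: np.random.Generator, corr_s: float = 0.5
) -> np.ndarray:
    """Slow positive gain process with unit mean and coefficient of variation cv."""
    tau = max(1, int(round(corr_s * sample_rate)))
    coarse = rng.standard_normal(n // tau + 2)
    fine = np.interp(np.arange(n) / tau, np.arange(coarse.size), coarse)
    return np.clip(1.0 + cv * fine, 0.05, None)


def simulate_motion_segment(
    label: MotionLabel,
    n: int,
    model: MotionModel,
    config: AcquisitionConfig,
    rng: np.random.Generator,
    start_index: int = 0,
) -> np.ndarray:
    """Simulate ``n`` samples of one held motion; shape ``(n_channels, n)``.

    ``start_index`` keeps the mains-interference phase continuous across
    consecutive segments of a longer stream.
    """
    if label not in model.channels:
        raise KeyError(f"motion {label!r} missing from model")
    t = (start_index + np.arange(n)) / config.sample_rate
    out = np.empty((model.n_channels, n))
    for ch, spec in enumerate(model.channels[label]):
        sig = _colored_noise(n, spec, config.sample_rate, rng)
        if spec.mains_amplitude > 0:
            sig = sig + spec.mains_amplitude * np.sin(2 * np.pi * 50.0 * t)
        out[ch] = sig + config.offset
    return out


def simulate_emg(
    schedule: TrialSchedule,
    model: MotionModel,
    config: AcquisitionConfig = AcquisitionConfig(),
    seed: int = 0,
) -> SampleStream:
    """Render a trial schedule into a continuous labeled voltage stream.

    Voltages pass through the ADC model (quantize then back-convert), so the
    returned stream carries the quantization the real controller would see.
    Deterministic for a given ``seed``.
    """
    missing = {m for m, _ in schedule.trials} - model.motions()
    if missing:
        raise KeyError(f"motions missing from model: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    edges = schedule.boundaries(config.sample_rate)
    n_total = edges[-1]
    samples = np.empty((model.n_channels, n_total))
    labels = np.empty(n_total, dtype=np.int8)
    for (motion, _), lo, hi in zip(schedule.trials, edges[:-1], edges[1:]):
        seg = simulate_motion_segment(motion, hi - lo, model, config, rng, start_index=lo)
        samples[:, lo:hi] = seg
        labels[lo:hi] = int(motion)
    samples = adc_undigitize(adc_digitize(samples, config), config)
    return SampleStream(samples=samples, labels=labels, config=config)


# --- default motion models -------------------------------------------------
#
# The study population's EMG amplitudes and spectra were never published, so
# these defaults are stand-ins chosen to be physiologically plausible for
# surface EMG: activity concentrated between ~50 and ~350 Hz, active-motion
# RMS an order of magnitude above baseline.  In threshold mode one sensor is
# read: "open" is commanded by muscle weakness (low amplitude), "grasp" by
# tension (high amplitude), with rest sitting between the two thresholds.

_BROADBAND = ((70.3, 1.0), (93.8, 1.0), (140.6, 0.8), (187.5, 0.5), (250.0, 0.3))


def default_threshold_model(
    open_rms: float = 0.02,
    rest_rms: float = 0.06,
    grasp_rms: float = 0.15,
    mains_amplitude: float = 0.0,
    effort_cv: float = 0.25,
) -> MotionModel:
    """Single-channel amplitude-graded model for threshold control."""
    mk = lambda rms: (
        ChannelSpectrum(rms, _BROADBAND, mains_amplitude=mains_amplitude,
                        effort_cv=effort_cv),
    )
    return MotionModel(
        channels={
            MotionLabel.OPEN: mk(open_rms),
            MotionLabel.REST: mk(rest_rms),
            MotionLabel.GRASP: mk(grasp_rms),
        }
    )


def default_pattern_model(
    separation: float = 1.0,
    rest_rms: float = 0.03,
    active_rms: float = 0.30,
    mains_amplitude: float = 0.0,
    effort_cv: float = 0.25,
) -> MotionModel:
    """Two-channel model with class-specific band-power signatures.

    Grasp drives the flexor-side channel with low-to-mid-band power and open
    drives the extensor-side channel with high-band power, so the
    16-dimensional band-power feature separates the three classes.

    ``separation`` in [0, 1] interpolates each class's spectral shape (and
    the cross-channel amplitude contrast) toward a common average: 1 keeps
    the classes fully distinct, 0 makes grasp and open statistically
    identical.  Used to study how recognition degrades as classes merge.
    """
    if not (0.0 <= separation <= 1.0):
        raise ValueError("separation must lie in [0, 1]")
    s = separation
    grasp_shape = ((70.3, 1.0), (93.8, 1.0), (140.6, 0.8))
    open_shape = ((187.5, 1.0), (250.0, 1.0), (312.5, 0.8))
    common = tuple(grasp_shape) + tuple(open_shape)

    def blend(shape):
        own = tuple((c, s * p) for c, p in shape)
        shared = tuple((c, (1 - s) * p * 0.5) for c, p in common)
        return own + shared

    # dominant / quiet channel RMS for an active motion; at s=0 both equal
    hi = active_rms
    quiet = hi * (1 - s) + (rest_rms * 2) * s

    def ch(rms, shape):
        return ChannelSpectrum(rms, blend(shape), mains_amplitude=mains_amplitude,
                               effort_cv=effort_cv)

    rest_shape = ((70.3, 0.5), (93.8, 0.5), (140.6, 0.3))
    return MotionModel(
        channels={
            MotionLabel.REST: (
                ChannelSpectrum(rest_rms, rest_shape, mains_amplitude=mains_amplitude,
                                effort_cv=effort_cv),
                ChannelSpectrum(rest_rms, rest_shape, mains_amplitude=mains_amplitude,
                                effort_cv=effort_cv),
            ),
            MotionLabel.GRASP: (ch(hi, grasp_shape), ch(quiet, open_shape)),
            MotionLabel.OPEN: (ch(quiet, grasp_shape), ch(hi, open_shape)),
        }
    )


# --- stream I/O ------------------------------------------------------------


def stream_to_csv(stream: SampleStream, path: str) -> None:
    """Write a labeled stream as CSV: time_s, ch1_V [, ch2_V ...], label."""
    cols: dict[str, np.ndarray] = {"time_s": stream.times}
    for ch in range(stream.n_channels):
        cols[f"ch{ch + 1}_V"] = stream.samples[ch]
    cols["label"] = stream.labels
    pd.DataFrame(cols).to_csv(path, index=False)


def stream_from_csv(path: str, config: AcquisitionConfig | None = None) -> SampleStream:
    df = pd.read_csv(path)
    chans = [c for c in df.columns if c.startswith("ch") and c.endswith("_V")]
    if config is None:
        if len(df) > 1:
            dt = float(df["time_s"].iloc[1] - df["time_s"].iloc[0])
            config = AcquisitionConfig(sample_rate=round(1.0 / dt))
        else:
            config = AcquisitionConfig()
    return SampleStream(
        samples=df[chans].to_numpy().T,
        labels=df["label"].to_numpy(),
        config=config,
    )


def write_counts(stream: SampleStream, path: str) -> None:
    """Compact binary dump of interleaved uint16 ADC counts."""
    counts = adc_digitize(stream.samples, stream.config).astype("<u2")
    counts.T.reshape(-1).tofile(path)


def read_counts(path: str, n_channels: int, config: AcquisitionConfig) -> SampleStream:
    raw = np.fromfile(path, dtype="<u2").reshape(-1, n_channels).T
    volts = adc_undigitize(raw, config)
    return SampleStream(
        samples=volts,
        labels=np.zeros(volts.shape[1], dtype=np.int8),
        config=config,
    )
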