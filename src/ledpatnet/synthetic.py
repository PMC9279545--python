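"""Synthetic multi-channel EEG with class-dependent band-power structure.

The generator emulates the shape of game-elicited EEG corpora: 14-channel
recordings sampled at 128 Hz, one long recording per subject x emotion
class, segmented into non-overlapping 7650-sample frames. Each recording
is a sum of band-limited oscillations — a few sinusoids per classical EEG
band (delta/theta/alpha/beta/gamma) with random in-band frequencies and
phases — whose per-band power follows a class-specific profile, plus AR(1)
noise. Classes therefore differ in their spectral signature, which is the
kind of structure the multilevel feature pipeline is designed to pick up.

Everything is a pure function of the spec's seed. The generator makes no
attempt at physiological realism (no dipole/forward modelling, no
artifacts, no inter-channel correlation beyond shared class structure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.signal import lfilter

from .fusion import DEFAULT_FRAME_LENGTH, EEGFrame, segment_frames

__all__ = ["SyntheticSpec", "generate_signals", "generate_dataset", "CHANNELS", "BANDS"]

logger = logging.getLogger(__name__)

#: EMOTIV EPOC 14-channel montage.
CHANNELS = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Classical EEG frequency bands, Hz.
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

_OSC_PER_BAND = 3

#: Relative band power (delta, theta, alpha, beta, gamma) per emotion class.
DEFAULT_BAND_PROFILES = {
    "boring": (1.2, 0.9, 0.50, 0.30, 0.15),
    "calm": (0.6, 1.1, 1.30, 0.35, 0.15),
    "horror": (0.5, 0.4, 0.45, 1.10, 0.70),
    "funny": (0.9, 0.5, 1.00, 0.75, 0.35),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic corpus."""

    n_subjects: int = 28
    n_channels: int = 14
    rate: float = 128.0
    signal_length: int = 38_252
    band_profiles: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_PROFILES)
    )
    noise_sd: float = 1.0
    ar_coefficient: float = 0.9
    seed: int = 0
    frame_length: int = DEFAULT_FRAME_LENGTH

    def __post_init__(self) -> None:
        if not 1 <= self.n_channels <= len(CHANNELS):
            raise ValueError(f"n_channels must be in [1, {len(CHANNELS)}]")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in (-1, 1)")
        profiles = {k: tuple(float(p) for p in v) for k, v in self.band_profiles.items()}
        if len(profiles) < 2:
            raise ValueError("need at least two classes")
        for name, prof in profiles.items():
            if len(prof) != len(BANDS) or any(p < 0 for p in prof):
                raise ValueError(
                    f"profile for class {name!r} must hold {len(BANDS)} "
                    "nonnegative band powers"
                )
        if len({v for v in profiles.values()}) < len(profiles):
            logger.warning(
                "some classes share identical band profiles; generated data "
                "will carry no signal between them"
            )
        object.__setattr__(self, "band_profiles", profiles)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.band_profiles)

    @property
    def channels(self) -> tuple[str, ...]:
        return CHANNELS[: self.n_channels]


def _one_signal(
    rng: np.random.Generator, spec: SyntheticSpec, profile: tuple[float, ...]
) -> NDArray[np.float64]:
    t = np.arange(spec.signal_length) / spec.rate
    x = np.zeros(spec.signal_length)
    for (lo, hi), power in zip(BANDS.values(), profile):
        amp = np.sqrt(2.0 * power / _OSC_PER_BAND)
        freqs = rng.uniform(lo, hi, size=_OSC_PER_BAND)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=_OSC_PER_BAND)
        x += amp * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)
    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.ar_coefficient**2)
        e = rng.normal(0.0, innov_sd, size=spec.signal_length)
        x += lfilter([1.0], [1.0, -spec.ar_coefficient], e)
    return x


def generate_signals(
    spec: SyntheticSpec,
    channels: tuple[str, ...] | None = None,
) -> dict[int, dict[str, dict[str, NDArray[np.float64]]]]:
    """Raw recordings: ``signals[subject][class][channel] -> 1-D array``.

    To keep generation a pure function of the seed regardless of which
    channels are requested, every channel's random draws are consumed in
    montage order and unwanted channels are simply discarded.
    """
    wanted = set(channels if channels is not None else spec.channels)
    unknown = wanted - set(spec.channels)
    if unknown:
        raise ValueError(f"unknown channels requested: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    out: dict[int, dict[str, dict[str, NDArray[np.float64]]]] = {}
    for subject in range(spec.n_subjects):
        out[subject] = {}
        for cls, profile in spec.band_profiles.items():
            per_channel = {}
            for channel in spec.channels:
                sig = _one_signal(rng, spec, profile)
                if channel in wanted:
                    per_channel[channel] = sig
            out[subject][cls] = per_channel
    return out


def generate_dataset(
    spec: SyntheticSpec,
    channels: tuple[str, ...] | None = None,
) -> dict[str, list[EEGFrame]]:
    """Framed synthetic corpus: ``dataset[channel] -> list of EEGFrame``.

    Each subject x class recording is segmented into non-overlapping
    frames of ``spec.frame_length`` samples (5 frames at the defaults).
    """
    signals = generate_signals(spec, channels)
    dataset: dict[str, list[EEGFrame]] = {
        ch: [] for ch in (channels if channels is not None else spec.channels)
    }
    for subject in sorted(signals):
        for cls, per_channel in signals[subject].items():
            for channel, sig in per_channel.items():
                dataset[channel].extend(
                    segment_frames(
                        sig, spec.frame_length, channel=channel, rate=spec.rate, label=cls
                    )
                )
    return dataset
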