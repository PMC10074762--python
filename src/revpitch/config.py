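"""Stimulus-generation configuration.

A :class:`NoiseConfig` collects every parameter of the randomized
pitch-contour stimuli: how many breakpoints carry Gaussian pitch noise,
the noise SD in cents, the winsorizing bound, the carrier F0 and
duration, and how breakpoint values are turned into a dense contour
(linear interpolation for the short speech/complex-tone sounds, a
"square" breakpoint function with short ramps for the melody notes).

Three presets mirror the experimental conditions:

* ``speech``       — 8 breakpoints, 210 Hz, 250 ms, linear, 800 stimuli / 400 trials
* ``complex_tone`` — identical to speech except for the carrier timbre
* ``melody``       — 3 note onsets, 260 Hz, 1380 ms, square BPF (0.1 s
  transitions), 600 stimuli / 300 trials
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONDITIONS = ("speech", "complex_tone", "melody")
INTERPOLATION_MODES = ("linear", "square_bpf")
CLIP_MODES = ("winsorize", "redraw")


class ConfigurationError(ValueError):
    """Raised when a NoiseConfig violates its invariants."""


@dataclass(frozen=True)
class NoiseConfig:
    """Parameters of the Gaussian pitch-noise stimulus generator.

    Attributes
    ----------
    condition:
        One of ``speech``, ``complex_tone``, ``melody``.
    n_breakpoints:
        Number of time points receiving an independent pitch shift.
    noise_sd:
        SD of the Gaussian pitch noise, in cents.
    clip_multiple:
        Shifts beyond ``clip_multiple * noise_sd`` are winsorized to the
        bound (or redrawn when ``clip_mode == "redraw"``).
    base_f0:
        Carrier fundamental, Hz.
    duration_ms:
        Stimulus duration, milliseconds.
    interpolation:
        ``linear`` (piecewise-linear through the breakpoints) or
        ``square_bpf`` (note plateaus with linear onset ramps).
    transition_time:
        Ramp duration in seconds for ``square_bpf`` mode.
    pool_size:
        Number of distinct stimuli synthesized for a session;
        always ``2 * n_trials`` (each stimulus is used in one pair).
    n_trials:
        Number of 2AFC trials per session.
    clip_mode:
        How out-of-bound draws are handled; recorded so a redraw variant
        stays available.
    """

    condition: str
    n_breakpoints: int
    noise_sd: float = 70.0
    clip_multiple: float = 2.2
    base_f0: float = 210.0
    duration_ms: float = 250.0
    interpolation: str = "linear"
    transition_time: float = 0.1
    pool_size: int = 800
    n_trials: int = 400
    clip_mode: str = "winsorize"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigurationError(f"unknown condition {self.condition!r}")
        if self.n_breakpoints < 2:
            raise ConfigurationError("n_breakpoints must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.clip_multiple <= 0:
            raise ConfigurationError("clip_multiple must be > 0")
        if self.base_f0 <= 0:
            raise ConfigurationError("base_f0 must be > 0")
        if self.interpolation not in INTERPOLATION_MODES:
            raise ConfigurationError(f"unknown interpolation {self.interpolation!r}")
        if self.clip_mode not in CLIP_MODES:
            raise ConfigurationError(f"unknown clip_mode {self.clip_mode!r}")
        if self.pool_size != 2 * self.n_trials:
            raise ConfigurationError("pool_size must equal 2 * n_trials")
        if self.interpolation == "square_bpf":
            if self.transition_time <= 0:
                raise ConfigurationError("square_bpf requires transition_time > 0")
            # ramps are centred on note onsets: each must fit inside the
            # shortest note segment
            segment = self.duration_ms / 1000.0 / self.n_breakpoints
            if self.transition_time >= segment:
                raise ConfigurationError(
                    "transition_time must be shorter than the shortest note segment"
                )

    @property
    def clip_bound(self) -> float:
        """Winsorizing bound in cents (``clip_multiple * noise_sd``)."""
        return self.clip_multiple * self.noise_sd

    @property
    def duration_s(self) -> float:
        return self.duration_ms / 1000.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_file(cls, path: str | Path) -> "NoiseConfig":
        """Load from YAML or JSON (by extension; YAML parses JSON too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def speech_config(**overrides) -> NoiseConfig:
    """Speech condition: 8 breakpoints on a 250 ms, 210 Hz carrier."""
    base = dict(
        condition="speech",
        n_breakpoints=8,
        base_f0=210.0,
        duration_ms=250.0,
        interpolation="linear",
        pool_size=800,
        n_trials=400,
    )
    base.update(overrides)
    return NoiseConfig(**base)


def complex_tone_config(**overrides) -> NoiseConfig:
    """Complex-tone condition: acoustically matched to speech (210 Hz, 250 ms)."""
    base = dict(
        condition="complex_tone",
        n_breakpoints=8,
        base_f0=210.0,
        duration_ms=250.0,
        interpolation="linear",
        pool_size=800,
        n_trials=400,
    )
    base.update(overrides)
    return NoiseConfig(**base)


def melody_config(**overrides) -> NoiseConfig:
    """Melody condition: 3 note onsets, square BPF, 260 Hz, 1380 ms."""
    base = dict(
        condition="melody",
        n_breakpoints=3,
        base_f0=260.0,
        duration_ms=1380.0,
        interpolation="square_bpf",
        transition_time=0.1,
        pool_size=600,
        n_trials=300,
    )
    base.update(overrides)
    return NoiseConfig(**base)


PRESETS = {
    "speech": speech_config,
    "complex_tone": complex_tone_config,
    "melody": melody_config,
}


def preset(condition: str, **overrides) -> NoiseConfig:
    try:
        return PRESETS[condition](**overrides)
    except KeyError:
        raise ConfigurationError(f"unknown condition {condition!r}") from None
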