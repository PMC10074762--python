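"""Additive rendering of contour stimuli and F0 estimation.

The carrier is a harmonic complex of the fundamental plus its seven odd
harmonics (partial numbers 1, 3, 5, ..., 15), equal amplitudes, sine
phase — a clarinet-like timbre.  The pitch contour c(t), in cents,
modulates the instantaneous fundamental f(t) = base_f0 * 2^(c(t)/1200);
phase is accumulated by integrating f(t) so the contour glides without
discontinuities.  Rendering is validation/demo machinery: the analysis
pipeline itself operates on breakpoint shift vectors, never on audio.

``estimate_f0`` is the rendering oracle — frame-wise autocorrelation
with parabolic peak interpolation, median-aggregated over frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

from .config import NoiseConfig
from .contour_noise import ContourStimulus, interpolate_contour

__all__ = [
    "Waveform",
    "render_harmonic_tone",
    "render_melody",
    "estimate_f0",
    "ODD_PARTIALS",
]

ODD_PARTIALS = (1, 3, 5, 7, 9, 11, 13, 15)
DEFAULT_SAMPLE_RATE = 44_100
DEFAULT_PEAK_DBFS = -3.0
RAMP_MS = 5.0


@dataclass
class Waveform:
    """A mono audio buffer with its sample rate."""

    samples: np.ndarray
    sample_rate: int

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.sample_rate

    def write(self, path) -> None:
        """Write PCM 16-bit WAV."""
        pcm = np.clip(self.samples, -1.0, 1.0)
        wavfile.write(path, self.sample_rate, (pcm * 32767).astype(np.int16))

    @classmethod
    def read(cls, path) -> "Waveform":
        sr, data = wavfile.read(path)
        if data.dtype == np.int16:
            data = data.astype(float) / 32767.0
        return cls(samples=np.asarray(data, dtype=float), sample_rate=int(sr))


def _apply_ramps(x: np.ndarray, sample_rate: int, ramp_ms: float = RAMP_MS) -> np.ndarray:
    n = int(round(ramp_ms / 1000.0 * sample_rate))
    if n == 0 or 2 * n >= len(x):
        return x
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n) / n))  # raised cosine
    x[:n] *= ramp
    x[-n:] *= ramp[::-1]
    return x


def render_harmonic_tone(stimulus: ContourStimulus, config: NoiseConfig,
                         sample_rate: int = DEFAULT_SAMPLE_RATE,
                         partials: tuple[int, ...] = ODD_PARTIALS,
                         peak_dbfs: float = DEFAULT_PEAK_DBFS) -> Waveform:
    """Render a contour stimulus as a harmonic complex tone.

    Parameters
    ----------
    partials:
        Harmonic numbers to sum (default the fundamental and its seven
        odd harmonics).  ``(1,)`` gives a pure tone, useful for tests.
    peak_dbfs:
        Peak level after normalization; the experiment's playback SPL is
        not representable in a file, so level is a file-domain choice.
    """
    if config.base_f0 <= 0:
        raise ValueError("base_f0 must be > 0")
    n = int(round(config.duration_s * sample_rate))
    cents = interpolate_contour(stimulus, config, n)
    f0 = config.base_f0 * np.exp2(cents / 1200.0)
    # accumulated phase of the fundamental (zero at onset => sine phase);
    # partial m has phase m * phi
    phi = 2 * np.pi * (np.cumsum(f0) - f0[0]) / sample_rate
    x = np.zeros(n)
    for m in partials:
        x += np.sin(m * phi)
    x = _apply_ramps(x, sample_rate)
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 10 ** (peak_dbfs / 20.0) / peak
    return Waveform(samples=x, sample_rate=sample_rate)


def render_melody(stimulus: ContourStimulus, config: NoiseConfig,
                  sample_rate: int = DEFAULT_SAMPLE_RATE,
                  peak_dbfs: float = DEFAULT_PEAK_DBFS) -> Waveform:
    """Render a 3-note melody stimulus (square-BPF contour, 260 Hz base)."""
    if config.n_breakpoints != 3 or config.interpolation != "square_bpf":
        raise ValueError("melody rendering requires a 3-breakpoint square_bpf config")
    return render_harmonic_tone(stimulus, config, sample_rate=sample_rate,
                                peak_dbfs=peak_dbfs)


def _frame_f0_autocorr(frame: np.ndarray, sample_rate: int,
                       fmin: float, fmax: float) -> float | None:
    """F0 of one frame by autocorrelation peak with parabolic interpolation."""
    frame = frame - frame.mean()
    if not np.any(frame):
        return None
    ac = np.correlate(frame, frame, mode="full")[len(frame) - 1:]
    lag_min = max(int(sample_rate / fmax), 2)
    lag_max = min(int(sample_rate / fmin), len(ac) - 2)
    if lag_max <= lag_min:
        return None
    seg = ac[lag_min:lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    if ac[k] <= 0:
        return None
    # parabolic refinement around the peak lag
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    lag = k + float(np.clip(delta, -1, 1))
    return sample_rate / lag


def estimate_f0(waveform: Waveform, frame: tuple[float, float] | None = None,
                fmin: float = 50.0, fmax: float = 1000.0,
                frame_ms: float = 60.0, hop_ms: float = 10.0) -> float:
    """Estimate the fundamental frequency in Hz.

    With ``frame=(start_s, end_s)`` only that window is analysed;
    otherwise the whole waveform is cut into overlapping frames and the
    median frame estimate is returned.  Raises ``ValueError`` on silent
    input (no periodicity found).
    """
    x = waveform.samples
    sr = waveform.sample_rate
    if frame is not None:
        i0, i1 = (max(int(t * sr), 0) for t in frame)
        x = x[i0:i1]
    if len(x) == 0 or not np.any(x):
        raise ValueError("cannot estimate F0 of silent input")
    flen = int(frame_ms / 1000.0 * sr)
    hop = max(int(hop_ms / 1000.0 * sr), 1)
    if len(x) <= flen:
        est = _frame_f0_autocorr(x, sr, fmin, fmax)
        if est is None:
            raise ValueError("cannot estimate F0: no periodicity in window")
        return est
    estimates = []
    for start in range(0, len(x) - flen + 1, hop):
        est = _frame_f0_autocorr(x[start:start + flen], sr, fmin, fmax)
        if est is not None:
            estimates.append(est)
    if not estimates:
        raise ValueError("cannot estimate F0: no voiced frames")
    return float(np.median(estimates))
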