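"""Randomized pitch-contour stimuli and 2AFC trial construction.

Each stimulus is a vector of pitch shifts in cents, one per breakpoint,
drawn i.i.d. from Normal(0, noise_sd^2) and winsorized at
``±clip_multiple * noise_sd``.  A session's stimulus pool is paired
without replacement into two-alternative forced-choice (2AFC) trials, so
every stimulus appears in exactly one pair.  Dense contours for audio
rendering are obtained by linear interpolation between breakpoints
(speech / complex tone) or by a square breakpoint function with short
linear onset ramps (melody notes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ConfigurationError, NoiseConfig

__all__ = [
    "ContourStimulus",
    "TrialRecord",
    "SessionLog",
    "sample_shifts",
    "sample_contour",
    "build_stimulus_pool",
    "pair_trials",
    "interpolate_contour",
    "winsorized_normal_sd",
    "save_pool",
    "load_pool",
]


@dataclass(frozen=True)
class ContourStimulus:
    """One randomized pitch contour: per-breakpoint shifts in cents."""

    stimulus_id: str
    shifts: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "shifts", np.asarray(self.shifts, dtype=float))


@dataclass
class TrialRecord:
    """A single 2AFC trial: a stimulus pair and (once made) the choice."""

    trial_index: int
    stim_a: ContourStimulus
    stim_b: ContourStimulus
    choice: str | None = None  # "A" | "B" | None (not yet responded)

    @property
    def chosen(self) -> ContourStimulus:
        if self.choice not in ("A", "B"):
            raise ValueError("trial has no choice")
        return self.stim_a if self.choice == "A" else self.stim_b

    @property
    def unchosen(self) -> ContourStimulus:
        if self.choice not in ("A", "B"):
            raise ValueError("trial has no choice")
        return self.stim_b if self.choice == "A" else self.stim_a


@dataclass
class SessionLog:
    """All trials of one participant in one condition."""

    participant_id: str
    group: str
    condition: str
    trials: list[TrialRecord] = field(default_factory=list)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def choice_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(chosen, unchosen) shift matrices, one row per trial."""
        chosen = np.array([t.chosen.shifts for t in self.trials])
        unchosen = np.array([t.unchosen.shifts for t in self.trials])
        return chosen, unchosen


def winsorized_normal_sd(noise_sd: float, clip_multiple: float) -> float:
    """SD of a Normal(0, noise_sd^2) variable winsorized at ±clip_multiple SD.

    Closed form: with z the clip multiple,
    E[X^2]/sigma^2 = (2 Phi(z) - 1) - 2 z phi(z) + 2 z^2 (1 - Phi(z)).
    """
    z = clip_multiple
    ratio2 = (2 * stats.norm.cdf(z) - 1) - 2 * z * stats.norm.pdf(z) + 2 * z * z * (
        1 - stats.norm.cdf(z)
    )
    return float(noise_sd * np.sqrt(ratio2))


def sample_shifts(config: NoiseConfig, rng: np.random.Generator, n: int = 1) -> np.ndarray:
    """Draw ``n`` shift vectors, shape (n, n_breakpoints), winsorized in cents."""
    if config.noise_sd < 0:  # defensive; NoiseConfig already rejects this
        raise ConfigurationError("noise_sd must be >= 0")
    bound = config.clip_bound
    draws = rng.normal(0.0, config.noise_sd, size=(n, config.n_breakpoints))
    if config.clip_mode == "winsorize":
        np.clip(draws, -bound, bound, out=draws)
    else:  # redraw until inside the bound
        bad = np.abs(draws) > bound
        while bad.any():
            draws[bad] = rng.normal(0.0, config.noise_sd, size=int(bad.sum()))
            bad = np.abs(draws) > bound
    return draws


def sample_contour(config: NoiseConfig, rng: np.random.Generator,
                   stimulus_id: str = "s0") -> ContourStimulus:
    """Sample one randomized contour stimulus."""
    shifts = sample_shifts(config, rng, 1)[0]
    return ContourStimulus(stimulus_id=stimulus_id, shifts=shifts, condition=config.condition)


def build_stimulus_pool(config: NoiseConfig, rng: np.random.Generator) -> list[ContourStimulus]:
    """Generate ``config.pool_size`` non-identical contour stimuli.

    Duplicate shift vectors (probability ~0 for continuous draws, but the
    guarantee is cheap) are regenerated so all contours are distinct.
    """
    if config.pool_size <= 0:
        raise ConfigurationError("pool_size must be > 0")
    shifts = sample_shifts(config, rng, config.pool_size)
    # regenerate exact duplicates until all rows are unique
    while True:
        _, idx = np.unique(shifts, axis=0, return_index=True)
        dup = np.setdiff1d(np.arange(len(shifts)), idx)
        if dup.size == 0:
            break
        shifts[dup] = sample_shifts(config, rng, dup.size)
    return [
        ContourStimulus(stimulus_id=f"{config.condition}_{i:04d}", shifts=s,
                        condition=config.condition)
        for i, s in enumerate(shifts)
    ]


def pair_trials(pool: list[ContourStimulus], rng: np.random.Generator,
                ) -> list[tuple[ContourStimulus, ContourStimulus]]:
    """Randomly pair a pool into 2AFC trials, each stimulus used once.

    The permutation (which stimuli meet, and which is presented as A)
    is drawn from ``rng``, so pairings differ across participants seeded
    differently.
    """
    n = len(pool)
    if n % 2 != 0:
        raise ValueError("pool size must be even to form pairs")
    order = rng.permutation(n)
    return [(pool[order[2 * i]], pool[order[2 * i + 1]]) for i in range(n // 2)]


def iid_pair_trials(config: NoiseConfig, rng: np.random.Generator,
                    n_trials: int) -> list[tuple[ContourStimulus, ContourStimulus]]:
    """Alternative on-the-fly mode: every trial gets two fresh i.i.d. draws."""
    pairs = []
    for i in range(n_trials):
        a = sample_contour(config, rng, f"{config.condition}_t{i}a")
        b = sample_contour(config, rng, f"{config.condition}_t{i}b")
        pairs.append((a, b))
    return pairs


def breakpoint_times(config: NoiseConfig) -> np.ndarray:
    """Normalized times of the breakpoints on [0, 1].

    Linear mode: evenly spaced anchors t_k = (k-1)/(K-1).
    Square-BPF mode: note onsets at the starts of K equal segments.
    """
    k = config.n_breakpoints
    if config.interpolation == "linear":
        return np.arange(k) / (k - 1)
    return np.arange(k) / k


def interpolate_contour(stimulus: ContourStimulus, config: NoiseConfig,
                        n_samples: int) -> np.ndarray:
    """Dense cents trajectory of length ``n_samples`` over the stimulus.

    linear      — piecewise-linear through breakpoints at t_k=(k-1)/(K-1),
                  held flat before the first and after the last anchor.
    square_bpf  — piecewise-constant note plateaus with linear ramps of
                  ``transition_time`` seconds centred on each note onset
                  (onsets at the starts of K equal-duration segments; the
                  first note starts at the plateau value).
    """
    if n_samples < config.n_breakpoints:
        raise ValueError("n_samples must be >= n_breakpoints")
    t = np.arange(n_samples) / max(n_samples - 1, 1)  # normalized time
    shifts = stimulus.shifts
    if config.interpolation == "linear":
        anchors = breakpoint_times(config)
        return np.interp(t, anchors, shifts)
    # square BPF
    onsets = breakpoint_times(config)
    half = (config.transition_time / config.duration_s) / 2.0
    out = np.empty_like(t)
    # plateau assignment: value of the last onset at or before t
    idx = np.searchsorted(onsets, t, side="right") - 1
    idx = np.clip(idx, 0, len(onsets) - 1)
    out[:] = shifts[idx]
    # ramps centred on onsets 2..K (the first note has no predecessor)
    for k in range(1, len(onsets)):
        lo, hi = onsets[k] - half, onsets[k] + half
        in_ramp = (t >= lo) & (t <= hi)
        frac = (t[in_ramp] - lo) / (hi - lo)
        out[in_ramp] = shifts[k - 1] + frac * (shifts[k] - shifts[k - 1])
    return out


# ---------------------------------------------------------------------------
# serialization

def save_pool(pool: list[ContourStimulus], path) -> None:
    """Write a stimulus pool to CSV: stimulus_id, condition, bp_1..bp_K."""
    k = len(pool[0].shifts)
    rows = [
        {"stimulus_id": s.stimulus_id, "condition": s.condition,
         **{f"bp_{j + 1}": s.shifts[j] for j in range(k)}}
        for s in pool
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_pool(path) -> list[ContourStimulus]:
    df = pd.read_csv(path)
    bp_cols = [c for c in df.columns if c.startswith("bp_")]
    bp_cols.sort(key=lambda c: int(c.split("_")[1]))
    return [
        ContourStimulus(stimulus_id=str(r["stimulus_id"]),
                        shifts=np.array([r[c] for c in bp_cols], dtype=float),
                        condition=str(r["condition"]))
        for _, r in df.iterrows()
    ]
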