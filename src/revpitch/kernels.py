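"""First-order temporal kernels and subset reliability.

The kernel is the classification image of the 2AFC task: for each
breakpoint, the mean shift of the chosen stimuli minus the mean shift of
the unchosen stimuli, in cents.  Reliability follows the pilot logic of
correlating the kernel from the first ``n`` trials with the kernel from
the full session (nested prefixes), with r >= 0.8 the conventional bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contour_noise import SessionLog

__all__ = ["Kernel", "ReliabilityCurve", "estimate_kernel", "reliability_curve"]


@dataclass
class Kernel:
    """Estimated temporal kernel: cents per breakpoint."""

    values: np.ndarray
    n_trials: int
    condition: str
    participant_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ReliabilityCurve:
    subset_sizes: np.ndarray
    r_values: np.ndarray


def _kernel_values(session: SessionLog, n: int | None = None) -> np.ndarray:
    trials = session.trials if n is None else session.trials[:n]
    if not trials:
        raise ValueError("session has no trials")
    chosen = np.array([t.chosen.shifts for t in trials])
    unchosen = np.array([t.unchosen.shifts for t in trials])
    return chosen.mean(axis=0) - unchosen.mean(axis=0)


def estimate_kernel(session: SessionLog) -> Kernel:
    """mean(chosen contours) - mean(unchosen contours), per breakpoint."""
    values = _kernel_values(session)
    return Kernel(values=values, n_trials=len(session.trials),
                  condition=session.condition,
                  participant_id=session.participant_id)


def reliability_curve(session: SessionLog, subset_sizes,
                      mode: str = "nested",
                      rng: np.random.Generator | None = None) -> ReliabilityCurve:
    """Pearson r between subset kernels and the full-session kernel.

    ``nested`` uses the first-n-trials prefix (the pilot's definition);
    ``random`` draws each subset without replacement from ``rng``.
    """
    subset_sizes = np.asarray(subset_sizes, dtype=int)
    n_total = len(session.trials)
    if np.any(subset_sizes < 2):
        raise ValueError("subset sizes must be >= 2")
    if np.any(subset_sizes > n_total):
        raise ValueError("subset sizes cannot exceed the trial count")
    full = _kernel_values(session)
    rs = []
    for n in subset_sizes:
        if mode == "nested":
            sub = _kernel_values(session, int(n))
        elif mode == "random":
            if rng is None:
                raise ValueError("random mode requires an rng")
            idx = rng.choice(n_total, size=int(n), replace=False)
            chosen = np.array([session.trials[i].chosen.shifts for i in idx])
            unchosen = np.array([session.trials[i].unchosen.shifts for i in idx])
            sub = chosen.mean(axis=0) - unchosen.mean(axis=0)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if n == n_total:
            rs.append(1.0)  # identical vectors by construction
        else:
            rs.append(float(stats.pearsonr(sub, full).statistic))
    return ReliabilityCurve(subset_sizes=subset_sizes, r_values=np.array(rs))
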