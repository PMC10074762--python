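"""Per-participant scalar metrics.

* RMS of the kernel — a scalar pitch-sensitivity index (higher = the
  participant weights pitch information more strongly).
* Agreement — the fraction of trials where the logged choice matches the
  "objectively correct" stimulus, i.e. the pair member whose shifts
  correlate more highly (Pearson) with the participant's own kernel.
  Higher agreement means lower internal noise.
* Exceptional-sensitivity flags — the subgroup rule: RMS strictly above
  mean + 2 SD of a reference group.
* Prototype correlation — Pearson r between a kernel and the
  notation-derived melody contour [0, -500, 0] cents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour_noise import SessionLog
from .kernels import Kernel
from .observer import PROTOTYPE_MELODY

__all__ = [
    "MetricRecord",
    "SubgroupResult",
    "kernel_rms",
    "agreement",
    "exceptional_sensitivity",
    "prototype_correlation",
]


@dataclass
class MetricRecord:
    participant_id: str
    condition: str
    rms: float
    agreement: float
    n_scored_trials: int


@dataclass
class SubgroupResult:
    """Outcome of the mean + 2 SD exceptional-sensitivity rule."""

    reference_mean: float
    reference_sd: float
    threshold: float
    flags: np.ndarray
    flagged_count: int
    flagged_percent: float


def _as_values(kernel) -> np.ndarray:
    return kernel.values if isinstance(kernel, Kernel) else np.asarray(kernel, dtype=float)


def kernel_rms(kernel) -> float:
    """Root-mean-square of the kernel values, in cents."""
    v = _as_values(kernel)
    if v.size == 0:
        raise ValueError("empty kernel")
    return float(np.sqrt(np.mean(v ** 2)))


def _pearson_with(kernel_values: np.ndarray, shifts: np.ndarray) -> float:
    """Pearson r; NaN when either vector has zero variance."""
    kv = kernel_values - kernel_values.mean()
    sv = shifts - shifts.mean()
    denom = np.sqrt((kv ** 2).sum() * (sv ** 2).sum())
    if denom == 0:
        return np.nan
    return float((kv * sv).sum() / denom)


def agreement(session: SessionLog, kernel=None,
              method: str = "in_sample") -> tuple[float, int]:
    """Agreement between logged choices and kernel-predicted choices.

    Per trial, each stimulus's shifts are correlated (Pearson) with the
    kernel; the one with the higher r is the objectively correct
    response.  Returns ``(agreement, n_scored_trials)``; trials with an
    undefined correlation (zero-variance contour or kernel) or a tie are
    excluded from the denominator.

    ``method="in_sample"`` scores against the supplied (or the session's
    own) kernel; ``"leave_one_out"`` rescores each trial against the
    kernel computed from all other trials, removing the optimistic bias
    the in-sample variant has for noisy observers.
    """
    trials = session.trials
    if not trials:
        raise ValueError("session has no trials")
    chosen = np.array([t.chosen.shifts for t in trials])
    unchosen = np.array([t.unchosen.shifts for t in trials])
    n = len(trials)

    if method == "in_sample":
        if kernel is None:
            kv = chosen.mean(axis=0) - unchosen.mean(axis=0)
        else:
            kv = _as_values(kernel)
        if np.allclose(kv, kv[0]):
            raise ValueError("agreement undefined: zero-variance kernel")
        kernels = np.broadcast_to(kv, chosen.shape)
    elif method == "leave_one_out":
        diff = chosen - unchosen
        total = diff.sum(axis=0)
        kernels = (total - diff) / (n - 1) if n > 1 else np.broadcast_to(
            total, chosen.shape)
    else:
        raise ValueError(f"unknown method {method!r}")

    hits = 0
    scored = 0
    for i in range(n):
        r_c = _pearson_with(kernels[i], chosen[i])
        r_u = _pearson_with(kernels[i], unchosen[i])
        if np.isnan(r_c) or np.isnan(r_u) or r_c == r_u:
            continue
        scored += 1
        if r_c > r_u:
            hits += 1
    if scored == 0:
        raise ValueError("agreement undefined: no scorable trials")
    return hits / scored, scored


def exceptional_sensitivity(rms_target_group, rms_reference_group) -> SubgroupResult:
    """Flag target-group RMS values strictly above mean + 2 SD of the reference.

    Sample SD (n-1 denominator); a value exactly at the threshold is not
    flagged.
    """
    target = np.asarray(rms_target_group, dtype=float)
    ref = np.asarray(rms_reference_group, dtype=float)
    if ref.size < 2:
        raise ValueError("reference group needs >= 2 values")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    threshold = mean + 2.0 * sd
    flags = target > threshold
    count = int(flags.sum())
    percent = 100.0 * count / target.size
    # half-up to 2 dp (round() is half-even and would print 15.625 -> 15.62)
    percent = float(np.floor(percent * 100 + 0.5) / 100)
    return SubgroupResult(
        reference_mean=mean, reference_sd=sd, threshold=threshold,
        flags=flags, flagged_count=count,
        flagged_percent=percent,
    )


def prototype_correlation(kernel, prototype=None) -> float:
    """Pearson r between a kernel and the prototypical melodic contour."""
    kv = _as_values(kernel)
    proto = PROTOTYPE_MELODY if prototype is None else np.asarray(prototype, dtype=float)
    if len(kv) != len(proto) or len(kv) < 3:
        raise ValueError("kernel and prototype must share length >= 3")
    r = _pearson_with(kv, proto)
    if np.isnan(r):
        raise ValueError("correlation undefined for zero-variance input")
    return r
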