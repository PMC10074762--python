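"""Simulated 2AFC observers and cohorts.

The synthetic participant is a linear template observer: on each trial
it forms the decision variable

    d = w . (s_A - s_B) + eps,    eps ~ Normal(0, (sigma_int * sigma_ext)^2)

where ``w`` is a unit-norm internal template over breakpoints, ``s_A``
and ``s_B`` are the two contours' shift vectors (cents), and
``sigma_ext`` is the analytic SD of ``w . (s_A - s_B)`` under the
stimulus distribution, so ``sigma_int`` is a dimensionless
internal-to-external noise ratio.  The observer chooses A iff d > 0
(d = 0 resolves to A; a measure-zero event kept deterministic for
testability).  With probability ``lapse_rate`` the choice is replaced by
a fair coin flip.

Cohorts add between-observer heterogeneity: observer i's template is
``normalize(base + dispersion * z_i)`` with standard-normal ``z_i``, and
internal noise / lapse rates are drawn from cohort-level distributions.
Everything is reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NoiseConfig
from .contour_noise import (
    ContourStimulus,
    SessionLog,
    TrialRecord,
    build_stimulus_pool,
    pair_trials,
    winsorized_normal_sd,
)

__all__ = [
    "ObserverSpec",
    "CohortSpec",
    "make_template",
    "external_decision_sd",
    "simulate_session",
    "make_cohort",
    "PROTOTYPE_MELODY",
]

# Notation-derived melody prototype: note 2 five semitones below note 1,
# note 3 five semitones above note 2 (cents).
PROTOTYPE_MELODY = np.array([0.0, -500.0, 0.0])


@dataclass
class ObserverSpec:
    """A simulated participant.

    ``internal_noise_ratio`` is the SD of the late decision noise in
    units of the external decision-variable SD; ``lapse_rate`` is the
    probability of an attention lapse (random choice).
    """

    participant_id: str
    group: str
    template: np.ndarray
    internal_noise_ratio: float = 0.0
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.template = np.asarray(self.template, dtype=float)
        norm = np.linalg.norm(self.template)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("template must be unit-norm")
        if self.internal_noise_ratio < 0:
            raise ValueError("internal_noise_ratio must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")


@dataclass
class CohortSpec:
    """Recipe for a group of heterogeneous observers."""

    group: str
    n_observers: int
    base_shape: str = "cubic"  # linear..quartic | prototype | custom
    custom_template: np.ndarray | None = None
    template_dispersion: float = 0.5
    internal_noise_mean: float = 4.0
    internal_noise_sd: float = 1.0
    lapse_mean: float = 0.02
    lapse_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        if self.template_dispersion < 0:
            raise ValueError("template_dispersion must be >= 0")


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ValueError("cannot normalize a zero vector")
    return v / norm


def make_template(shape: str, n_points: int,
                  extra: np.ndarray | None = None) -> np.ndarray:
    """Build a unit-norm internal template.

    ``linear``/``quadratic``/``cubic``/``quartic`` give the pure
    degree-d polynomial shape on the normalized time grid
    t_k = (k-1)/(K-1), orthogonal to all lower degrees, zero-mean and
    unit-norm; ``prototype`` is the notation-derived melody contour
    [0, -500, 0], mean-centred and normalized; ``custom`` normalizes
    ``extra``.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    degrees = {"linear": 1, "quadratic": 2, "cubic": 3, "quartic": 4}
    if shape in degrees:
        d = degrees[shape]
        if n_points < d + 1:
            raise ValueError(f"{shape} template needs >= {d + 1} points")
        t = np.arange(n_points) / (n_points - 1)
        # discrete orthogonal polynomial on the breakpoint grid (QR of the
        # Vandermonde): the pure degree-d shape with zero projection onto
        # all lower degrees, so a degree-d template is recoverable as
        # degree d by nested model selection (a raw monomial like t^4 is
        # dominated by its quadratic component and would not be)
        q, _ = np.linalg.qr(np.vander(t, d + 1, increasing=True))
        v = q[:, d]
        if v[-1] < 0:  # sign convention matching Legendre P_d(1) = 1 > 0
            v = -v
        return _normalize(v)  # zero-mean by orthogonality to the constant
    if shape == "prototype":
        if n_points != len(PROTOTYPE_MELODY):
            raise ValueError("prototype template has 3 points")
        # mean-centred (the observer only weighs relative pitch), then
        # unit-normalized: [0, -500, 0] -> [0.4082, -0.8165, 0.4082]
        return _normalize(PROTOTYPE_MELODY - PROTOTYPE_MELODY.mean())
    if shape == "custom":
        if extra is None:
            raise ValueError("custom shape requires an explicit vector")
        v = np.asarray(extra, dtype=float)
        if len(v) != n_points:
            raise ValueError("custom vector length must equal n_points")
        return _normalize(v)
    raise ValueError(f"unknown template shape {shape!r}")


def external_decision_sd(config: NoiseConfig) -> float:
    """Analytic SD of w.(s_A - s_B) for a unit-norm template.

    Shifts are i.i.d. winsorized normals with SD sigma_w, so the
    difference of two independent contours projected on any unit vector
    has SD sigma_w * sqrt(2), independent of the template direction.
    """
    sigma_w = winsorized_normal_sd(config.noise_sd, config.clip_multiple)
    return float(sigma_w * np.sqrt(2.0))


def simulate_session(observer: ObserverSpec,
                     trials: list[tuple[ContourStimulus, ContourStimulus]],
                     config: NoiseConfig,
                     rng: np.random.Generator | None = None) -> SessionLog:
    """Simulate the observer's choices over prepared stimulus pairs."""
    w = observer.template
    if len(w) != config.n_breakpoints:
        raise ValueError("template length must equal n_breakpoints")
    if rng is None:
        rng = np.random.default_rng(observer.seed)
    sigma = observer.internal_noise_ratio * external_decision_sd(config)
    a = np.array([p[0].shifts for p in trials])
    b = np.array([p[1].shifts for p in trials])
    d = (a - b) @ w
    if sigma > 0:
        d = d + rng.normal(0.0, sigma, size=len(d))
    choose_a = d >= 0.0
    if observer.lapse_rate > 0:
        lapse = rng.random(len(d)) < observer.lapse_rate
        coin = rng.random(len(d)) < 0.5
        choose_a = np.where(lapse, coin, choose_a)
    records = [
        TrialRecord(trial_index=i + 1, stim_a=sa, stim_b=sb,
                    choice="A" if ca else "B")
        for i, ((sa, sb), ca) in enumerate(zip(trials, choose_a))
    ]
    return SessionLog(participant_id=observer.participant_id,
                      group=observer.group, condition=config.condition,
                      trials=records, seed=observer.seed)


def make_cohort(spec: CohortSpec, config: NoiseConfig,
                ) -> list[tuple[ObserverSpec, SessionLog]]:
    """Simulate a whole cohort: templates, noise levels and sessions.

    Each observer receives a fresh stimulus pool and pairing drawn from
    their own child seed, mirroring pairings being randomized across
    participants.
    """
    base = make_template(spec.base_shape, config.n_breakpoints,
                         extra=spec.custom_template)
    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_observers)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(config.n_breakpoints)
        template = _normalize(base + spec.template_dispersion * z)
        noise = max(rng.normal(spec.internal_noise_mean, spec.internal_noise_sd), 0.0)
        lapse = float(np.clip(rng.normal(spec.lapse_mean, spec.lapse_sd), 0.0, 1.0))
        obs = ObserverSpec(
            participant_id=f"{spec.group}_{i + 1:02d}", group=spec.group,
            template=template, internal_noise_ratio=noise, lapse_rate=lapse,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        pool = build_stimulus_pool(config, rng)
        pairs = pair_trials(pool, rng)
        session = simulate_session(obs, pairs, config, rng=rng)
        cohort.append((obs, session))
    return cohort
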