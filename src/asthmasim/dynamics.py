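"""Jump-decay inflammation process.

Airway impairment I(t) follows a shot-noise process: exponential relaxation
toward the unimpaired state I = 0 at rate gamma (per day), punctuated by
instantaneous additive jumps at Poisson-timed trigger events,

    dI/dt = -gamma * I + sum_i alpha_i * delta(t - s_i),

where alpha_i > 0 is the effect size of the i-th environmental trigger and
s_i its time.  Trigger times form a homogeneous Poisson process of rate
``lam`` (per day); effect sizes are drawn from an exponential distribution
whose mean reflects the individual's sensitivity.  The stationary
distribution of I is Gamma(shape=lam/gamma, scale=mean_alpha), with mean
lam * mean_alpha / gamma — used both for initial conditions and for
calibration proposals.

All times are in days and all rates per day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ImpairmentState",
    "StimulusEvent",
    "PhysiologyParams",
    "decay",
    "apply_stimulus",
    "sample_stimuli",
    "sample_effect_size",
    "recovery_crossing_time",
    "simulate_trajectory",
    "evaluate_trajectory",
    "simulate_fixed_step",
    "trajectory_time_average",
]


@dataclass
class ImpairmentState:
    """Current inflammation-impairment level and clock time."""

    I: float
    t: float

    def __post_init__(self) -> None:
        if self.I < 0:
            raise ValueError(f"impairment level must be >= 0, got {self.I}")


@dataclass(frozen=True)
class StimulusEvent:
    """One environmental trigger: time s (days) and jump magnitude alpha."""

    s: float
    alpha: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"jump magnitude must be > 0, got {self.alpha}")


@dataclass(frozen=True)
class PhysiologyParams:
    """Per-patient shot-noise parameters.

    gamma: baseline recovery rate (1/day), > 0.
    lam: trigger-event rate (1/day), >= 0.
    mean_alpha: mean trigger effect size (dimensionless), > 0.
    """

    gamma: float
    lam: float
    mean_alpha: float

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.mean_alpha <= 0:
            raise ValueError("mean_alpha must be > 0")

    @property
    def stationary_mean(self) -> float:
        """Long-run time-average of I: lam * mean_alpha / gamma."""
        return self.lam * self.mean_alpha / self.gamma


def decay(I0: float, gamma_eff: float, dt: float) -> float:
    """Relax impairment for ``dt`` days at effective rate ``gamma_eff``.

    Returns I0 * exp(-gamma_eff * dt); lies in [0, I0].
    """
    if I0 < 0:
        raise ValueError(f"impairment level must be >= 0, got {I0}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if gamma_eff < 0:
        raise ValueError(f"gamma_eff must be >= 0, got {gamma_eff}")
    return I0 * np.exp(-gamma_eff * dt)


def apply_stimulus(I: float, alpha: float) -> float:
    """Instantaneous additive trigger jump: I -> I + alpha."""
    if I < 0:
        raise ValueError(f"impairment level must be >= 0, got {I}")
    if alpha <= 0:
        raise ValueError(f"jump magnitude must be > 0, got {alpha}")
    return I + alpha


def sample_stimuli(
    lam: float, horizon: float, rng: np.random.Generator
) -> np.ndarray:
    """Homogeneous Poisson trigger times on (0, horizon], sorted ascending.

    The count is drawn Poisson(lam * horizon) and times are placed uniformly,
    which is the conditional law of a homogeneous Poisson process.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    n = rng.poisson(lam * horizon)
    times = np.sort(rng.uniform(0.0, horizon, size=n))
    return times


def sample_effect_size(
    mean_alpha: float,
    sensitivity_mult: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Draw trigger effect sizes, exponential with mean mean_alpha * sensitivity_mult.

    ``sensitivity_mult`` in (0, 1] carries anti-inflammatory sensitivity
    reduction (1 = untreated sensitivity).
    """
    if mean_alpha <= 0:
        raise ValueError("mean_alpha must be > 0")
    if not (0 < sensitivity_mult <= 1):
        raise ValueError("sensitivity_mult must be in (0, 1]")
    draw = rng.standard_exponential(size=size)
    return mean_alpha * sensitivity_mult * draw


def recovery_crossing_time(
    I: float, gamma_eff: float, I_thresh: float
) -> float | None:
    """Time (days) until I decays down to I_thresh, or None if already there.

    Closed form ln(I / I_thresh) / gamma_eff; the event-driven engine uses it
    to schedule threshold re-arming and cascade exits without stepping.
    """
    if gamma_eff <= 0:
        raise ValueError("gamma_eff must be > 0")
    if I_thresh <= 0:
        raise ValueError("I_thresh must be > 0")
    if I <= I_thresh:
        return None
    return float(np.log(I / I_thresh) / gamma_eff)


def simulate_trajectory(
    params: PhysiologyParams,
    horizon: float,
    rng_stimuli: np.random.Generator,
    rng_effects: np.random.Generator,
    I0: float = 0.0,
):
    """Sample one untreated trajectory; returns (times, sizes, I_pre, I_post).

    ``I_pre[i]``/``I_post[i]`` are the impairment levels immediately before
    and after the i-th jump.  Between jumps the trajectory is the exact
    exponential decay from the last post-jump level.
    """
    times = sample_stimuli(params.lam, horizon, rng_stimuli)
    sizes = sample_effect_size(params.mean_alpha, 1.0, rng_effects, size=len(times))
    I_pre = np.empty(len(times))
    I_post = np.empty(len(times))
    I, t = float(I0), 0.0
    for i, (s, a) in enumerate(zip(times, sizes)):
        I = decay(I, params.gamma, s - t)
        I_pre[i] = I
        I = apply_stimulus(I, a)
        I_post[i] = I
        t = s
    return times, sizes, I_pre, I_post


def evaluate_trajectory(
    times: np.ndarray,
    I_post: np.ndarray,
    gamma: float,
    query_times: np.ndarray,
    I0: float = 0.0,
) -> np.ndarray:
    """Impairment at ``query_times`` given jump times and post-jump levels."""
    q = np.asarray(query_times, dtype=float)
    idx = np.searchsorted(times, q, side="right") - 1
    base_I = np.concatenate([[I0], np.asarray(I_post, dtype=float)])
    base_t = np.concatenate([[0.0], np.asarray(times, dtype=float)])
    return base_I[idx + 1] * np.exp(-gamma * (q - base_t[idx + 1]))


def simulate_fixed_step(
    gamma: float,
    jump_times: np.ndarray,
    jump_sizes: np.ndarray,
    horizon: float,
    dt: float,
    I0: float = 0.0,
) -> np.ndarray:
    """Brute-force fixed-step reference integrator (testing oracle).

    Steps the decay with the per-step factor exp(-gamma*dt) and deposits each
    jump at the first grid point at or after its time (so the set of jumps
    included at any grid time matches the continuous-time trajectory);
    returns I at grid times dt, 2*dt, ....  Discretization error on I is of
    order gamma*dt from jump-time rounding.
    """
    n_steps = int(round(horizon / dt))
    steps = np.clip(np.ceil(np.asarray(jump_times) / dt).astype(int), 1, n_steps)
    f = float(np.exp(-gamma * dt))
    traj = np.empty(n_steps)
    I = float(I0)
    ptr = 0
    n_jumps = len(steps)
    for k in range(1, n_steps + 1):
        I *= f
        while ptr < n_jumps and steps[ptr] == k:
            I += jump_sizes[ptr]
            ptr += 1
        traj[k - 1] = I
    return traj


def trajectory_time_average(
    times: np.ndarray,
    I_post: np.ndarray,
    gamma: float,
    horizon: float,
    I0: float = 0.0,
) -> float:
    """Exact time-average of the piecewise-exponential trajectory on [0, horizon]."""
    t_knots = np.concatenate([[0.0], np.asarray(times, dtype=float), [horizon]])
    levels = np.concatenate([[I0], np.asarray(I_post, dtype=float)])
    spans = np.diff(t_knots)
    # integral of I0*exp(-g*t) over a span of length L is I0*(1-exp(-g*L))/g
    area = np.sum(levels * (1.0 - np.exp(-gamma * spans)) / gamma)
    return float(area / horizon)
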