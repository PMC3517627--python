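"""Simulate the raw jump-decay impairment process for one untreated patient.

Airway impairment I(t) relaxes exponentially toward 0 (rate gamma per day)
and jumps by a random effect size at Poisson-timed environmental triggers.
The long-run time-average has the closed form lam * mean_alpha / gamma,
which the simulation should approach over a long horizon.
"""

import numpy as np

from asthmasim.dynamics import (
    PhysiologyParams,
    simulate_trajectory,
    trajectory_time_average,
)

params = PhysiologyParams(gamma=0.4, lam=0.3, mean_alpha=0.35)
horizon = 2000.0  # days

times, sizes, I_pre, I_post = simulate_trajectory(
    params,
    horizon,
    rng_stimuli=np.random.default_rng(1),
    rng_effects=np.random.default_rng(2),
)

avg = trajectory_time_average(times, I_post, params.gamma, horizon)
print(f"triggers over {horizon:.0f} days : {len(times)}")
print(f"mean trigger effect size       : {sizes.mean():.3f} (true {params.mean_alpha})")
print(f"time-average impairment        : {avg:.3f}")
print(f"stationary mean lam*alpha/gamma: {params.stationary_mean:.3f}")
# The two numbers above should agree within a few percent: the process is a
# shot-noise process whose stationary mean is exactly lam*mean_alpha/gamma.
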