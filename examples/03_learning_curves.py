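"""Learning curves and parameter recovery.

Simulates one agent through a full 100-trial training session (six
streets per trial, frame-level kinematics) and recovers the generating
learning rate by fitting an exponential to the per-trial error.
"""

import random

import numpy as np

from streetnav.agents import AgentParams, fit_learning_curve, steering_policy
from streetnav.geometry import StraightStreet, schedule_angles, training_task_spec
from streetnav.kinematics import run_street_scored

TRUE_RATE = 0.03
agent = AgentParams(baseline_skill=0.5, learning_rate=TRUE_RATE, asymptote_gain=0.5,
                    motor_noise_sd=12.0, noise_floor=2.0, competence=2, rng_seed=3)
spec = training_task_spec("Train-I")
seq = schedule_angles(spec, seed=3)
rng = random.Random(3)

errors = []
for t in range(1, 101):
    trial_angles = seq[(t - 1) * 6: t * 6]
    errs = [
        run_street_scored(
            steering_policy(agent, t, StraightStreet(float(a)), rng=rng),
            StraightStreet(float(a))).rms_error
        for a in trial_angles
    ]
    errors.append(np.mean(errs))

print(f"mean error, trials  1-10: {np.mean(errors[:10]):.4f} height units")
print(f"mean error, trials 91-100: {np.mean(errors[-10:]):.4f} height units")
amp, rate, floor = fit_learning_curve(np.asarray(errors))
print(f"\nexponential fit: amplitude {amp:.4f}, rate {rate:.4f}/trial, "
      f"floor {floor:.4f}")
print(f"true learning rate {TRUE_RATE}: recovered within "
      f"{abs(rate - TRUE_RATE) / TRUE_RATE:.0%} (single agent; averaging "
      f"agents tightens this)")
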