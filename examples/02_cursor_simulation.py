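"""Frame-level simulation of the two-key cursor control law.

A steering agent navigates one straight street: holding a key
accelerates the cursor 0.001 height units per 60 Hz frame along that
axis (capped at 0.3), releasing decelerates it the same way, and
leaving the corridor resets the cursor to the street start.
"""

import random

from streetnav.agents import AgentParams, steering_policy
from streetnav.geometry import StraightStreet
from streetnav.kinematics import advance_street
from streetnav.scoring import movement_time, street_error

agent = AgentParams(baseline_skill=0.5, learning_rate=0.03, asymptote_gain=0.5,
                    motor_noise_sd=12.0, noise_floor=2.0, competence=2, rng_seed=7)
street = StraightStreet(angle=45.0)

for trial in (1, 50, 100):
    policy = steering_policy(agent, trial, street, rng=random.Random(7))
    traj = advance_street(policy, street)
    print(f"trial {trial:>3}: {traj.outcome}, {traj.n_frames} frames, "
          f"{traj.n_resets} wall resets, "
          f"movement time {movement_time(traj):.2f} s, "
          f"RMS error {street_error(traj):.4f} height units")

print("\nPractice shrinks both movement time and path error: the agent's "
      "steering noise decays and its preferred speed rises exponentially "
      "with trial number.")
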