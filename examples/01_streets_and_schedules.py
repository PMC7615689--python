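"""Training street sets and pseudo-randomised session schedules.

Each training task is a set of straight streets whose angles span 0-90
degrees at a task-specific minimum spacing; a session is 100 six-street
trials in which every street repeats equally often and consecutive
streets differ by at least 22.5 degrees.
"""

import numpy as np

from streetnav.geometry import (
    TRAINING_DELTAS,
    build_training_angles,
    neighbour_spacing_summary,
    schedule_angles,
    training_task_spec,
)

for task, delta in TRAINING_DELTAS.items():
    angles = build_training_angles(delta)
    print(f"{task}: Δ = {delta:>6}°  ->  {len(angles):>2} streets")

summary = neighbour_spacing_summary(list(TRAINING_DELTAS.values()))
print(f"\nspacing between neighbouring tasks: mean {summary.mean:.3f}°, "
      f"SE {summary.se:.3f}°  (approximately linear task scale)")

spec = training_task_spec("Train-V")
seq = schedule_angles(spec, seed=1)
_, counts = np.unique(seq, return_counts=True)
print(f"\nTrain-V session: {seq.size} streets over {len(counts)} angles; "
      f"per-angle counts {counts.min()}-{counts.max()} (maximally balanced)")
print(f"smallest consecutive angular difference: "
      f"{np.abs(np.diff(seq)).min():.1f}° (constraint: >= 22.5°)")
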