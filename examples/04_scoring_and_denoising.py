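"""Performance index and trial-difficulty denoising.

Trial scores combine street-averaged movement time (mt) and RMS error
against pilot-calibrated constants: Pe = a/error, Pm = mt/b,
PI = Pm * Pe.  Before the learning analysis, the street-angle
difficulty structure is regressed out of the training series.
"""

import numpy as np

from streetnav.agents import PopulationSpec
from streetnav.denoise import denoise_trials, street_difficulty_profile
from streetnav.pipeline import StudyConfig, pilot_constants, simulate_street_table
from streetnav.scoring import NormalizationConstants, performance_index

cfg = StudyConfig(
    population=PopulationSpec(n_per_group=2, master_seed=5),
    pilot_n_per_group=1, master_seed=5)

constants = pilot_constants(cfg)
print(f"pilot constants: a = {constants.a:.5f} height units, b = {constants.b:.3f} s")
print(f"PI at the pilot average (mt = b, error = a): "
      f"{performance_index(constants.b, constants.a, constants):.1f}")

table = simulate_street_table(cfg)
train = table[(table.phase == 'train') & (table.training_task == 'Train-V')]
profile = street_difficulty_profile(train, "error", task="Train-V").means
print(f"\nstreet difficulty (error) on Train-V: "
      f"0° -> {profile.loc[0.0]:.4f}, 30° -> {profile.loc[30.0]:.4f}, "
      f"90° -> {profile.loc[90.0]:.4f}")
print("single-key angles are easiest; the 10-40° and 50-80° bands hardest")

wide = (train.groupby(["subject_id", "trial"])["error"].mean()
        .reset_index().pivot(index="subject_id", columns="trial", values="error"))
sd = profile.reindex(train["angle"]).to_numpy()
difficulty = (train.assign(d=sd).groupby(["subject_id", "trial"])["d"].mean()
              .reset_index().pivot(index="subject_id", columns="trial", values="d")
              .mean(axis=0).to_numpy())
res = denoise_trials(wide.to_numpy(), difficulty)
r_before = np.corrcoef(wide.to_numpy().mean(axis=0), difficulty)[0, 1]
r_after = np.corrcoef(res.values.mean(axis=0), difficulty)[0, 1]
print(f"\ncorrelation of group-mean error with trial difficulty: "
      f"{r_before:+.3f} before, {r_after:+.3f} after denoising")
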