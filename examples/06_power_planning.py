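"""A-priori sample-size planning for the between-factors design.

Converts a pilot partial eta squared into Cohen's f and searches the
smallest total N (multiple of the 15 groups) whose repeated-measures
between-factors ANOVA reaches the target power under a noncentral-F
model with correlated repeated measures.
"""

from streetnav.stats import between_factors_power, eta2_to_f, required_sample_size

eta2 = 0.054          # pilot interaction effect
rho = 0.663           # correlation among the repeated measures
f = eta2_to_f(eta2)
print(f"pilot partial eta^2 = {eta2}  ->  Cohen's f = {f:.4f} (~0.24, medium)")

n = required_sample_size(f, alpha=0.05, power=0.95, n_groups=15,
                         n_measurements=2, corr_repeated=rho)
achieved = between_factors_power(n, f, 15, 2, rho)
print(f"required total N at alpha 0.05, power 0.95: {n} "
      f"({n // 15} per group; achieved power {achieved:.4f})")
print(f"one step smaller ({n - 15}) would give power "
      f"{between_factors_power(n - 15, f, 15, 2, rho):.4f} — short of target")
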