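"""Fit the logistic non-breeding survival curve to synthetic counts.

The stop-selection emulator draws survivor counts from the density-
dependent logistic curve Su(N) = 1 / (1 + (N/v)^w) without regard to body
size.  Refitting the curve to those counts recovers the generating
parameters: the half-survival abundance v and shape exponent w.
"""

import ecocycles as ec

config = ec.ExperimentConfig(n_populations=45, n_generations=43, seed=1)
tables = ec.emulate_stop_selection(config)
sv = tables.survival
print(f"{len(sv)} population-generations, non-breeding start abundance "
      f"{sv.n_start.min()}-{sv.n_start.max()}")

fit = ec.fit_logistic_survival(sv)
print(f"\nv = {fit.v:.2f} +/- {fit.se_v:.2f} individuals "
      f"(generating value {config.su.v})")
print(f"w = {fit.w:.3f} +/- {fit.se_w:.3f} (generating value {config.su.w})")
print("\nv is the abundance at which non-breeding survival is exactly 50%;")
print("w controls how sharply survival falls once density exceeds v.")
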