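"""Combining-ability analysis of a simulated two-tester trial.

Simulates a 24-line x 2-tester multi-environment testcross trial, runs
the combined line x tester ANOVA for grain yield under infestation, and
prints the GCA/SCA summary. The tester GCA pair is exactly antisymmetric
(+g / -g): with two testers, one tester's gain is the other's loss.
"""

from lxt import (
    TrialSimConfig,
    anova_line_by_tester,
    estimate_gca_sca,
    estimate_variance_components,
    simulate_trial,
)

frame, truth = simulate_trial(TrialSimConfig(seed=42))
print(f"simulated {len(frame)} plots over "
      f"{frame['environment'].nunique()} environments\n")

an = anova_line_by_tester(frame, "yield", "infested")
print("ANOVA, grain yield under infestation (kg/ha):")
print(an.to_frame().round(1).to_string(), "\n")

res = estimate_gca_sca(frame, "yield", "infested", anova=an)
print("tester GCA (kg/ha):", res.gca_tester.round(0).to_dict())
print("top lines by GCA (kg/ha):")
print(res.gca_line.sort_values(ascending=False).head(5).round(0).to_string())
print(f"\nSE(GCA line) = {res.se_gca_line:.0f} kg/ha, "
      f"SE(SCA) = {res.se_sca:.0f} kg/ha")

vc = estimate_variance_components(an)
print(f"\nsigma2_A = {vc.sigma2_a:.0f}, sigma2_D = {vc.sigma2_d:.0f} (kg/ha)^2")
print(f"narrow-sense h2 (entry-mean) = {vc.h2_narrow:.2f}, "
      f"repeatability = {vc.repeatability:.2f}")
print("\nA positive line GCA means that line's testcrosses out-yield the "
      "trial mean on average; h2 near the repeatability means additive "
      "effects dominate the entry differences.")
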