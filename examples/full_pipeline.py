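"""The complete two-stage analysis on a simulated experiment.

Simulates the full design (3 colors x 4 seasons x 2 replications x 2
harvests x 120 plants), runs stage 1 (dose-response fits per cell) and
stage 2 (split-plot mixed model on the slopes), and prints the color
comparison of dry-weight efficiencies with Tukey letters — plus the same
analysis with far-red photons counted (band 800).
"""

from basilight.pipeline import analyze_experiment, plant_efficiency_table
from basilight.stage2 import marginal_means
from basilight.synthetic_data import SimulationConfig, simulate_plants

exp = simulate_plants(SimulationConfig(seed=1))
res = analyze_experiment(exp, band=700, compute_varcomp=False)

dw = res.stage2[("shoot_dw_g", "slope")]
print("stage-2 ANOVA for shoot dry-weight efficiencies (slopes):")
print(dw.anova.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

print("\nmarginal means by color (levels sharing a letter do not differ):")
print(marginal_means(dw, "color").to_string(index=False,
                                            float_format=lambda v: f"{v:.5f}"))
print("-> the color main effect is strong, interactions are not: light-color"
      "\n   efficiency ranking is stable across seasons and harvests.")

p700 = res.plants
p800 = plant_efficiency_table(exp, band=800)
m700 = p700.groupby("treatment")["lue"].mean()
m800 = p800.groupby("treatment")["lue"].mean()
print("\nmean LUE (g per MJ/m2 absorbed) by treatment and band:")
for color in m700.index:
    print(f"  {color:9s} band 700: {m700[color]:.4f}   band 800: {m800[color]:.4f}")
print("-> counting 700-800 nm photons adds incident energy without adding"
      "\n   dry weight, so band-800 LUE is lower - drastically so for the"
      "\n   far-red treatment.")
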