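"""Evaluate the free energies of the model system's growth pathways.

Builds the sulfate-reducer/methanogen configuration, evaluates every
catabolic and anabolic reaction at pH 7, 310.15 K with unit activities,
and shows the energy coupling (lambda_cat, yield) of the sulfate
respiration pathway.  Negative values are energy-yielding under these
standard-like conditions; lactate fermentation is endergonic until the
products (H2, acetate) are kept low by a syntrophic partner.
"""

import thermocomm as tc
from thermocomm.fixtures import FixtureOptions, build_dv_mm_mb_system

config = build_dv_mm_mb_system(FixtureOptions(cultures=("Dv", "Mm", "Mb")))
species = config.species
activities = {name: 1.0 for name in species}

print("pathway free energies at pH 7, 310.15 K (kJ per mol substrate):")
for pop in config.populations:
    for pw in pop.pathways:
        dg = tc.reaction_energy(pw.reaction, species, activities, 7.0, 310.15)
        print(f"  {pop.name}:{pw.name:34s} {dg:8.2f}")
    dg_an = tc.reaction_energy(pop.anabolic.reaction, species, activities, 7.0, 310.15)
    print(f"  {pop.name}:anabolism{'':26s} {dg_an:8.2f}  (per C-mol biomass)")

# energy coupling of sulfate respiration (per mol sulfate, i.e. 2 lactate)
dv = config.populations[0]
resp = dv.pathways[1]
dg_cat = tc.reaction_energy(
    resp.reaction.normalized_to("SO4-2"), species, activities, 7.0, 310.15
)
dg_an = tc.reaction_energy(dv.anabolic.reaction, species, activities, 7.0, 310.15)
lam = tc.lambda_cat(resp.dg_met, dg_an, dg_cat)
y = tc.growth_yield(lam, dv.anabolic.gamma_d)
print(f"\nsulfate respiration: lambda_cat = {lam:.3f} catabolic runs per C-mol")
print(f"biomass, yield = {y:.3f} C-mol biomass per mol substrate")
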