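"""Simulate the sulfate-reducer monoculture with and without
thermodynamic inhibition.

30 mM lactate and 7.5 mM sulfate in a sealed 5 mL tube for 21 days.  The
purely kinetic variant (F_T forced to 1) converts all the lactate; the
thermodynamic model stalls fermentation once accumulating H2 and acetate
push the reaction energy above the -30 kJ/mol threshold, leaving a
millimolar lactate residual -- the qualitative signature that discriminates
the two model classes.
"""

import thermocomm as tc
from thermocomm.fixtures import FixtureOptions, build_dv_mm_mb_system

config = build_dv_mm_mb_system(FixtureOptions(cultures=("Dv",)))

thermo = tc.simulate(config, thermodynamics=True)
kinetic = tc.simulate(config, thermodynamics=False)

print("final state after 504 h (mol/L):")
print(f"{'':24s}{'thermodynamic':>16s}{'kinetic only':>16s}")
for var in ("lactate", "acetate", "SO4-2", "H2(g)", "Dv", "pH"):
    a, b = thermo.final()[var], kinetic.final()[var]
    print(f"  {var:22s}{a:16.4g}{b:16.4g}")

residual = thermo.final()["lactate"] * 1e3
print(f"\nthermodynamic model retains {residual:.1f} mM lactate;")
print("the kinetic variant predicts (incorrectly, for this organism in")
print("monoculture) essentially complete conversion.")
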