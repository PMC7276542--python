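"""Estimate a gas-liquid mass-transfer coefficient from an equilibration
series.

Emulates the bench protocol: a tube whose liquid carries dissolved H2 is
headspace-flushed with N2, then the headspace composition is sampled at
0, 1, 2, 4, 8 and 24 h while the dissolved gas re-equilibrates.  The k_La
is recovered by least squares against the integrated two-film transfer
dynamics, here with 2% multiplicative measurement noise.
"""

import numpy as np

import thermocomm as tc

TRUE_KLA = 0.5  # 1/h

times, series, spec, geom, aq0, gas0 = tc.gas_equilibration_fixture(TRUE_KLA)
rng = np.random.default_rng(3)
noisy = series * np.exp(0.02 * rng.standard_normal(series.size))

blank = tc.PhaseExchangeSpec(
    spec.aqueous, spec.gas, kla=0.0, h_ref=spec.h_ref, dh_sol=spec.dh_sol
)
estimate = tc.fit_kla(times, noisy, blank, geom, aq0=aq0, gas0=gas0)

print("headspace H2 (mol per L gas):")
for t, clean, obs in zip(times, series, noisy):
    print(f"  t = {t:4.0f} h   model {clean:.3e}   observed {obs:.3e}")
print(f"\ntrue k_La      {TRUE_KLA:.3f} 1/h")
print(f"estimated k_La {estimate:.3f} 1/h")
print("the estimate sits within the few-percent scatter of the noise.")
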