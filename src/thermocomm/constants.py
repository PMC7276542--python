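"""Physical constants and standard atomic weights.

All energies in the package are in kJ; concentrations in mol L^-1 of the
respective phase volume; time in hours; temperatures in kelvin.
"""

#: Gas constant in kJ (mol K)^-1, used for all reaction-energy arithmetic.
R_KJ = 8.314e-3

#: Gas constant in J (mol K)^-1 (SI), used for ideal-gas pressure conversion.
R_J = 8.314

#: Reference temperature for standard formation energies, K.
T_REF = 298.15

#: Standard atmospheric pressure, Pa.
P_ATM = 101_325.0

# IUPAC 2021 conventional atomic weights, g mol^-1.  Only elements that
# plausibly occur in growth-medium chemistry are bundled; anything else
# raises a configuration error at parse time.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "Na": 22.990,
    "Cl": 35.45,
    "K": 39.098,
    "Mg": 24.305,
    "Ca": 40.078,
    "Fe": 55.845,
    "Mn": 54.938,
    "Zn": 65.38,
    "Se": 78.971,
    "Mo": 95.95,
    "Ni": 58.693,
    "Co": 58.933,
    "Cu": 63.546,
    "B": 10.81,
    "Si": 28.085,
}
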