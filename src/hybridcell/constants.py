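"""Physical constants and the package-wide unit system.

All quantities inside the package use a single internal unit system:

========== ==========
length     um
time       ms
potential  mV
current    nA (pA for single channels)
conductance uS (mS/cm^2 at membrane-density level)
capacitance nF (uF/cm^2 at membrane-density level)
concentration uM
resistance MOhm (Ohm*cm for specific intracellular resistivity)
========== ==========

Readers and configuration loaders convert on ingest; nothing downstream
re-converts.  A handful of frequently needed bridge factors are collected
here so unit algebra happens in exactly one place.
"""

import numpy as np

#: Faraday constant [C/mol]
FARADAY = 96485.33212
#: molar gas constant [J/(mol*K)]
GAS_CONSTANT = 8.314462618

#: membrane capacitance density: 1 uF/cm^2 = 1e-5 nF/um^2
UF_PER_CM2_TO_NF_PER_UM2 = 1.0e-5
#: membrane conductance density: 1 mS/cm^2 = 1e-5 uS/um^2
MS_PER_CM2_TO_US_PER_UM2 = 1.0e-5


def f_over_rt(temperature_K: float) -> float:
    """F/(R*T) per millivolt, i.e. the thermal-voltage reciprocal in 1/mV."""
    return FARADAY / (GAS_CONSTANT * temperature_K * 1.0e3)


def nernst_potential(z: int, c_in_uM: float, c_out_mM: float,
                     temperature_K: float) -> float:
    """Nernst (reversal) potential in mV for an ion of valence ``z``.

    ``c_in_uM`` is intracellular (uM), ``c_out_mM`` extracellular (mM);
    the mixed units mirror how the two concentrations are conventionally
    quoted for calcium.
    """
    c_in = c_in_uM * 1.0e-6          # -> mol/L
    c_out = c_out_mM * 1.0e-3        # -> mol/L
    return np.log(c_out / c_in) / (z * f_over_rt(temperature_K))


def axial_resistance_megaohm(length_um: float, diameter_um: float,
                             r_i_ohm_cm: float) -> float:
    """Axial resistance R_a = R_i * 4 l / (pi d^2) of a cylinder, in MOhm.

    ``r_i_ohm_cm`` is the specific intracellular resistivity in Ohm*cm,
    ``length_um``/``diameter_um`` in um.  1 Ohm*cm * um/um^2 = 1e-2 MOhm.
    """
    return 1.0e-2 * r_i_ohm_cm * 4.0 * length_um / (np.pi * diameter_um ** 2)
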