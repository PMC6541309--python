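"""Physical constants and unit conventions.

Unit conventions used throughout the package (NEURON-compatible):

===========================  ==========
quantity                     unit
===========================  ==========
voltage                      mV
time                         ms
conductance density          S/cm^2
permeability                 cm/s
current density              mA/cm^2
absolute current             nA
absolute conductance         uS
capacitance (specific)       uF/cm^2
capacitance (absolute)       nF
length (morphology)          um
area (internal)              cm^2
axial resistivity            Ohm*cm
concentration                mM
temperature                  degC (Kelvin internally where needed)
===========================  ==========

With these units the current balance ``C[nF] * dv/dt[mV/ms] = -I[nA]``
is consistent without further conversion factors, and
``I[nA] = i[mA/cm^2] * area[cm^2] * 1e6 = g[uS] * (v - E)[mV]``.
"""

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.31446262  # J/(mol*K)
ZERO_CELSIUS = 273.15  # K

UM2_TO_CM2 = 1e-8
MA_PER_CM2_TO_NA = 1e6  # multiplied by area in cm^2


def kelvin(temp_c: float) -> float:
    """Convert a temperature in degrees Celsius to Kelvin."""
    return temp_c + ZERO_CELSIUS
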