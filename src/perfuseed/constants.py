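"""Physical constants and unit conversions used across the package.

Internal unit system: millimetre / second / milligram, so that dynamic
viscosity carries its conventional mPa·s value unchanged (1 mPa·s =
1 mg/(mm·s)) and pressure comes out in mPa.  Flow rates are stated in
ml/min at the user surface and converted once, here.
"""

# 1 ml/min expressed in mm^3/s
ML_PER_MIN_TO_MM3_S = 1000.0 / 60.0

# Cell-suspension rheology measured at 37 degC (double-cone rheometer)
DEFAULT_VISCOSITY_MPAS = 1.176
DEFAULT_DENSITY_KG_M3 = 1004.0

# kg/m^3 -> mg/mm^3 is 1:1000; handy when mixing unit systems
KG_M3_TO_MG_MM3 = 1e-3

# Physical half-life of fluorine-18 in minutes (CODATA/nuclear data value)
F18_HALF_LIFE_MIN = 109.77

# Gravitational acceleration, mm/s^2
G_MM_S2 = 9810.0

# Silicone flow-tubing inner bore used to feed the connector nozzles, mm
DEFAULT_PORT_BORE_MM = 1.6

# Kozeny-Carman constant, classic granular-bed form
KOZENY_CARMAN_CONST = 180.0
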