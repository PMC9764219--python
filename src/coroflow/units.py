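"""Unit conversion constants.

File formats and clinical inputs use conventional units (mm, mmHg, L/min,
cP, bpm); all internal computation is SI (m, m2, m3/s, Pa, Pa*s).
"""

MMHG_TO_PA = 133.322387415
PA_TO_MMHG = 1.0 / MMHG_TO_PA

LMIN_TO_M3S = 1.0e-3 / 60.0        # litres/min -> m3/s
MLMIN_TO_M3S = 1.0e-6 / 60.0       # mL/min -> m3/s

CP_TO_PAS = 1.0e-3                 # centipoise -> Pa*s

MM_TO_M = 1.0e-3
MM2_TO_M2 = 1.0e-6
UM_TO_M = 1.0e-6

# Windkessel compliance: 1 cm^4 s^2 g^-1 = 1e-5 m^3/Pa
CM4S2G_TO_M3PA = 1.0e-5
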