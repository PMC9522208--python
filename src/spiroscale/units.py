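"""Unit conversions used throughout the package.

Raw spiracle dimensions are recorded in mm (micro-CT pixel scale);
all diffusive biophysics is done in cm (Krogh constants are per-cm),
advective conductance in SI (m), and energetics in uW / nmol O2.
Every conversion lives here so no other module hard-codes a factor.
"""

CM_PER_MM = 0.1
CM2_PER_MM2 = 0.01
M_PER_CM = 0.01
M2_PER_CM2 = 1e-4

#: (cm^2)^2 / cm  ->  (m^2)^2 / m, for the Poiseuille index area^2/length
M3_PER_CM3_ADVECTIVE = M2_PER_CM2**2 / M_PER_CM  # 1e-6


def mm_to_cm(x: float) -> float:
    return x * CM_PER_MM


def mm2_to_cm2(x: float) -> float:
    return x * CM2_PER_MM2


def cm_to_m(x: float) -> float:
    return x * M_PER_CM


def cm2_to_m2(x: float) -> float:
    return x * M2_PER_CM2
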