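# PZT-4 ceramic constants (lead zirconate titanate, poled along the 3-axis).
# Stiffness at constant electric field in GPa; piezoelectric stress constants
# in C/m^2; permittivities are relative clamped (constant-strain) values.
[pzt4]
c11_gpa = 139.0
c12_gpa = 77.8
c13_gpa = 74.3
c33_gpa = 115.0
c44_gpa = 25.6
c66_gpa = 30.6
e15 = 12.7
e31 = -5.2
e33 = 15.1
eps11_rel = 370.0
eps33_rel = 635.0
density_kg_m3 = 7500.0
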