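schema_version = 1
seed = 0

[stack]
n_layers = 50
layer_thickness_mm = 0.04
width_mm = 2.0
depth_mm = 2.0

[rod]
diameter_mm = 0.5
length_mm = 2.0
youngs_modulus_gpa = 116.0
density = 4500.0
n_elements = 6

[drive]
type = "voltage"
v_rms = 10.5
spl_ref = 100.0
f_lo = 160.0
f_hi = 8000.0
n_freq = 40

[outputs]
directory = "results"
stem = "default"

[study]
layer_counts = [10, 25, 50]
rod_moduli_gpa = [116.0, 510.0]
power_frequency_hz = 1000.0
power_v_rms = 1.0
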