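# Reference pump-free multi-organ-chip device at its measured operating point.
# Loading this file reproduces mochip.make_reference_config() plus the
# hydraulics operating point (Q = 44.4 µL/s, 5.55 mm pressure-drop path).

[geometry]
length_mm = 40.0
width_mm = 4.0
height_mm = 2.0

[fluid]
density_kg_m3 = 1000.0
viscosity_mpa_s = 1.0

[protocol]
tilt_amplitude_deg = 6.0
frequency_cpm = 10.0
peak_mean_velocity_mm_s = 5.0
profile_kind = "poiseuille"

[tracer]
diffusivity_m2_s = 4e-10

[simulation]
nx = 400
ny = 20
duration_s = 20.0
snapshot_times_s = [0.0, 2.5, 5.0, 7.5, 20.0]
cfl_number = 0.9
diffusion_number_max = 0.25
advection_scheme = "upwind"
seed = 0

[simulation.initial_condition]
kind = "centered_block"
fraction = 0.1

[hydraulics]
flow_rate_ul_s = 44.4
path_length_mm = 5.55
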