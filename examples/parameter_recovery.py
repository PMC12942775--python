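"""Calibration from noisy synthetic dye observations.

Emulates the dye-visualization experiment (width-averaged intensity
profiles with 5 % additive noise and a 2 % background offset), then
recovers the rocking velocity amplitude from the center-of-mass trajectory
and the tracer diffusivity from variance growth in a no-flow run.
"""

import numpy as np

import mochip as m
from mochip.synthetic import (
    recover_diffusivity,
    recover_velocity_amplitude,
    synthesize_observations,
)

noise = m.NoiseSpec(additive_sigma=0.05, background_offset=0.02, seed=7)

# velocity amplitude: 25 samples over two rocking periods
times = tuple(np.linspace(0.0, 12.0, 25))
cfg = m.make_reference_config().with_(duration=12.0, snapshot_times=times)
obs = synthesize_observations(cfg, noise, times)
fit = recover_velocity_amplitude(obs, frequency_cpm=10.0)
print(f"true V_peak      : 5.000 mm/s")
print(f"recovered V_peak : {fit.v_peak * 1e3:.3f} mm/s "
      f"(residual rms {fit.residual_rms * 1e3:.3f} mm, n = {fit.n_obs})")

# diffusivity: no-flow run of a fast synthetic tracer (D = 1e-6 m²/s)
diff_cfg = m.make_reference_config().with_(
    protocol=m.RockingProtocol(peak_mean_velocity=0.0),
    tracer=m.TracerSpec(diffusivity=1e-6),
    nx=800, ny=40,
    initial_condition=m.InitialCondition(kind="gaussian", sigma=1.5e-3),
    duration=2.0, snapshot_times=tuple(np.linspace(0.0, 2.0, 9)),
)
dobs = synthesize_observations(diff_cfg, noise, diff_cfg.snapshot_times)
dfit = recover_diffusivity(dobs)
print(f"true D           : 1.000e-06 m²/s")
print(f"recovered D      : {dfit.diffusivity:.3e} m²/s (n = {dfit.n_obs})")

print()
print(
    "Both parameters come back within a few percent from data as noisy as a\n"
    "fluorescence camera would deliver, so the same fits can calibrate the\n"
    "physical device from its dye movies."
)
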