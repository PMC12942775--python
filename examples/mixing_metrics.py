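"""Mixing quantification: segment CV and homogenization.

Compares the reference rocking protocol against a no-flow control on a
faster-diffusing tracer, using the coefficient of variation of mean
concentration across 5 axial segments (a 1D proxy for the device's five
chambers).
"""

import numpy as np

import mochip as m
from mochip.metrics import trajectory_metrics

# a faster-diffusing solute so homogenization happens on a simulable scale
base = m.make_reference_config().with_(
    tracer=m.TracerSpec(diffusivity=1e-7),
    duration=60.0,
    snapshot_times=(0.0, 30.0, 60.0),
)

for label, cfg in [
    ("rocked ", base),
    ("static ", base.with_(protocol=m.RockingProtocol(peak_mean_velocity=0.0))),
]:
    metrics = trajectory_metrics(m.simulate(cfg), threshold=0.5)
    t_h = metrics.homogenization_time
    print(
        f"{label}: CV(0 s) = {metrics.mixing_cv[0]:.3f} -> "
        f"CV(60 s) = {metrics.mixing_cv[-1]:.3f}, "
        f"time to CV < 0.5 : {'never' if t_h is None else f'{t_h:.1f} s'}"
    )

print()
print(
    "Rocking drives the segment CV down far faster than diffusion alone:\n"
    "oscillatory advection shears the blob across segments, which is how the\n"
    "pump-free device exchanges nutrients between its organ chambers."
)
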