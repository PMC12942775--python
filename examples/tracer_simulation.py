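"""Oscillatory tracer transport in the rocked channel.

Runs the reference 20 s simulation (fluorescein block released mid-channel,
sinusoidal rocking at 10 cycles/min) and prints the conservation audit, the
center-of-mass oscillation, and where the snapshot heatmaps were written.
"""

import numpy as np

import mochip as m
from mochip.metrics import oscillation_period
from mochip.render import render_snapshots

config = m.make_reference_config()
print(f"grid {config.nx} x {config.ny}, stable dt = {m.stable_dt(config):.4g} s")

traj = m.simulate(config)

drift = np.abs(traj.total_mass - traj.total_mass[0]).max() / traj.total_mass[0]
print(f"snapshots at t = {traj.snapshot_times} s")
print(f"relative mass drift over 20 s : {drift:.3e}")
print(f"com oscillation period        : {oscillation_period(traj.times, traj.com_x):.4f} s")
amp = (traj.com_x.max() - traj.com_x.min()) * 1e3
print(f"com peak-to-peak excursion    : {amp:.3f} mm")

paths = render_snapshots(traj, "example_output")
print(f"wrote {len(paths)} heatmap frames to example_output/")

print()
print(
    "The tracer sloshes back and forth with the 6 s rocking period (peak-to-\n"
    "peak excursion ≈ 2·V_peak/ω ≈ 9.5 mm), mass is conserved to rounding\n"
    "error, and the frames show the progressive smearing that mixes the\n"
    "medium between organ chambers."
)
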