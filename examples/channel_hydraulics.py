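"""Laminar-flow diagnostics of the rectangular circulation channel.

Builds the reference 40 mm × 4 mm × 2 mm channel, applies the measured
steady-equivalent flow rate of 44.4 µL/s of water, and prints every derived
hydraulic quantity.
"""

import mochip as m
from mochip.hydraulics import summarize

geometry = m.ChannelGeometry(length=40e-3, width=4e-3, height=2e-3)
summary = summarize(
    geometry,
    m.WATER,
    m.RockingProtocol(),          # ±6°, 10 cycles/min, 5 mm/s peak
    m.TracerSpec(),               # fluorescein, D = 4e-10 m²/s
    flow_rate=44.4e-9,            # m³/s
    path_length=5.55e-3,          # m
)

for key, value in summary.as_dict().items():
    print(f"{key:28s} {value:.6g}" if isinstance(value, float) else f"{key:28s} {value}")

print()
print(
    "Re ≈ 15 (deep in the laminar regime), wall shear ≈ 0.17 dyn/cm² (gentle\n"
    "enough for epithelial culture), and a sub-0.1 Pa pressure drop: the\n"
    "rocker perfuses the chambers without stressing the cells."
)
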