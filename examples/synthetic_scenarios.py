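"""Building SST scenarios: presets, custom gradients, and file I/O.

Shows the bundled meridional SST emulations, their 16 degC
coldest-month crossings (the latitude where winter temperature would
become limiting), and a round trip through a scenario CSV file.
"""

import tempfile
from pathlib import Path

from corallight import (
    PRESETS,
    crossing_latitude,
    preset,
    read_scenario,
    write_scenario,
)

print("preset              16C crossing  cold(0)  cold(50)  warm(0)")
for name in PRESETS:
    scn = preset(name)
    crossing = crossing_latitude(scn, 16.0)
    print(f"{name:<20}{str(crossing):>10}"
          f"{scn.coldest_month_sst[0]:>9.1f}"
          f"{scn.coldest_month_sst[50]:>10.1f}"
          f"{scn.warmest_month_sst[0]:>9.1f}")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "x6.csv"
    write_scenario(preset("eocene-x6-like"), path)
    back = read_scenario(path)
    print(f"\nround trip through {path.name}: "
          f"{back.latitudes.size} latitudes, "
          f"cold(54) = {back.coldest_month_sst[54]:.2f} degC (< 16: winter-limited)")

# The x6-like emulation keeps coldest-month SST above 16 degC out to
# 53 deg (crossing at 54), the x9-like out to 70 deg - yet the light
# model confines calcification to 50 deg in both, which is the point:
# under hothouse temperatures, light takes over as the poleward limit.
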