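"""Simulate the canonical circular nutation pattern and recover its driver.

A cylindrical organ (R = 0.5 mm, L = 20 mm) is driven by differential
growth whose principal direction rotates uniformly at omega = 4.6e-4
rad/s (a ~228 min period).  The apical tip then traces a circle in the
horizontal plane; inverting the track recovers the rotation rate.
"""

import numpy as np

from nutkin import RunConfig, invert_track, run_simulation
from nutkin.drivers import DEFAULTS

omega = DEFAULTS["omega"]
res = run_simulation(
    RunConfig(preset=4, driver_overrides={"edot": 0.0},
              t_end=5 * 2 * np.pi / omega)
)
track = res.track

print(f"simulated {len(res.frames)} frames, tip radius "
      f"{track.rho[-1]:.2f} mm (circle)")
print(f"radial deviation over the last turn: "
      f"{100 * np.ptp(track.rho[-137:]) / track.rho[-137:].mean():.2f} % "
      "(a perfect circle would give 0)")

inv = invert_track(track, R=0.5, L=20.0)
print(f"recovered mean d(psi_g)/dt = {inv.mean_rate:.3e} rad/s "
      f"(driver: {omega:.3e})")
print(f"full-rotation period T_r = {inv.T_r / 60:.1f} min "
      "— the time the growth direction takes to sweep the cross-section")
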