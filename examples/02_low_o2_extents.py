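"""How local is a local O2 challenge? Steady-state extent of a 2% window.

Runs the canonical single-window scenario (400 x 200 um window, 25 um PDMS)
to steady state under a 2% O2 challenge and prints the gradient-threshold
extent report. Uses a coarse 12.5 um grid so the demo finishes in seconds;
production runs use dx = 5 um (see scripts/acceptance.py) and give extents
a few micrometres different.
"""

from oxywindow import scenarios

res = scenarios.low_o2_challenge(dx=12.5)
rep = res.report

print(f"grid: {res.grid.shape} nodes at dx = {res.grid.spec.dx} um")
print(f"penetration depth below tissue surface : {rep.depth_from_tissue_surface:6.1f} um")
print(f"lateral extent beyond edge, long axis  : {rep.lateral_long_axis:6.1f} um")
print(f"lateral extent beyond edge, short axis : {rep.lateral_short_axis:6.1f} um")
long_dim, short_dim = rep.affected_area
print(f"affected area at the {rep.area_plane_z:.0f} um imaging plane: "
      f"{long_dim:.0f} x {short_dim:.0f} um")
print()
print("Reach is defined by where |grad PO2| falls below e^-4 ~ 0.018 mmHg/um.")
print("The affected area exceeds the 400 x 200 um window because oxygen")
print("spreads laterally inside the highly permeable PDMS membrane before")
print("entering the tissue.")
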