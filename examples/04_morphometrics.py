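"""Morphometric metrics on constructed geometry with known answers.

Curvature every 1 mm (Menger), branching angle, and end-stent angle are
each evaluated on shapes whose values are known in closed form.
"""

import numpy as np

from fevarsim import (
    Centerline,
    branching_angle,
    end_stent_angle,
    generate_aorta_centerline,
    generate_renal_branch,
    pointwise_curvature,
)
from fevarsim.stents import DeployedSG, StentGraftSpec

# circle of radius 10 mm: curvature 1/10 everywhere
t = np.linspace(0, 2 * np.pi, 63, endpoint=False)
circle = Centerline(np.column_stack([10 * np.cos(t), 10 * np.sin(t), np.zeros_like(t)]))
_, kmax = pointwise_curvature(circle)
print(f"circle r=10 mm: max curvature {kmax:.6f} 1/mm (analytic 0.1)")

# perpendicular synthetic branch: 90 degrees by construction
aorta = generate_aorta_centerline(200.0, 10.0, 0.0, 201, 0)
branch = generate_renal_branch(aorta, "right", 90.0, 40.0, 3.0, 0.0, 0)
print(f"perpendicular branch: branching angle {branching_angle(aorta, branch):.2f} deg")

# a 20-degree kink placed exactly at the distal stent end
th = np.radians(20.0)
s1 = np.arange(0.0, 21.0)
proximal = np.column_stack([s1, np.zeros_like(s1), np.zeros_like(s1)])
d = np.array([np.cos(th), np.sin(th), 0.0])
distal = proximal[-1] + np.arange(1.0, 16.0)[:, None] * d[None, :]
kinked = Centerline(np.vstack([proximal, distal]))
spec = StentGraftSpec("Patient 1", "RRA", "nominal", 23.0, 7.0)
sg = DeployedSG(spec, kinked, s_start=-3.0, s_end=20.0, flared_diameter_mm=8.0)
print(f"constructed 20 deg kink: end-stent angle {end_stent_angle(kinked, sg):.2f} deg")
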