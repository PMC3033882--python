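"""Classify intracranial electrodes against a traced lesion.

A 4 mm contact is in/on the lesion when at least half of its surface
footprint lies inside the traced label, adjacent when within 10 mm
geodesically, and outside otherwise.
"""
import numpy as np

import surfmorph as sm

mesh = sm.make_icosphere(4, 50.0)
d = sm.geodesic_distance(mesh, {0}).values
lesion = sm.LesionLabel(np.flatnonzero(d <= 15.0), source="manual_tracing")
print(f"lesion: {len(lesion)} vertices, {lesion.area(mesh):.0f} mm^2")

positions = {
    "G01 (at lesion center)": mesh.vertices[0],
    "G02 (~5 mm beyond rim)": mesh.vertices[int(np.argmin(np.abs(d - 20.0)))],
    "G03 (~30 mm away)": mesh.vertices[int(np.argmin(np.abs(d - 45.0)))],
}
for name, pos in positions.items():
    e = sm.Electrode(name.split()[0], pos, diameter=4.0)
    category = sm.classify_electrode(mesh, lesion, e)
    print(f"{name:26s} -> {category}")

print("\nin_on / adjacent / outside mirror how seizure-onset contacts are"
      " related to a structural lesion during implantation review")
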