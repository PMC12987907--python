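"""Generate one synthetic temporal-bone case and inspect its structures.

The generator builds the geometry the planner expects from a segmented
CT: three torus-arc semicircular canals with ampullary swellings, the
facial nerve and chorda tympani, the ear canal, a mastoid bone block
with a sigmoid-sinus channel and air cells, per-canal stimulation
targets and a cochlear-implant reference trajectory.
"""

import numpy as np

from canalplan import AnatomyParams, generate_case

params = AnatomyParams(seed=0)
case = generate_case(params).validate()

print(f"side: {case.side}")
print(f"inner-ear centre (origin of the case frame): {case.inner_ear_centre}")
for name, mesh in case.meshes.items():
    size = mesh.bounds[1] - mesh.bounds[0]
    print(
        f"{name:26s} {len(mesh.faces):6d} faces, "
        f"extent {size[0]:5.1f} x {size[1]:5.1f} x {size[2]:5.1f} mm"
    )
for canal, target in case.nerve_targets.items():
    print(f"nerve target ({canal:9s}): {np.round(target, 2)}")
# Each target sits at the ampullary end of its canal, where the electrode
# should come to rest; all coordinates are millimetres in a right-ear
# frame (x lateral, y anterior, z superior).
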