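"""Sweep the fenestration site along the superior canal.

The fenestration (where the drill opens the canal) can be placed at any
arc-length offset from the electrode target near the ampulla.  Placing
it further away tends to improve accessibility slightly but steepens the
achievable entry angles — the package default of 2 mm is the compromise
between the two.
"""

from canalplan import AnatomyParams, PipelineConfig, generate_case
from canalplan.pipeline import run_sweep

case = generate_case(AnatomyParams(seed=0))
table = run_sweep(case, canal="superior", config=PipelineConfig.coarse(seed=1))
print(table.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
# offset_mm is the distance of the fenestration from the electrode
# target along the canal centreline (0 = drill straight at the target).
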