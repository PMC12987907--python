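"""Run a small synthetic cohort and print summary tables.

Each case gets its own seeded anatomy (sizes +-10%, canal orientations
+-10 degrees, sigmoid position jitter, left/right mix); the summary
reports median, interquartile range and range per metric, in the style
of a clinical feasibility table.
"""

from canalplan import AnatomyParams, PipelineConfig, generate_cohort
from canalplan.pipeline import run_cohort

cases = generate_cohort(3, AnatomyParams(), seed=7)
summary, reports, errors = run_cohort(cases, PipelineConfig.coarse(seed=1))

rows = summary[summary.metric.isin(
    ["accessibility_1.0mm_pct", "min_accessible_angle_deg", "mutual_entry_angle_deg"]
)]
print(summary.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print(f"\nfeasible cases: {sum(r.feasible for r in reports)} / {len(reports)}")
if errors:
    print("failed cases:", errors)
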