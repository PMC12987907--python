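"""Plan keyhole access to all three canals for one synthetic case.

Runs the complete pipeline: outer-surface extraction, skull base and
sigmoid reconstruction, entry-region sampling, canal centrelines,
distance fields, per-canal accessibility maps, and the mutual
three-trajectory optimization that fits all entries into one 15 mm
mastoidectomy.  Desk-scale problem sizes (400 entry points, 0.5 mm
fields) keep the run around a minute.
"""

from canalplan import AnatomyParams, PipelineConfig, generate_case, run_case

case = generate_case(AnatomyParams(seed=0))
config = PipelineConfig.coarse(seed=1)
report, artifacts = run_case(case, config)

print("accessibility (% of entry points with margin > threshold, angle < 80 deg)")
for canal, metrics in report.per_canal.items():
    print(
        f"  {canal:9s} @0.5mm {metrics['accessibility_0.5mm_pct']:5.1f}%"
        f"  @1mm {metrics['accessibility_1.0mm_pct']:5.1f}%"
        f"  @2mm {metrics['accessibility_2.0mm_pct']:5.1f}%"
        f"  | lowest accessible entry angle {metrics['min_accessible_angle_deg']:.1f} deg"
    )

plan = artifacts["plan"]
print(f"\nmutual plan feasible: {plan.feasible}")
if plan.feasible:
    for canal, angle in plan.angles.items():
        print(
            f"  {canal:9s} entry angle {angle:5.1f} deg, "
            f"margin {plan.margins[canal]:.2f} mm, "
            f"drill length {plan.trajectories[canal].length:.1f} mm"
        )
    print(f"  objective sum((angle-30)^2): {plan.objective:.2f} deg^2")
    print(f"  enclosing circle of the three entries: {plan.enclosing_diameter:.1f} mm")
    print(f"  (needs to fit the {config.mastoidectomy_diameter:.0f} mm mastoidectomy)")
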