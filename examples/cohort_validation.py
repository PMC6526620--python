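"""Validate the correction over a multi-system synthetic cohort.

Three simulated CMR systems: two with first-order offset fields (one
thermally unstable, so some of its phantom references fail the 0.6 cm/s
accuracy gate) and one whose fields are purely second-order — the pattern
where linear interpolation is not enough and the order selector must step
up to a second-order surface.
"""

from pcflow import SystemProfile, analyze_cohort, generate_cohort

profiles = [
    SystemProfile(system_id="sys-linear", vessel_offset_sd=1.5),
    SystemProfile(system_id="sys-unstable", vessel_offset_sd=1.5,
                  instability_rate=0.25),
    SystemProfile(system_id="sys-quadratic", vessel_offset_sd=1.5,
                  field_order=2, curvature_sd=4.0),
]
cohort = generate_cohort(10, profiles, seed=2025)
result, _ = analyze_cohort([study for study, _ in cohort])

table = result.per_study
print(f"{len(table)} studies, {int(table['passed'].sum())} passed the "
      f"phantom accuracy check\n")
for system, summary in result.per_system.items():
    rms = summary["rms_by_order"]
    print(f"{system}: selected order {summary['selected_order']} "
          f"(RMS residual by order: "
          + ", ".join(f"{k}: {v:.2f}" for k, v in rms.items()) + " cm/s)")

o = result.overall
print(f"\noffset at vessel, passed studies (mean +/- SD):")
print(f"  before correction {o['v_pre'].mean:+.2f} +/- {o['v_pre'].sd:.2f} cm/s")
print(f"  after correction  {o['v_post'].mean:+.2f} +/- {o['v_post'].sd:.2f} cm/s")
print(f"cardiac-output error SD: {o['co_error_pre'].sd:.1f}% -> "
      f"{o['co_error_post'].sd:.2f}%")
print(f"paired t (signed offsets) p = {result.tests.p_signed:.3g}; "
      f"F-test on variances p = {result.tests.p_f:.3g}")
# the SD collapse from ~1.5 cm/s to the noise floor is the point of the
# correction; the F-test confirms the variance reduction is not chance.
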